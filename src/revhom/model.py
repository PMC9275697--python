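"""The reverse-homology dual-encoder model.

Two independently parameterized convolutional encoders embed protein
sequences: g1 encodes a *query set* of homologous IDRs (their
representations are averaged), g2 encodes each *target* sequence.  The
score between a query set and a target is the dot product of the two
256-dimensional representations, and training maximizes the score of the
held-out homolog against a large set of non-homologous decoys via the
InfoNCE objective.

Each encoder stacks three convolutional layers.  The first layer runs
parallel branches with kernel sizes 1, 3 and 5 — single-residue
composition up to short motifs.  After the last convolutional layer the
per-position channel activations are both max-pooled (best-matching
window: motif-like, presence/absence signals) and average-pooled over the
whole sequence (distributed "bulk" signals such as composition or charge).
Average-pooled values are rescaled by ``L_std / receptive_field`` so the
two pooling modes live on the same numerical scale before the two
fully-connected layers combine them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .encoding import ALPHABET
from .nn import Adam, Conv1d, Dense, Layer, ReLU


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of one encoder.

    Defaults give a 15-residue receptive field (5 + 6 + 4) and 256 final
    conv channels, hence 512 pooled features and an average-pool scale
    factor of 256/15 (printed as 17.06).
    """

    L_std: int = 256
    branch_kernels: Tuple[int, ...] = (1, 3, 5)
    branch_filters: int = 64
    conv2_kernel: int = 7
    conv2_filters: int = 256
    conv3_kernel: int = 5
    conv3_filters: int = 256
    fc_dims: Tuple[int, int] = (256, 256)
    share_weights: bool = False

    @property
    def receptive_field(self) -> int:
        return (max(self.branch_kernels) + (self.conv2_kernel - 1)
                + (self.conv3_kernel - 1))

    @property
    def scale_factor(self) -> float:
        return avg_pool_scale_factor(self.L_std, self.receptive_field)

    @property
    def n_pooled_features(self) -> int:
        return 2 * self.conv3_filters

    def to_dict(self) -> dict:
        d = asdict(self)
        d["branch_kernels"] = list(self.branch_kernels)
        d["fc_dims"] = list(self.fc_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        d["branch_kernels"] = tuple(d["branch_kernels"])
        d["fc_dims"] = tuple(d["fc_dims"])
        return cls(**d)


def avg_pool_scale_factor(L_std: int, receptive_field: int) -> float:
    """Rescaling applied to average-pooled features: standardized input
    length divided by the receptive field of the final conv layer."""
    if receptive_field < 1:
        raise ValueError("receptive field must be >= 1")
    return L_std / receptive_field


class Encoder:
    """One convolutional sequence encoder (g1 or g2)."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        c1 = config.branch_filters * len(config.branch_kernels)
        self.branches = [Conv1d(len(ALPHABET), config.branch_filters, k, rng)
                         for k in config.branch_kernels]
        self.relu1 = ReLU()
        self.conv2 = Conv1d(c1, config.conv2_filters, config.conv2_kernel, rng)
        self.relu2 = ReLU()
        self.conv3 = Conv1d(config.conv2_filters, config.conv3_filters,
                            config.conv3_kernel, rng)
        self.relu3 = ReLU()
        self.fc1 = Dense(config.n_pooled_features, config.fc_dims[0], rng)
        self.relu4 = ReLU()
        self.fc2 = Dense(config.fc_dims[0], config.fc_dims[1], rng,
                         relu_gain=False)

    @property
    def layers(self) -> List[Layer]:
        return [*self.branches, self.relu1, self.conv2, self.relu2,
                self.conv3, self.relu3, self.fc1, self.relu4, self.fc2]

    # -- forward ---------------------------------------------------------
    def conv_activations(self, x: np.ndarray) -> np.ndarray:
        """Final-conv-layer activation map, shape ``(B, L_std, conv3_filters)``."""
        h = np.concatenate([b.forward(x) for b in self.branches], axis=2)
        h = self.relu1.forward(h)
        h = self.relu2.forward(self.conv2.forward(h))
        return self.relu3.forward(self.conv3.forward(h))

    def pool(self, amap: np.ndarray) -> np.ndarray:
        """Concatenate max-pooled and scaled average-pooled channels."""
        self._argmax = amap.argmax(axis=1)
        maxv = amap.max(axis=1)
        avgv = amap.mean(axis=1) * self.config.scale_factor
        self._amap_shape = amap.shape
        return np.concatenate([maxv, avgv], axis=1)

    def forward(self, x: np.ndarray):
        """Return ``(conv3 activation map, pooled features, representation)``."""
        amap = self.conv_activations(x)
        pooled = self.pool(amap)
        h = self.relu4.forward(self.fc1.forward(pooled))
        z = self.fc2.forward(h)
        return amap, pooled, z

    def represent(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[2]

    # -- backward --------------------------------------------------------
    def backward(self, dz: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(representation)."""
        dh = self.relu4.backward(self.fc2.backward(dz))
        dpooled = self.fc1.backward(dh)
        B, L, C = self._amap_shape
        dmax, davg = dpooled[:, :C], dpooled[:, C:]
        damap = np.zeros((B, L, C))
        bi = np.repeat(np.arange(B), C)
        ci = np.tile(np.arange(C), B)
        damap[bi, self._argmax.ravel(), ci] += dmax.ravel()
        damap += (davg * self.config.scale_factor / L)[:, None, :]
        dh = self.conv3.backward(self.relu3.backward(damap))
        dh = self.conv2.backward(self.relu2.backward(dh))
        dh = self.relu1.backward(dh)
        off = 0
        for b in self.branches:
            b.backward(dh[:, :, off:off + self.config.branch_filters])
            off += self.config.branch_filters

    # -- parameters ------------------------------------------------------
    def named_params(self) -> Dict[str, np.ndarray]:
        out = {}
        for i, b in enumerate(self.branches):
            for k, v in b.params.items():
                out[f"branch{i}/{k}"] = v
        for name, layer in [("conv2", self.conv2), ("conv3", self.conv3),
                            ("fc1", self.fc1), ("fc2", self.fc2)]:
            for k, v in layer.params.items():
                out[f"{name}/{k}"] = v
        return out

    def load_params(self, params: Dict[str, np.ndarray]) -> None:
        for name, value in self.named_params().items():
            value[...] = params[name]


def score(query_repr: np.ndarray, target_repr: np.ndarray) -> float:
    """Score function f: the dot product of the two representations."""
    q = np.asarray(query_repr, dtype=float)
    t = np.asarray(target_repr, dtype=float)
    if q.shape != t.shape:
        raise ValueError(f"dimension mismatch: {q.shape} vs {t.shape}")
    return float(q @ t)


def info_nce_loss(positive_score: float, negative_scores) -> float:
    """InfoNCE: cross-entropy of the positive against M-1 negatives,
    computed through a stable log-sum-exp."""
    s = np.concatenate([[positive_score], np.asarray(negative_scores, dtype=float)])
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    m = s.max()
    return float(np.log(np.exp(s - m).sum()) + m - positive_score)


def batch_info_nce(scores: np.ndarray, positive_idx: np.ndarray):
    """Mean InfoNCE over a batch plus d(loss)/d(scores).

    ``scores`` is ``(B, M)``; ``positive_idx[k]`` marks episode k's positive
    column.  Every other column is a negative for that episode.
    """
    B = scores.shape[0]
    m = scores.max(axis=1, keepdims=True)
    e = np.exp(scores - m)
    Z = e.sum(axis=1, keepdims=True)
    logp = scores - m - np.log(Z)
    rows = np.arange(B)
    loss = -logp[rows, positive_idx].mean()
    dscores = e / Z
    dscores[rows, positive_idx] -= 1.0
    return float(loss), dscores / B


class ReverseHomologyModel:
    """Query encoder g1 + target encoder g2 + the dot-product score."""

    def __init__(self, config: EncoderConfig, seed: int = 0,
                 rng: Optional[np.random.Generator] = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.g1 = Encoder(config, rng)
        self.g2 = self.g1 if config.share_weights else Encoder(config, rng)
        self.seed = seed

    @property
    def layers(self) -> List[Layer]:
        ls = list(self.g1.layers)
        if self.g2 is not self.g1:
            ls += self.g2.layers
        return ls

    def encode_query_set(self, query_batch: np.ndarray) -> np.ndarray:
        """Average the g1 representations of a query set ``(q, L, 20)``."""
        if query_batch.shape[0] == 0:
            raise ValueError("empty query set")
        return self.g1.represent(query_batch).mean(axis=0)

    def encode_targets(self, target_batch: np.ndarray) -> np.ndarray:
        return self.g2.represent(target_batch)

    # -- persistence -----------------------------------------------------
    def save(self, prefix) -> None:
        """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (sidecar
        with config, alphabet, scale factor and seed)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"g1/{k}": v for k, v in self.g1.named_params().items()}
        if self.g2 is not self.g1:
            arrays.update({f"g2/{k}": v for k, v in self.g2.named_params().items()})
        np.savez(str(prefix) + ".npz", **arrays)
        sidecar = {
            "config": self.config.to_dict(),
            "alphabet": ALPHABET,
            "scale_factor": self.config.scale_factor,
            "receptive_field": self.config.receptive_field,
            "seed": self.seed,
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix) -> "ReverseHomologyModel":
        sidecar = json.loads(Path(str(prefix) + ".json").read_text())
        config = EncoderConfig.from_dict(sidecar["config"])
        model = cls(config, seed=sidecar.get("seed", 0))
        with np.load(str(prefix) + ".npz") as data:
            g1 = {k[len("g1/"):]: data[k] for k in data.files if k.startswith("g1/")}
            model.g1.load_params(g1)
            if model.g2 is not model.g1:
                g2 = {k[len("g2/"):]: data[k] for k in data.files if k.startswith("g2/")}
                model.g2.load_params(g2)
        return model
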