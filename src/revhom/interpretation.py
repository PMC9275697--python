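"""Turning a trained target encoder into human-readable features.

Two complementary views are produced for any of the 512 pooled features
(256 max-pooled + 256 scaled-average-pooled channels of the final conv
layer):

* **Sequence logos** — activation-weighted position frequency matrices
  built from the sequence windows that most strongly activate a channel
  (sequences reaching at least 70% of the dataset-maximal activation; if
  fewer than 20 do, the 20 highest-activating sequences are used).  Max
  features contribute their single best window with weight one; average
  features contribute every window, weighted by its activation relative
  to the sequence's best window.  Window positions hanging over a
  sequence boundary contribute nothing to those PFM columns.

* **Mutation maps / letter maps** — in-silico mutagenesis: every residue
  is substituted to every alternative and the induced change in the
  pooled feature value is recorded, giving an L x 20 delta matrix that is
  summarized per position as a signed "favourability".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .encoding import ALPHABET, AA_INDEX, encode_batch, one_hot, standardize_length
from .model import ReverseHomologyModel

FeatureId = Tuple[str, int]  # ("max" | "avg", channel)


def feature_name(feature_id: FeatureId) -> str:
    pool, ch = feature_id
    return {"max": "Max", "avg": "Average"}[pool] + f" F{ch}"


def parse_feature_name(name: str) -> FeatureId:
    kind, fnum = name.split()
    pool = {"Max": "max", "Average": "avg"}[kind]
    return pool, int(fnum.lstrip("F"))


def _conv_maps(model: ReverseHomologyModel, X: np.ndarray,
               chunk: int = 64) -> np.ndarray:
    maps = [model.g2.conv_activations(X[i:i + chunk])
            for i in range(0, len(X), chunk)]
    return np.concatenate(maps) if len(maps) > 1 else maps[0]


def _pooled_value(model: ReverseHomologyModel, amap: np.ndarray,
                  feature_id: FeatureId) -> np.ndarray:
    pool, ch = feature_id
    if ch >= amap.shape[2]:
        raise ValueError(f"channel {ch} out of range")
    trace = amap[:, :, ch]
    if pool == "max":
        return trace.max(axis=1)
    if pool == "avg":
        return trace.mean(axis=1) * model.config.scale_factor
    raise ValueError(f"unknown pool type {pool!r}")


def feature_values(model: ReverseHomologyModel, X: np.ndarray,
                   feature_id: FeatureId, chunk: int = 256) -> np.ndarray:
    """Pooled feature value of ``feature_id`` for each encoded sequence."""
    out = []
    for i in range(0, len(X), chunk):
        amap = model.g2.conv_activations(X[i:i + chunk])
        out.append(_pooled_value(model, amap, feature_id))
    return np.concatenate(out)


def extract_features(model: ReverseHomologyModel, sequences: Sequence[str],
                     ids: Optional[Sequence[str]] = None,
                     crop_mode: str = "ends", chunk: int = 64) -> pd.DataFrame:
    """Pooled target-encoder features for every sequence.

    Returns a DataFrame with one row per IDR and ``2 * conv3_filters``
    columns named ``Max F{k}`` and ``Average F{k}``.
    """
    L = model.config.L_std
    C = model.config.conv3_filters
    rows = []
    for i in range(0, len(sequences), chunk):
        X = encode_batch(sequences[i:i + chunk], L, crop_mode)
        amap = model.g2.conv_activations(X)
        maxv = amap.max(axis=1)
        avgv = amap.mean(axis=1) * model.config.scale_factor
        rows.append(np.concatenate([maxv, avgv], axis=1))
    mat = np.concatenate(rows)
    cols = [f"Max F{k}" for k in range(C)] + [f"Average F{k}" for k in range(C)]
    return pd.DataFrame(mat, columns=cols,
                        index=list(ids) if ids is not None else None)


def position_activations(model: ReverseHomologyModel, sequence: str,
                         channel: int, crop_mode: str = "ends") -> np.ndarray:
    """Final-conv-layer activation of one channel at each position of the
    standardized sequence (length ``L_std``)."""
    if channel >= model.config.conv3_filters:
        raise ValueError(f"invalid channel {channel}")
    X = encode_batch([sequence], model.config.L_std, crop_mode)
    return model.g2.conv_activations(X)[0, :, channel]


@dataclass
class PositionFrequencyMatrix:
    """Activation-weighted residue counts behind one feature's logo."""

    counts: np.ndarray           # (RF, 20)
    n_contributions: np.ndarray  # effective weight per column
    feature_id: FeatureId

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def probabilities(self) -> np.ndarray:
        """Per-column probabilities; zero-weight columns are all-NaN."""
        probs = np.full_like(self.counts, np.nan)
        ok = self.n_contributions > 0
        probs[ok] = self.counts[ok] / self.n_contributions[ok, None]
        return probs

    def information_content(self, cap: float = 4.0) -> np.ndarray:
        """Per-column information content in bits (0..log2 20, displayed
        capped at ``cap``); zero-weight columns give 0."""
        probs = self.probabilities()
        ic = np.zeros(self.width)
        for j in range(self.width):
            p = probs[j]
            if np.any(np.isnan(p)):
                continue
            nz = p[p > 0]
            ic[j] = np.log2(20) + float((nz * np.log2(nz)).sum())
        return np.minimum(ic, cap)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=list(ALPHABET))


def build_feature_logo(model: ReverseHomologyModel, sequences: Sequence[str],
                       feature_id: FeatureId, threshold: float = 0.7,
                       min_sequences: int = 20,
                       crop_mode: str = "ends") -> PositionFrequencyMatrix:
    """Activation-weighted PFM for one feature over a dataset.

    Sequences reaching ``threshold`` of the maximal activation are
    collected (at least ``min_sequences``, topping up with the highest
    activating ones).  See the module docstring for the max/avg window
    weighting rules.
    """
    if len(sequences) == 0:
        raise ValueError("empty dataset")
    L = model.config.L_std
    rf = model.config.receptive_field
    half = rf // 2
    pool, ch = feature_id

    std_seqs = [standardize_length(s, L, crop_mode) for s in sequences]
    X = encode_batch(sequences, L, crop_mode)
    amaps = _conv_maps(model, X)
    traces = amaps[:, :, ch]                      # (N, L)
    acts = _pooled_value(model, amaps, feature_id)
    if np.all(acts <= 0):
        raise ValueError(f"feature {feature_name(feature_id)} never activates "
                         "on this dataset (dead feature)")

    cut = threshold * acts.max()
    selected = np.flatnonzero(acts >= cut)
    if len(selected) < min_sequences:
        selected = np.argsort(acts)[::-1][:min_sequences]

    counts = np.zeros((rf, 20))
    weight = np.zeros(rf)
    for i in selected:
        trace = traces[i]
        seq = std_seqs[i]
        if pool == "max":
            centers = [int(trace.argmax())]
            weights = [1.0]
        else:
            wmax = trace.max()
            if wmax <= 0:
                continue
            centers = list(range(L))
            weights = list(trace / wmax)
        for p, w in zip(centers, weights):
            if w <= 0:
                continue
            for j in range(rf):
                pos = p - half + j
                if 0 <= pos < L:
                    counts[j, AA_INDEX[seq[pos]]] += w
                    weight[j] += w
    return PositionFrequencyMatrix(counts=counts, n_contributions=weight,
                                   feature_id=feature_id)


@dataclass
class LetterMap:
    """In-silico mutagenesis of one IDR against one feature.

    ``deltas[i, a]`` is the change in the pooled feature value when
    residue i is substituted to amino acid a (0 for the wild type).
    ``favourability`` has magnitude ``sum_a |delta|`` and carries the sign
    of ``-sum_a delta``: positive means mutations generally *reduce* the
    feature, i.e. the wild-type residue is favored.
    """

    deltas: np.ndarray  # (L, 20)
    wild_type: str
    feature_id: FeatureId
    cropped_positions: Tuple[int, ...] = ()

    @property
    def favourability(self) -> np.ndarray:
        total = self.deltas.sum(axis=1)
        mag = np.abs(self.deltas).sum(axis=1)
        return np.where(total <= 0, mag, -mag) * (mag > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.deltas, columns=list(ALPHABET))


def mutation_map(model: ReverseHomologyModel, sequence: str,
                 feature_id: FeatureId, crop_mode: str = "ends",
                 chunk: int = 512) -> LetterMap:
    """Full L x 20 substitution scan of ``sequence`` against one feature.

    Deltas are computed on the standardized sequence but indexed by the
    original coordinates: substituting position i mutates every repeated
    copy of that residue introduced by padding, so one biological
    substitution equals one matrix entry.  Positions removed by cropping
    (middle of sequences longer than ``L_std``) necessarily have zero
    deltas and are reported in ``cropped_positions``.
    """
    L_std = model.config.L_std
    n = len(sequence)
    wt_X = encode_batch([sequence], L_std, crop_mode)
    wt_val = feature_values(model, wt_X, feature_id)[0]

    cropped: List[int] = []
    if n > L_std and crop_mode == "ends":
        half = L_std // 2
        cropped = list(range(half, n - (L_std - half)))
    elif n > L_std and crop_mode == "center":
        start = (n - L_std) // 2
        cropped = list(range(start)) + list(range(start + L_std, n))
    cropped_set = set(cropped)

    deltas = np.zeros((n, 20))
    variants: List[np.ndarray] = []
    slots: List[Tuple[int, int]] = []

    def flush():
        nonlocal variants, slots
        if not variants:
            return
        vals = feature_values(model, np.stack(variants), feature_id)
        for (i, a), v in zip(slots, vals):
            deltas[i, a] = v - wt_val
        variants, slots = [], []

    for i in range(n):
        if i in cropped_set:
            continue
        wt_aa = sequence[i]
        for a, aa in enumerate(ALPHABET):
            if aa == wt_aa:
                continue
            mutated = sequence[:i] + aa + sequence[i + 1:]
            variants.append(one_hot(
                standardize_length(mutated, L_std, crop_mode)).matrix)
            slots.append((i, a))
            if len(variants) >= chunk:
                flush()
    flush()
    return LetterMap(deltas=deltas, wild_type=sequence, feature_id=feature_id,
                     cropped_positions=tuple(cropped))


def letter_map_summary(lmap: LetterMap, max_letters: int = 3) -> pd.DataFrame:
    """Per-position rendering data for a letter map.

    A position sits above the axis when mutations on balance *decrease*
    the feature (retaining the wild type is preferable); its letters are
    the residues yielding the highest feature value.  Below-axis positions
    show the residues yielding the lowest value.  Height is the total
    mutation-effect magnitude ``sum_a |delta|``.
    """
    rows = []
    for i in range(lmap.deltas.shape[0]):
        d = lmap.deltas[i]
        height = float(np.abs(d).sum())
        total = float(d.sum())
        if height == 0:
            rows.append({"position": i, "sign": 0, "height": 0.0, "letters": ""})
            continue
        sign = 1 if total < 0 else -1
        order = np.argsort(d)[::-1] if sign > 0 else np.argsort(d)
        letters = "".join(ALPHABET[a] for a in order[:max_letters])
        rows.append({"position": i, "sign": sign, "height": height,
                     "letters": letters})
    return pd.DataFrame(rows)


def smooth_activations(trace: np.ndarray, kernel_sd: float = 15.0,
                       truncate: float = 4.0) -> np.ndarray:
    """Gaussian smoothing of a per-position trace (reflective boundaries,
    kernel normalized to sum one)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if kernel_sd <= 0:
        return trace.copy()
    return gaussian_filter1d(trace, sigma=kernel_sd, mode="reflect",
                             truncate=truncate)


def rank_top_features(feature_matrix: pd.DataFrame, idr_id: str,
                      k: int = 5) -> pd.DataFrame:
    """Top-k features of one IDR, ranked by z-score of its activation
    against the feature's distribution over all IDRs; zero-variance
    features are excluded."""
    if len(feature_matrix) < 2:
        raise ValueError("need at least 2 IDRs to compute z-scores")
    std = feature_matrix.std(axis=0, ddof=0)
    usable = std[std > 0].index
    if len(usable) == 0:
        raise ValueError("all features have zero variance")
    sub = feature_matrix[usable]
    z = (sub.loc[idr_id] - sub.mean(axis=0)) / std[usable]
    top = z.sort_values(ascending=False).head(k)
    return pd.DataFrame({"feature": top.index, "z_score": top.values,
                         "activation": feature_matrix.loc[idr_id, top.index].values})


def max_feature_span(lmap: LetterMap, magnitude_cutoff: float = 10.0
                     ) -> Optional[Tuple[int, int]]:
    """Smallest interval containing every strongly favored position — those
    whose summed mutation effect is at most ``-magnitude_cutoff``; ``None``
    when no position qualifies."""
    totals = lmap.deltas.sum(axis=1)
    hits = np.flatnonzero(totals <= -magnitude_cutoff)
    if hits.size == 0:
        return None
    return int(hits[0]), int(hits[-1])
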