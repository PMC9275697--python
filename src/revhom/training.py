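"""Episodic contrastive training on homolog sets.

Each epoch visits every training homolog set once: q member IDRs are drawn
as the query set and one more as the held-out positive target.  Episodes
are processed in batches that share a single target list — the positives
of every episode in the batch plus filler sequences drawn from homolog
sets not represented in the batch — so each episode's positive is a
negative for every other episode (memory- and compute-sharing without
label leakage).

Validation is homology-aware: after a random 90/10 split by set, any
validation set whose reference IDR shows detectable homology to a training
reference (an externally computed pair list, e.g. all-vs-all blastp at
E < 1e-5) is discarded outright so held-out accuracy is not inflated by
near-duplicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import encode_batch
from .homolog_data import HomologSet
from .model import EncoderConfig, ReverseHomologyModel, batch_info_nce
from .nn import Adam


@dataclass
class TrainingConfig:
    query_size: int = 8
    target_size: int = 400
    batch_size: int = 64
    epochs: int = 1000
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    seed: int = 0
    validation_fraction: float = 0.10
    #: evaluate validation accuracy every k epochs (always at first/last)
    val_interval: int = 1
    #: episodes per validation set per evaluation
    val_episodes_per_set: int = 1

    def __post_init__(self):
        if self.target_size < self.batch_size:
            raise ValueError("target_size must be >= batch_size")


def sample_episode(hset: HomologSet, q: int,
                   rng: np.random.Generator) -> Tuple[List[int], int]:
    """Draw q distinct member indices as the query set plus one more as the
    positive target.  Indices refer to ``hset.members``."""
    n = len(hset)
    if n < q + 1:
        raise ValueError(
            f"set {hset.set_id!r} has {n} members; need at least {q + 1}"
        )
    picks = rng.choice(n, size=q + 1, replace=False)
    return [int(i) for i in picks[:q]], int(picks[q])


def build_batch_targets(episodes: Sequence[Tuple[str, int]],
                        all_sets: Dict[str, HomologSet],
                        M: int,
                        rng: np.random.Generator):
    """Assemble the shared target list for one batch.

    ``episodes`` is a sequence of ``(set_id, positive_member_index)``.  The
    target list holds each episode's positive followed by ``M - B`` filler
    sequences from homolog sets absent from the batch; episode k's positive
    sits at index k and all other targets are its negatives.
    """
    B = len(episodes)
    if M < B:
        raise ValueError("target size M must be >= batch size")
    batch_ids = {sid for sid, _ in episodes}
    pool = sorted(set(all_sets) - batch_ids)
    if M > B and not pool:
        raise ValueError("no homolog sets available for filler targets")
    targets: List[Tuple[str, int]] = list(episodes)
    if M > B:
        filler_sets = rng.choice(len(pool), size=M - B, replace=True)
        for si in filler_sets:
            sid = pool[int(si)]
            mi = int(rng.integers(len(all_sets[sid])))
            targets.append((sid, mi))
    positive_idx = np.arange(B)
    return targets, positive_idx


def homology_aware_split(dataset: Dict[str, HomologSet],
                         fraction: float,
                         homology_pairs: Iterable[Tuple[str, str]],
                         rng: np.random.Generator):
    """Random split by set; validation sets homologous to any training set
    (by reference-IDR pair list) are *discarded*, not moved."""
    ids = sorted(dataset)
    rng.shuffle(ids)
    n_val = int(round(len(ids) * fraction))
    val_ids, train_ids = set(ids[:n_val]), set(ids[n_val:])
    linked = set()
    for a, b in homology_pairs:
        if a in val_ids and b in train_ids:
            linked.add(a)
        if b in val_ids and a in train_ids:
            linked.add(b)
    val_ids -= linked
    if not val_ids and fraction > 0:
        warnings.warn("validation set empty after homology filtering")
    train = {sid: dataset[sid] for sid in sorted(train_ids)}
    val = {sid: dataset[sid] for sid in sorted(val_ids)}
    return train, val


@dataclass
class TrainResult:
    model: ReverseHomologyModel
    log: pd.DataFrame
    best_epoch: Optional[int] = None
    best_val_accuracy: Optional[float] = None
    best_params: Optional[dict] = None


def _sequences_of(hset: HomologSet) -> List:
    return hset.members


def train(dataset: Dict[str, HomologSet],
          encoder_config: EncoderConfig,
          training_config: TrainingConfig,
          homology_pairs: Iterable[Tuple[str, str]] = (),
          crop_mode: str = "ends") -> TrainResult:
    """Train a reverse-homology model; deterministic given the seed.

    Returns the final model, a per-epoch log of mean InfoNCE loss and
    validation accuracy, and the best-validation-accuracy parameters.
    """
    cfg = training_config
    rng = np.random.default_rng(cfg.seed)
    model = ReverseHomologyModel(encoder_config, seed=cfg.seed, rng=rng)
    opt = Adam(model.layers, lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)

    train_sets, val_sets = homology_aware_split(
        dataset, cfg.validation_fraction, homology_pairs, rng)
    L = encoder_config.L_std
    q = cfg.query_size

    # pre-encode every member once: datasets are modest and encoding is
    # deterministic, so this trades memory for a large speedup
    enc: Dict[str, np.ndarray] = {}
    for sid, hset in {**train_sets, **val_sets}.items():
        from .encoding import clip_initiator_met, standardize_length, one_hot
        mats = []
        for rec in hset.members:
            rec = clip_initiator_met(rec)
            mats.append(one_hot(standardize_length(rec.sequence, L, crop_mode)).matrix)
        enc[sid] = np.stack(mats)

    rows = []
    best = (None, -1.0, None)  # epoch, acc, params
    order = sorted(train_sets)
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_ids = order[start:start + cfg.batch_size]
            episodes = []
            queries = []
            for sid in batch_ids:
                q_idx, pos_idx = sample_episode(train_sets[sid], q, rng)
                episodes.append((sid, pos_idx))
                queries.append(enc[sid][q_idx])
            targets, positive_idx = build_batch_targets(
                episodes, train_sets, cfg.target_size, rng)
            target_X = np.stack([enc[sid][mi] for sid, mi in targets])

            B = len(batch_ids)
            query_X = np.concatenate(queries)          # (B*q, L, 20)
            q_repr = model.g1.represent(query_X)       # (B*q, d)
            q_mean = q_repr.reshape(B, q, -1).mean(axis=1)
            t_repr = model.g2.represent(target_X)      # (M, d)
            scores = q_mean @ t_repr.T                 # (B, M)

            loss, dscores = batch_info_nce(scores, positive_idx)
            losses.append(loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; training diverged")

            dq_mean = dscores @ t_repr                 # (B, d)
            dt = dscores.T @ q_mean                    # (M, d)
            dq = np.repeat(dq_mean / q, q, axis=0)
            opt.zero_grad()
            if model.g2 is model.g1:
                # shared weights: run target backward first, then query
                model.g2.backward(dt)
                model.g1.represent(query_X)  # re-cache
                model.g1.backward(dq)
            else:
                model.g2.backward(dt)
                model.g1.backward(dq)
            opt.step()

        mean_loss = float(np.mean(losses)) if losses else float("nan")
        val_acc = np.nan
        do_eval = val_sets and (
            epoch % max(cfg.val_interval, 1) == 0 or epoch == cfg.epochs - 1)
        if do_eval:
            val_acc = evaluate_accuracy(
                model, val_sets, q, cfg.target_size,
                np.random.default_rng(cfg.seed + 1_000_003 + epoch),
                episodes_per_set=cfg.val_episodes_per_set,
                encoded=enc)
            if val_acc > best[1]:
                params = {f"g1/{k}": v.copy()
                          for k, v in model.g1.named_params().items()}
                if model.g2 is not model.g1:
                    params.update({f"g2/{k}": v.copy()
                                   for k, v in model.g2.named_params().items()})
                best = (epoch, val_acc, params)
        rows.append({"epoch": epoch, "loss": mean_loss, "val_accuracy": val_acc})

    log = pd.DataFrame(rows, columns=["epoch", "loss", "val_accuracy"])
    return TrainResult(model=model, log=log, best_epoch=best[0],
                       best_val_accuracy=(best[1] if best[0] is not None else None),
                       best_params=best[2])


def evaluate_accuracy(model: ReverseHomologyModel,
                      eval_sets: Dict[str, HomologSet],
                      q: int, M: int,
                      rng: np.random.Generator,
                      episodes_per_set: int = 1,
                      encoded: Optional[Dict[str, np.ndarray]] = None) -> float:
    """Top-1 episode accuracy: fraction of episodes whose positive scores
    strictly above all M-1 negatives (ties count as incorrect)."""
    if encoded is None:
        L = model.config.L_std
        encoded = {}
        for sid, hset in eval_sets.items():
            encoded[sid] = encode_batch([m.sequence for m in hset.members], L)
    usable = [sid for sid in sorted(eval_sets) if len(eval_sets[sid]) >= q + 1]
    if not usable:
        return float("nan")
    n_correct = 0
    n_total = 0
    all_ids = sorted(encoded)
    for sid in usable:
        others = [o for o in all_ids if o != sid]
        if M > 1 and not others:
            raise ValueError("need at least two homolog sets to draw negatives")
        for _ in range(episodes_per_set):
            q_idx, pos_idx = sample_episode(eval_sets[sid], q, rng)
            q_repr = model.encode_query_set(encoded[sid][q_idx])
            neg_X = []
            for _ in range(M - 1):
                o = others[int(rng.integers(len(others)))]
                neg_X.append(encoded[o][int(rng.integers(len(encoded[o])))])
            target_X = np.stack([encoded[sid][pos_idx]] + neg_X)
            t_repr = model.encode_targets(target_X)
            scores = t_repr @ q_repr
            if np.all(scores[0] > scores[1:]):
                n_correct += 1
            n_total += 1
    return n_correct / n_total
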