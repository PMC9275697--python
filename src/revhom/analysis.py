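"""Downstream statistics over learned IDR features.

Covers: correlation of conv-channel activations with literature-curated
regex features (against a random-initialization baseline), nearest-neighbor
label enrichment in feature space, per-feature two-sample enrichment,
contingency statistics, residue-level recall at fixed coverage, and the
feature-feature correlation-distance map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .encoding import encode_batch, standardize_length
from .interpretation import _conv_maps
from .model import ReverseHomologyModel

CATEGORIES = ("motif", "physicochemical", "repeat", "amino-acid-content")


@dataclass(frozen=True)
class RegexFeature:
    """A literature-curated sequence feature expressed as a regex."""

    name: str
    pattern: str
    category: str = "motif"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        re.compile(self.pattern)


@dataclass
class EnrichmentResult:
    label: str
    statistic: float
    p_value: Optional[float] = None
    group_sizes: Tuple[int, ...] = ()
    extra: Optional[dict] = None


def binarize_regex(sequence: str, feature: RegexFeature) -> np.ndarray:
    """0/1 per-position trace: 1 inside any (possibly overlapping) match."""
    trace = np.zeros(len(sequence), dtype=float)
    # lookahead finds overlapping matches too
    for m in re.finditer(f"(?=({feature.pattern}))", sequence):
        trace[m.start():m.start() + len(m.group(1))] = 1.0
    return trace


def max_feature_correlation(model: ReverseHomologyModel,
                            sequences: Sequence[str],
                            feature: RegexFeature,
                            crop_mode: str = "ends"):
    """Best conv3 channel for a regex feature.

    Positions of every (standardized) sequence are binarized by the regex
    and correlated, over the concatenation of all sequences, with each
    channel's activation trace; returns ``(best_channel, best_correlation,
    all_correlations)``.  Zero-variance channels score 0 by convention; a
    never-matching regex yields ``(None, nan, ...)``.
    """
    if len(sequences) == 0:
        raise ValueError("empty dataset")
    L = model.config.L_std
    std_seqs = [standardize_length(s, L, crop_mode) for s in sequences]
    y = np.concatenate([binarize_regex(s, feature) for s in std_seqs])
    X = encode_batch(sequences, L, crop_mode)
    amaps = _conv_maps(model, X)                      # (N, L, C)
    A = amaps.reshape(-1, amaps.shape[2])             # (N*L, C)

    if y.std() == 0:
        return None, float("nan"), np.full(A.shape[1], np.nan)
    yc = y - y.mean()
    Ac = A - A.mean(axis=0)
    denom = np.sqrt((yc ** 2).sum()) * np.sqrt((Ac ** 2).sum(axis=0))
    corrs = np.zeros(A.shape[1])
    ok = denom > 0
    corrs[ok] = (Ac[:, ok].T @ yc) / denom[ok]
    best = int(np.argmax(corrs))
    return best, float(corrs[best]), corrs


def compare_to_random_baseline(trained: ReverseHomologyModel,
                               random_init: ReverseHomologyModel,
                               sequences: Sequence[str],
                               features: Iterable[RegexFeature],
                               crop_mode: str = "ends"):
    """Per-feature max correlation for a trained vs a randomly initialized
    model of the same architecture, plus a paired t-test per category.

    Returns ``(table, category_tests)`` DataFrames.
    """
    if trained.config != random_init.config:
        raise ValueError("checkpoints have different encoder configurations")
    rows = []
    for feat in features:
        _, c_tr, _ = max_feature_correlation(trained, sequences, feat, crop_mode)
        _, c_rd, _ = max_feature_correlation(random_init, sequences, feat, crop_mode)
        rows.append({"feature": feat.name, "category": feat.category,
                     "trained": c_tr, "random": c_rd})
    table = pd.DataFrame(rows)
    tests = []
    for cat, grp in table.dropna().groupby("category"):
        if len(grp) < 2:
            continue
        diffs = grp["trained"] - grp["random"]
        if np.allclose(diffs, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(grp["trained"], grp["random"])
        tests.append({"category": cat, "n": len(grp),
                      "t_statistic": float(t), "p_value": float(p)})
    return table, pd.DataFrame(tests, columns=["category", "n", "t_statistic",
                                               "p_value"])


def nn_label_enrichment(feature_matrix: pd.DataFrame,
                        labels: Dict[str, Set[str]],
                        label: str,
                        metric: str = "cosine") -> EnrichmentResult:
    """Nearest-neighbor label sharing versus background frequency.

    For every protein carrying ``label``, its nearest neighbor in feature
    space (excluding itself) is found; the fraction of neighbors that also
    carry the label is compared with the label's background frequency over
    all proteins: fold = observed / background.
    """
    ids = list(feature_matrix.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 proteins")
    has = np.array([label in labels.get(i, set()) for i in ids])
    if not has.any():
        raise ValueError(f"label {label!r} absent from all proteins")
    Xm = feature_matrix.to_numpy(dtype=float)
    D = cdist(Xm, Xm, metric=metric)
    np.fill_diagonal(D, np.inf)
    nn = D.argmin(axis=1)
    carriers = np.flatnonzero(has)
    observed = float(has[nn[carriers]].mean())
    background = float(has.mean())
    fold = observed / background
    return EnrichmentResult(label=label, statistic=fold,
                            group_sizes=(int(has.sum()), len(ids)),
                            extra={"observed": observed,
                                   "background": background})


def feature_set_enrichment(feature_matrix: pd.DataFrame,
                           target_ids: Sequence[str],
                           background_ids: Sequence[str]) -> pd.DataFrame:
    """Welch two-sample t per feature, target group vs background group,
    ranked by descending t statistic."""
    tg = feature_matrix.loc[list(target_ids)]
    bg = feature_matrix.loc[list(background_ids)]
    if len(tg) < 2 or len(bg) < 2:
        raise ValueError("both groups need at least 2 members")
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), \
            _warnings.catch_warnings():
        # constant features trip scipy's precision-loss warning; the
        # degenerate cases are resolved explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(tg, bg, equal_var=False)
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    # degenerate features: both groups constant and equal -> no effect
    same = (tg.std(axis=0, ddof=0) == 0) & (bg.std(axis=0, ddof=0) == 0) \
        & (tg.mean(axis=0) == bg.mean(axis=0))
    t[np.isnan(t) & same.to_numpy()] = 0.0
    p[np.isnan(p) & same.to_numpy()] = 1.0
    out = pd.DataFrame({"feature": feature_matrix.columns,
                        "t_statistic": t, "p_value": p,
                        "target_mean": tg.mean(axis=0).values,
                        "background_mean": bg.mean(axis=0).values})
    out = out.replace([np.inf, -np.inf], np.nan).dropna(subset=["t_statistic"])
    return out.sort_values("t_statistic", ascending=False,
                           ignore_index=True)


def top_activating_ids(feature_matrix: pd.DataFrame, feature: str,
                       threshold: float = 0.7) -> List[str]:
    """IDs whose activation exceeds ``threshold`` of the maximal one."""
    col = feature_matrix[feature]
    return list(col[col > threshold * col.max()].index)


def proportion_ratio(a: int, n_a: int, b: int, n_b: int) -> float:
    """Ratio of two proportions, (a/n_a) / (b/n_b)."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if b <= 0:
        raise ValueError("denominator proportion is zero")
    return (a / n_a) / (b / n_b)


def fisher_exact(table) -> Tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table; returns (odds ratio, p)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def residue_recall_at_coverage(ranked_positions: Sequence[int],
                               annotated_sites: Set[int],
                               coverage: int) -> float:
    """Fraction of annotated residues found in the top-``coverage`` ranked
    positions."""
    if not annotated_sites:
        raise ValueError("no annotated sites")
    if coverage > len(ranked_positions):
        raise ValueError("coverage exceeds number of ranked positions")
    top = set(ranked_positions[:coverage])
    return len(top & set(annotated_sites)) / len(annotated_sites)


def window_annotation_counts(feature_matrix: pd.DataFrame,
                             model: ReverseHomologyModel,
                             sequences: Dict[str, str],
                             feature: str,
                             sites: Dict[str, Set[int]],
                             window: int = 8,
                             min_sites_in_window: int = 2,
                             threshold: float = 0.7) -> Tuple[int, int]:
    """Count top-activating IDRs whose ``window`` residues around the
    maximally activated position contain at least ``min_sites_in_window``
    annotated sites (e.g. phosphosites).  Returns (hits, n_top)."""
    from .interpretation import parse_feature_name, position_activations
    pool, ch = parse_feature_name(feature)
    ids = top_activating_ids(feature_matrix, feature, threshold)
    hits = 0
    half = window // 2
    for i in ids:
        trace = position_activations(model, sequences[i], ch)
        p = int(trace.argmax())
        span = range(p - half, p + half)
        n_in = sum(1 for s in sites.get(i, set()) if s in span)
        if n_in >= min_sites_in_window:
            hits += 1
    return hits, len(ids)


def feature_distance_map(feature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Feature-feature correlation distance (1 - Pearson r across IDRs);
    zero-variance features are dropped with a warning."""
    import warnings
    std = feature_matrix.std(axis=0, ddof=0)
    usable = std[std > 0].index
    dropped = set(feature_matrix.columns) - set(usable)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features")
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable features")
    sub = feature_matrix[usable].to_numpy(dtype=float)
    corr = np.corrcoef(sub.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=usable, columns=usable)


def load_regex_features(path) -> List[RegexFeature]:
    """Read a TSV of (name, category, pattern) into RegexFeature objects."""
    df = pd.read_csv(path, sep="\t")
    return [RegexFeature(name=r["name"], pattern=r["pattern"],
                         category=r["category"]) for _, r in df.iterrows()]


def demo_regex_features() -> List[RegexFeature]:
    """The packaged 10-pattern demo set of literature-flavored IDR features
    (kinase/ligand motifs, repeats, charge tracts, residue content)."""
    from importlib.resources import files
    return load_regex_features(files("revhom") / "data" / "demo_features.tsv")
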