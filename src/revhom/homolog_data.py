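"""Construction and filtering of homologous-IDR sets.

A homolog set pairs one reference IDR with the IDR segments clipped from an
alignment of its orthologs.  This module covers the whole dataset-building
pipeline downstream of external tools (disorder prediction, alignment,
ortholog retrieval are consumed as files, never re-run here): clipping IDRs
out of whole-protein alignments, quality filters, an amino-acid F81
evolutionary distance, a redundancy-aware homolog selection heuristic, and
overlap deduplication of reference IDRs.

Coordinates in external files are 1-based inclusive; internally everything
is 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = set("-.")

#: Sentinel distance for saturated comparisons (p >= B).
SATURATED = math.inf


@dataclass(frozen=True)
class IDRRecord:
    """One intrinsically disordered region, ungapped.

    ``source_interval`` is the 1-based inclusive span of the IDR within its
    parent protein, when known.  ``is_n_terminal`` marks IDRs that begin at
    protein position 1 (their initiator Met is removed at encoding time).
    """

    id: str
    sequence: str
    species: Optional[str] = None
    source_interval: Optional[Tuple[int, int]] = None
    is_n_terminal: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.source_interval is not None:
            s, e = self.source_interval
            if s < 1 or e < s:
                raise ValueError(
                    f"record {self.id!r}: invalid interval {self.source_interval}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HomologSet:
    """A reference IDR together with its homologous IDRs (the set H)."""

    set_id: str
    reference: IDRRecord
    homologs: List[IDRRecord] = field(default_factory=list)
    #: optional clipped *aligned* rows (with gaps), keyed by record id;
    #: used for pairwise distances without re-alignment
    aligned: Optional[Dict[str, str]] = None

    @property
    def members(self) -> List[IDRRecord]:
        return [self.reference] + list(self.homologs)

    def __len__(self) -> int:
        return 1 + len(self.homologs)


@dataclass(frozen=True)
class DistanceEstimate:
    """Method-of-moments F81 distance between two aligned sequences.

    ``p`` is the proportion of differing comparable sites, ``B`` the
    background heterozygosity ``1 - sum(pi_i^2)`` and ``d`` the estimated
    substitutions per site, ``-B ln(1 - p/B)``; ``d`` is ``inf`` when the
    observed divergence saturates the model (``p >= B``).
    """

    p: float
    B: float
    d: float

    @property
    def saturated(self) -> bool:
        return not math.isfinite(self.d)


def _ungap(row: str) -> str:
    return "".join(c for c in row if c not in GAP_CHARS)


def extract_idr_homologs(alignment: Dict[str, str], reference_id: str,
                         reference_interval: Tuple[int, int],
                         set_id: Optional[str] = None) -> HomologSet:
    """Clip the IDR of every aligned homolog.

    ``reference_interval`` is 1-based inclusive on the *ungapped* reference.
    The alignment columns spanned by the reference interval are located and
    each non-reference row is clipped to those columns; gaps are removed.
    Rows that are all-gap within the clipped columns are omitted.
    """
    if reference_id not in alignment:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    rows = dict(alignment)
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    ref_row = rows[reference_id]
    start1, end1 = reference_interval
    ungapped_len = len(_ungap(ref_row))
    if start1 < 1 or end1 > ungapped_len or end1 < start1:
        raise ValueError(
            f"interval {reference_interval} out of bounds for ungapped "
            f"reference of length {ungapped_len}"
        )

    # map ungapped reference positions (0-based) -> alignment columns
    col_of = []
    for col, c in enumerate(ref_row):
        if c not in GAP_CHARS:
            col_of.append(col)
    c0, c1 = col_of[start1 - 1], col_of[end1 - 1] + 1  # half-open columns

    ref_seq = _ungap(ref_row[c0:c1])
    reference = IDRRecord(id=reference_id, sequence=ref_seq,
                          source_interval=(start1, end1),
                          is_n_terminal=start1 == 1)
    homologs = []
    aligned = {reference_id: ref_row[c0:c1]}
    for rid, row in rows.items():
        if rid == reference_id:
            continue
        clipped = row[c0:c1]
        seq = _ungap(clipped)
        if not seq:
            continue
        homologs.append(IDRRecord(id=rid, sequence=seq))
        aligned[rid] = clipped
    return HomologSet(set_id=set_id or reference_id, reference=reference,
                      homologs=homologs, aligned=aligned)


def _clean(seq: str) -> bool:
    return all(c in STANDARD_AA for c in seq)


def filter_sequences(hset: HomologSet, min_len: int = 5) -> HomologSet:
    """Drop homologs shorter than ``min_len`` or containing X / non-standard
    residues.  The reference is never dropped; it failing is an error."""
    ref = hset.reference
    if len(ref.sequence) < min_len or not _clean(ref.sequence):
        raise ValueError(
            f"reference {ref.id!r} of set {hset.set_id!r} fails the sequence filter"
        )
    kept = [h for h in hset.homologs
            if len(h.sequence) >= min_len and _clean(h.sequence)]
    return replace(hset, homologs=kept)


def filter_length_ratio(hset: HomologSet, max_ratio: float = 3.0) -> HomologSet:
    """Drop homologs more than ``max_ratio`` times longer or shorter than the
    reference (strict inequality: exactly ``max_ratio``-fold is kept)."""
    ref_len = len(hset.reference.sequence)
    if ref_len == 0:
        raise ValueError("reference has zero length")
    kept = [h for h in hset.homologs
            if len(h.sequence) <= max_ratio * ref_len
            and len(h.sequence) >= ref_len / max_ratio]
    return replace(hset, homologs=kept)


def validate_frequencies(frequencies: Sequence[float]) -> np.ndarray:
    pi = np.asarray(frequencies, dtype=float)
    if pi.shape != (20,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must be a 20-vector summing to 1")
    return pi


def f81_distance(seq_a: str, seq_b: str,
                 frequencies: Sequence[float]) -> DistanceEstimate:
    """Amino-acid F81 distance between two rows of an alignment.

    Sites where either row carries a gap or non-standard residue are
    ignored.  ``d = -B ln(1 - p/B)`` with ``B = 1 - sum(pi^2)``; when
    ``p >= B`` the estimator is saturated and ``d = inf``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    pi = validate_frequencies(frequencies)
    B = 1.0 - float(np.sum(pi ** 2))
    comparable = 0
    diff = 0
    for a, b in zip(seq_a, seq_b):
        if a in STANDARD_AA and b in STANDARD_AA:
            comparable += 1
            if a != b:
                diff += 1
    if comparable == 0:
        raise ValueError("no comparable (both-standard) sites")
    p = diff / comparable
    if p == 0.0:
        return DistanceEstimate(p=0.0, B=B, d=0.0)
    if p >= B:
        return DistanceEstimate(p=p, B=B, d=SATURATED)
    return DistanceEstimate(p=p, B=B, d=-B * math.log1p(-p / B))


def select_nonredundant_homologs(hset: HomologSet,
                                 frequencies: Sequence[float],
                                 redundancy_factor: float = 0.2,
                                 total_divergence_stop: float = 30.0,
                                 saturation_cap: float = 10.0,
                                 pairwise_total: bool = True) -> HomologSet:
    """Greedy distance-based homolog selection.

    Homologs are sorted by F81 distance to the reference and admitted in
    that order, skipping any candidate whose distance to an already-admitted
    member is below ``redundancy_factor`` times its distance to the
    reference (such candidates add little divergence of their own).
    Admission stops once the accumulated evolutionary distance among
    admitted members reaches ``total_divergence_stop`` substitutions per
    site, or candidates run out.

    Distances are computed on the clipped alignment columns carried by
    ``hset.aligned``.  Saturated distances always pass the redundancy test
    and count as ``saturation_cap`` in the running total.  When
    ``pairwise_total`` is false the total is the sum of reference distances
    only instead of all admitted pairs.
    """
    if hset.aligned is None:
        raise ValueError("select_nonredundant_homologs needs aligned rows "
                         "(HomologSet.aligned)")
    rows = hset.aligned
    ref_id = hset.reference.id

    def dist(i: str, j: str) -> float:
        d = f81_distance(rows[i], rows[j], frequencies).d
        return d

    def capped(d: float) -> float:
        return saturation_cap if not math.isfinite(d) else d

    candidates = [h for h in hset.homologs if h.id in rows]
    ref_d = {h.id: dist(ref_id, h.id) for h in candidates}
    candidates.sort(key=lambda h: (capped(ref_d[h.id]) if math.isfinite(ref_d[h.id])
                                   else math.inf, h.id))

    admitted: List[IDRRecord] = []
    total = 0.0
    for h in candidates:
        if total >= total_divergence_stop:
            break
        d_ref = ref_d[h.id]
        if admitted and math.isfinite(d_ref):
            d_closest = min(dist(h.id, m.id) for m in admitted)
            if math.isfinite(d_closest) and d_closest < redundancy_factor * d_ref:
                continue
        if pairwise_total:
            total += capped(d_ref)
            total += sum(capped(dist(h.id, m.id)) for m in admitted)
        else:
            total += capped(d_ref)
        admitted.append(h)
    return replace(hset, homologs=admitted)


def deduplicate_overlapping_idrs(records: Iterable[IDRRecord]) -> List[IDRRecord]:
    """Among reference IDRs on the same protein, keep only the longest of any
    overlapping group (ties: smaller start, then lexicographic id)."""
    recs = sorted(records, key=lambda r: r.source_interval[0])
    kept: List[IDRRecord] = []

    def overlaps(a: IDRRecord, b: IDRRecord) -> bool:
        (s1, e1), (s2, e2) = a.source_interval, b.source_interval
        return s1 <= e2 and s2 <= e1

    def better(a: IDRRecord, b: IDRRecord) -> IDRRecord:
        la = a.source_interval[1] - a.source_interval[0]
        lb = b.source_interval[1] - b.source_interval[0]
        ka = (-la, a.source_interval[0], a.id)
        kb = (-lb, b.source_interval[0], b.id)
        return a if ka <= kb else b

    for rec in recs:
        clashing = [k for k in kept if overlaps(k, rec)]
        if not clashing:
            kept.append(rec)
            continue
        winner = rec
        for c in clashing:
            winner = better(winner, c)
        if winner is rec:
            kept = [k for k in kept if k not in clashing]
            kept.append(rec)
    return sorted(kept, key=lambda r: r.source_interval[0])


def amino_acid_frequencies(sequences: Iterable[str]) -> np.ndarray:
    """Empirical residue frequencies over the given sequences, in the
    canonical ACDEFGHIKLMNPQRSTVWY order (non-standard residues ignored)."""
    order = "ACDEFGHIKLMNPQRSTVWY"
    counts = np.zeros(20)
    idx = {aa: i for i, aa in enumerate(order)}
    for seq in sequences:
        for c in seq:
            j = idx.get(c)
            if j is not None:
                counts[j] += 1
    if counts.sum() == 0:
        raise ValueError("no standard residues in input")
    return counts / counts.sum()
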