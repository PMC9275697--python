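"""Synthetic homolog sets with known, planted structure.

The generator emulates the two kinds of signal a reverse-homology model is
expected to learn: short conserved *motifs* (a consensus realized with
per-position substitution noise, retained across homologs) and *bulk*
compositional biases shared by a whole set.  Background residues are drawn
i.i.d. from a disorder-biased amino-acid composition (elevated S/T/P/E/K/Q,
nearly absent W/C) and homologs are derived from the reference by
independent per-site substitution — a star phylogeny, no indels, which is
deliberately simpler than real ortholog sets but gives exact ground truth
for planted-feature recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import ALPHABET
from .homolog_data import HomologSet, IDRRecord

#: Disorder-biased background composition (ACDEFGHIKLMNPQRSTVWY order).
DISORDER_FREQS = np.array([
    0.070, 0.005, 0.060, 0.100, 0.010, 0.070, 0.020, 0.025, 0.090, 0.040,
    0.015, 0.050, 0.090, 0.060, 0.045, 0.120, 0.080, 0.040, 0.0025, 0.0075,
])
assert abs(DISORDER_FREQS.sum() - 1.0) < 1e-12


@dataclass(frozen=True)
class PlantSpec:
    """Description of a feature planted into a fraction of homolog sets.

    For ``kind="motif"``, each carrier set realizes the consensus once
    with per-position ``substitution_prob`` noise — the set's own variant,
    which is what makes carrier sets mutually distinguishable; each
    homolog inherits that variant exactly with probability
    ``conservation``, otherwise the region drifts like background.  For
    ``kind="bulk"``, the whole set's background composition is mixed with
    ``bulk_bias`` at weight ``bulk_strength``.
    """

    kind: str = "motif"
    motif: str = "WFRYPH"
    substitution_prob: float = 0.1
    bulk_bias: Optional[Tuple[float, ...]] = None
    bulk_strength: float = 0.0
    prevalence: float = 1.0
    conservation: float = 1.0

    def __post_init__(self):
        if self.kind not in ("motif", "bulk"):
            raise ValueError(f"unknown plant kind {self.kind!r}")
        for p in (self.substitution_prob, self.prevalence, self.conservation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.kind == "motif" and any(c not in ALPHABET for c in self.motif):
            raise ValueError("motif consensus must use the 20 standard residues")


def default_length_sampler(rng: np.random.Generator,
                           mean_log: float = 4.0, sd_log: float = 0.6,
                           lo: int = 5, hi: int = 600) -> int:
    """Log-normal IDR length (median ~55 residues), clipped to [lo, hi]."""
    return int(np.clip(round(rng.lognormal(mean_log, sd_log)), lo, hi))


def _draw_residues(n: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=n, p=freqs)
    return "".join(ALPHABET[i] for i in idx)


def sample_background(length_sampler: Callable[[np.random.Generator], int],
                      aa_frequencies: np.ndarray,
                      rng: np.random.Generator,
                      record_id: str = "bg") -> IDRRecord:
    """One i.i.d. background IDR."""
    freqs = np.asarray(aa_frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6 or np.any(freqs < 0):
        raise ValueError("frequencies must be a non-negative vector summing to 1")
    n = length_sampler(rng)
    return IDRRecord(id=record_id, sequence=_draw_residues(n, freqs, rng))


def _realize_motif(spec: PlantSpec, rng: np.random.Generator) -> str:
    out = []
    for c in spec.motif:
        if rng.random() < spec.substitution_prob:
            alt = [a for a in ALPHABET if a != c]
            out.append(alt[int(rng.integers(19))])
        else:
            out.append(c)
    return "".join(out)


def _substitute(seq: str, rate: float, freqs: np.ndarray,
                rng: np.random.Generator,
                protected: range = range(0)) -> str:
    out = list(seq)
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            cur = out[i]
            while True:
                a = ALPHABET[int(rng.choice(20, p=freqs))]
                if a != cur:
                    out[i] = a
                    break
    return "".join(out)


def make_homolog_set(set_id: str, set_size: int, divergence: float,
                     rng: np.random.Generator,
                     spec: Optional[PlantSpec] = None,
                     length_sampler: Optional[Callable] = None,
                     frequencies: Optional[np.ndarray] = None,
                     edge_margin: int = 8):
    """One synthetic homolog set plus its ground-truth plant annotations.

    Returns ``(HomologSet, list of ground-truth dicts)``; each dict records
    member id, plant kind and the motif's 1-based inclusive span (motif
    plants only, conserved members only).
    """
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    length_sampler = length_sampler or default_length_sampler
    freqs = np.asarray(frequencies if frequencies is not None
                       else DISORDER_FREQS, dtype=float)
    if spec is not None and spec.kind == "bulk" and spec.bulk_bias is not None:
        bias = np.asarray(spec.bulk_bias, dtype=float)
        freqs = (1 - spec.bulk_strength) * freqs + spec.bulk_strength * bias
        freqs = freqs / freqs.sum()

    n = length_sampler(rng)
    motif_len = len(spec.motif) if (spec is not None and spec.kind == "motif") else 0
    if motif_len:
        n = max(n, motif_len + 2 * edge_margin)
        if n < motif_len:
            raise ValueError("plant longer than sequence")
    background = _draw_residues(n, freqs, rng)

    truth: List[dict] = []
    plant_at = None
    set_variant = None
    if motif_len:
        lo, hi = edge_margin, n - edge_margin - motif_len
        plant_at = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
        set_variant = _realize_motif(spec, rng)

    def build(member_id: str, is_ref: bool) -> str:
        if is_ref:
            seq = background
        else:
            prot = range(plant_at, plant_at + motif_len) if motif_len else range(0)
            seq = _substitute(background, divergence, freqs, rng, protected=prot)
        if motif_len:
            conserved = is_ref or (rng.random() < spec.conservation)
            if conserved:
                seq = seq[:plant_at] + set_variant + seq[plant_at + motif_len:]
                truth.append({"set_id": set_id, "member_id": member_id,
                              "kind": "motif", "start": plant_at + 1,
                              "end": plant_at + motif_len,
                              "realized": set_variant})
            else:
                drift = _substitute(background[plant_at:plant_at + motif_len],
                                    divergence, freqs, rng)
                seq = seq[:plant_at] + drift + seq[plant_at + motif_len:]
        elif spec is not None and spec.kind == "bulk":
            truth.append({"set_id": set_id, "member_id": member_id,
                          "kind": "bulk", "start": 1, "end": n,
                          "realized": ""})
        return seq

    ref = IDRRecord(id=f"{set_id}_ref", sequence=build(f"{set_id}_ref", True))
    homologs = [IDRRecord(id=f"{set_id}_h{j}",
                          sequence=build(f"{set_id}_h{j}", False))
                for j in range(1, set_size)]
    return HomologSet(set_id=set_id, reference=ref, homologs=homologs), truth


def generate_dataset(n_sets: int,
                     plant_specs: Sequence[PlantSpec],
                     seed: int = 0,
                     set_size: int = 12,
                     divergence: float = 0.3,
                     length_sampler: Optional[Callable] = None,
                     frequencies: Optional[np.ndarray] = None,
                     out_dir=None,
                     edge_margin: int = 8):
    """Generate ``n_sets`` homolog sets; each set carries at most one plant
    (the first spec whose prevalence roll succeeds).

    Returns ``(dict of HomologSet, ground-truth DataFrame)``; when
    ``out_dir`` is given the canonical dataset layout plus a
    ``ground_truth.tsv`` is written there.
    """
    rng = np.random.default_rng(seed)
    sets: Dict[str, HomologSet] = {}
    truth_rows: List[dict] = []
    for i in range(n_sets):
        spec = None
        for cand in plant_specs:
            if rng.random() < cand.prevalence:
                spec = cand
                break
        sid = f"set{i:04d}"
        hset, truth = make_homolog_set(sid, set_size, divergence, rng,
                                       spec=spec,
                                       length_sampler=length_sampler,
                                       frequencies=frequencies,
                                       edge_margin=edge_margin)
        sets[sid] = hset
        truth_rows.extend(truth)
    truth_df = pd.DataFrame(truth_rows, columns=["set_id", "member_id", "kind",
                                                 "start", "end", "realized"])
    if out_dir is not None:
        from .dataset_io import write_dataset
        out_dir = Path(out_dir)
        write_dataset(sets, out_dir)
        truth_df.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return sets, truth_df
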