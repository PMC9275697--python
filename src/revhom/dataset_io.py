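"""Reading and writing the canonical homolog-set dataset layout.

A dataset directory holds one FASTA per homolog set (record ids
``set_id|seq_id|species``, reference first) plus ``manifest.tsv`` with
per-set member counts and, where members are alignable without gaps
(equal lengths), the total pairwise F81 divergence.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homolog_data import (HomologSet, IDRRecord, amino_acid_frequencies,
                           f81_distance)


def _total_pairwise_divergence(hset: HomologSet,
                               frequencies: np.ndarray,
                               saturation_cap: float = 10.0) -> float:
    members = hset.members
    if len({len(m.sequence) for m in members}) != 1:
        return float("nan")
    total = 0.0
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            d = f81_distance(members[i].sequence, members[j].sequence,
                             frequencies).d
            total += saturation_cap if not math.isfinite(d) else d
    return total


def write_dataset(sets: Dict[str, HomologSet], out_dir,
                  frequencies: Optional[np.ndarray] = None) -> Path:
    """Write one FASTA per set plus a manifest TSV; deterministic."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if frequencies is None:
        frequencies = amino_acid_frequencies(
            s.reference.sequence for s in sets.values())
    rows = []
    for sid in sorted(sets):
        hset = sets[sid]
        records = []
        for m in hset.members:
            rid = f"{sid}|{m.id}|{m.species or 'NA'}"
            records.append(SeqRecord(Seq(m.sequence), id=rid, description=""))
        SeqIO.write(records, out_dir / f"{sid}.fasta", "fasta")
        rows.append({
            "set_id": sid,
            "n_members": len(hset),
            "ref_id": hset.reference.id,
            "ref_length": len(hset.reference.sequence),
            "total_divergence": _total_pairwise_divergence(hset, frequencies),
        })
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return out_dir


def read_dataset(in_dir) -> Dict[str, HomologSet]:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.tsv"
    if manifest.exists():
        set_ids = list(pd.read_csv(manifest, sep="\t")["set_id"].astype(str))
    else:
        set_ids = sorted(p.stem for p in in_dir.glob("*.fasta"))
    sets: Dict[str, HomologSet] = {}
    for sid in set_ids:
        records: List[IDRRecord] = []
        for rec in SeqIO.parse(in_dir / f"{sid}.fasta", "fasta"):
            parts = rec.id.split("|")
            seq_id = parts[1] if len(parts) >= 2 else rec.id
            species = parts[2] if len(parts) >= 3 and parts[2] != "NA" else None
            records.append(IDRRecord(id=seq_id, sequence=str(rec.seq),
                                     species=species))
        if not records:
            continue
        sets[sid] = HomologSet(set_id=sid, reference=records[0],
                               homologs=records[1:])
    return sets


def read_membership_table(path) -> Dict[str, HomologSet]:
    """Read a TSV of (set_id, seq_id, species, sequence); the first row of
    each set is its reference."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sets: Dict[str, HomologSet] = {}
    for sid, grp in df.groupby("set_id", sort=True):
        recs = [IDRRecord(id=r["seq_id"], sequence=r["sequence"],
                          species=(r.get("species") or None))
                for _, r in grp.iterrows()]
        sets[str(sid)] = HomologSet(set_id=str(sid), reference=recs[0],
                                    homologs=recs[1:])
    return sets


def read_intervals_table(path) -> Dict[str, Tuple[int, int]]:
    """TSV of (protein_id, start, end) with 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t")
    return {str(r["protein_id"]): (int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()}


def read_alignment_fasta(path) -> Dict[str, str]:
    """Aligned FASTA -> ordered {id: aligned sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
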