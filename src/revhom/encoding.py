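"""One-hot preprocessing of IDR sequences.

Sequences are standardized to a fixed length before entering the encoders:
long sequences keep their first and last ``L_std/2`` residues (terminal
regions of disordered regions are often the functional ones), short
sequences are repeat-padded ("ACD" -> "ACDACD" -> ...) and clipped, which
avoids giving the model a trivial length cue that a padding token would
provide.  An initiator methionine is removed from N-terminal IDRs for the
same reason: it is a start-codon artifact, not a disorder feature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .homolog_data import IDRRecord

#: Fixed residue ordering used by every matrix in the package
#: (logos, letter maps, frequency vectors).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

DEFAULT_LENGTH = 256


@dataclass(frozen=True)
class EncodedSequence:
    """A standardized sequence as an ``L_std x 20`` indicator matrix."""

    matrix: np.ndarray
    original_length: int
    was_cropped: bool
    was_padded: bool

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def clip_initiator_met(record: IDRRecord) -> IDRRecord:
    """Drop a leading start-codon methionine from an N-terminal IDR."""
    if record.is_n_terminal and record.sequence.startswith("M"):
        new_seq = record.sequence[1:]
        if not new_seq:
            raise ValueError(
                f"clipping initiator Met of {record.id!r} leaves an empty sequence"
            )
        return replace(record, sequence=new_seq)
    return record


def standardize_length(sequence: str, L_std: int = DEFAULT_LENGTH,
                       crop_mode: str = "ends") -> str:
    """Return a length-``L_std`` version of ``sequence``.

    Longer sequences are cropped: ``ends`` keeps the first and last
    ``L_std/2`` residues, ``center`` keeps the central window.  Shorter
    sequences are repeated until they exceed ``L_std`` and clipped at the
    end.
    """
    if not sequence:
        raise ValueError("cannot standardize an empty sequence")
    n = len(sequence)
    if n == L_std:
        return sequence
    if n > L_std:
        if crop_mode == "ends":
            half = L_std // 2
            return sequence[:half] + sequence[n - (L_std - half):]
        if crop_mode == "center":
            start = (n - L_std) // 2
            return sequence[start:start + L_std]
        raise ValueError(f"unknown crop_mode {crop_mode!r}")
    reps = -(-L_std // n)  # ceil
    return (sequence * reps)[:L_std]


def one_hot(sequence: str) -> EncodedSequence:
    """Encode a (already standardized) sequence as an ``L x 20`` matrix."""
    idx = np.empty(len(sequence), dtype=np.int64)
    for i, aa in enumerate(sequence):
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
        idx[i] = j
    mat = np.zeros((len(sequence), len(ALPHABET)), dtype=np.float64)
    mat[np.arange(len(sequence)), idx] = 1.0
    return EncodedSequence(matrix=mat, original_length=len(sequence),
                           was_cropped=False, was_padded=False)


def decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot` for indicator matrices."""
    return "".join(ALPHABET[j] for j in np.asarray(matrix).argmax(axis=1))


def encode_record(record: IDRRecord, L_std: int = DEFAULT_LENGTH,
                  crop_mode: str = "ends") -> EncodedSequence:
    """Full preprocessing: Met clipping, length standardization, one-hot."""
    record = clip_initiator_met(record)
    std = standardize_length(record.sequence, L_std, crop_mode)
    enc = one_hot(std)
    n = len(record.sequence)
    return EncodedSequence(matrix=enc.matrix, original_length=n,
                           was_cropped=n > L_std, was_padded=n < L_std)


def encode_batch(sequences, L_std: int = DEFAULT_LENGTH,
                 crop_mode: str = "ends") -> np.ndarray:
    """Stack plain strings into a ``(B, L_std, 20)`` one-hot array."""
    out = np.zeros((len(sequences), L_std, len(ALPHABET)), dtype=np.float64)
    for b, seq in enumerate(sequences):
        out[b] = one_hot(standardize_length(seq, L_std, crop_mode)).matrix
    return out
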