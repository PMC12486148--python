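"""Peptide validation, one-hot encoding, Hamming distance, mutation moves
and FASTA I/O.

Design campaigns operate on fixed-length peptides over the canonical
20-letter alphabet (12 residues by default).  All randomness flows through a
:class:`numpy.random.Generator` supplied by the caller; nothing in this
module touches global random state.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import CANONICAL, NON_CANONICAL, Alphabet

logger = logging.getLogger(__name__)

DEFAULT_LENGTH = 12


class Peptide(str):
    """A validated fixed-length peptide sequence.

    Instances are ordinary strings; use :func:`validate_peptide` to
    construct one with validation.
    """

    __slots__ = ()


def validate_peptide(
    raw: str,
    length: int = DEFAULT_LENGTH,
    alphabet: Alphabet = CANONICAL,
) -> Peptide:
    """Validate ``raw`` as a peptide of the given design length.

    Lowercase input is accepted and uppercased.  Non-canonical letters
    (ambiguity codes B/J/O/U/X/Z etc.) are rejected with the 1-based
    offending position.
    """
    seq = raw.strip().upper()
    if len(seq) != length:
        raise ValueError(
            f"peptide {raw!r} has length {len(seq)}, expected {length}"
        )
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            kind = "non-canonical letter" if ch in NON_CANONICAL else "invalid character"
            raise ValueError(f"{kind} {ch!r} at position {pos} in {raw!r}")
    return Peptide(seq)


def one_hot_encode(p: str, alphabet: Alphabet = CANONICAL) -> np.ndarray:
    """Encode a peptide as an L x |alphabet| one-hot matrix (uint8)."""
    idx = alphabet.to_indices(p)
    mat = np.zeros((len(idx), len(alphabet)), dtype=np.uint8)
    mat[np.arange(len(idx)), idx] = 1
    return mat


def one_hot_decode(mat: np.ndarray, alphabet: Alphabet = CANONICAL) -> Peptide:
    """Invert :func:`one_hot_encode`."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != len(alphabet):
        raise ValueError(f"expected an L x {len(alphabet)} matrix")
    if not (mat.sum(axis=1) == 1).all():
        raise ValueError("every row of a one-hot matrix must sum to 1")
    return Peptide(alphabet.to_sequence(mat.argmax(axis=1)))


def encode_batch(peptides: Sequence[str], alphabet: Alphabet = CANONICAL) -> np.ndarray:
    """Encode equal-length peptides as a (B, L) uint8 index array."""
    if len(peptides) == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    return np.stack([alphabet.to_indices(p) for p in peptides])


def hamming(p: str, q: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(p) != len(q):
        raise ValueError(f"length mismatch: {len(p)} vs {len(q)}")
    return sum(a != b for a, b in zip(p, q))


def hamming_indices(a: np.ndarray, b: np.ndarray) -> int:
    return int((np.asarray(a) != np.asarray(b)).sum())


def mutate_indices(
    idx: np.ndarray,
    rng: np.random.Generator,
    p_substitution: float = 0.5,
    n_letters: int = 20,
) -> np.ndarray:
    """Propose a mutation of an index-encoded peptide.

    With probability ``p_substitution`` one position is changed to one of the
    other ``n_letters - 1`` letters (both drawn uniformly); otherwise the
    residues at two distinct positions are swapped.  A swap of two equal
    residues would leave the sequence unchanged, so it is resampled as a
    substitution: every proposal differs from its parent.
    """
    L = len(idx)
    out = idx.copy()
    if rng.random() >= p_substitution and L >= 2:
        i, j = rng.choice(L, size=2, replace=False)
        if idx[i] != idx[j]:
            out[i], out[j] = idx[j], idx[i]
            return out
        # equal residues: fall through to a substitution
    pos = int(rng.integers(L))
    shift = int(rng.integers(1, n_letters))
    out[pos] = (int(idx[pos]) + shift) % n_letters
    return out


def propose_mutation(
    p: str,
    rng: np.random.Generator,
    p_substitution: float = 0.5,
    alphabet: Alphabet = CANONICAL,
) -> Peptide:
    """Propose a substitution or swap move on a peptide (see
    :func:`mutate_indices` for the move semantics)."""
    idx = alphabet.to_indices(p)
    new = mutate_indices(idx, rng, p_substitution, n_letters=len(alphabet))
    return Peptide(alphabet.to_sequence(new))


def random_peptide(
    rng: np.random.Generator,
    length: int = DEFAULT_LENGTH,
    alphabet: Alphabet = CANONICAL,
) -> Peptide:
    return Peptide(alphabet.to_sequence(rng.integers(len(alphabet), size=length)))


# ---------------------------------------------------------------------------
# FASTA and plain-text I/O
# ---------------------------------------------------------------------------

def read_fasta(
    path,
    length: int = DEFAULT_LENGTH,
    alphabet: Alphabet = CANONICAL,
    strict: bool = True,
) -> list[tuple[str, Peptide]]:
    """Read peptides from a FASTA file.

    In strict mode an invalid record raises; in lenient mode it is logged
    (with its record id) and skipped.  Lowercase sequences are uppercased in
    both modes.  An empty file yields an empty list.
    """
    records: list[tuple[str, Peptide]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            pep = validate_peptide(str(rec.seq), length=length, alphabet=alphabet)
        except ValueError as exc:
            if strict:
                raise ValueError(f"record {rec.id!r}: {exc}") from exc
            logger.warning("skipping record %r: %s", rec.id, exc)
            continue
        records.append((rec.id, pep))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA, preserving order."""
    seq_records = [
        SeqRecord(Seq(str(seq)), id=str(name), description="")
        for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_sequence_lines(
    path,
    length: int = DEFAULT_LENGTH,
    alphabet: Alphabet = CANONICAL,
) -> list[Peptide]:
    """Convenience dialect: one sequence per line, blank lines ignored."""
    peptides = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                peptides.append(validate_peptide(line, length=length, alphabet=alphabet))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return peptides
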