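"""Post-campaign analyses: novelty, diversity-based candidate selection,
amino-acid composition profiles and composition correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alphabet import CANONICAL, Alphabet
from .sequences import Peptide, hamming

__all__ = [
    "CompositionProfile",
    "SelectionResult",
    "novelty",
    "select_diverse",
    "composition_frequencies",
    "frequency_correlation",
    "composition_ratio",
]


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled residue frequencies over a set of equal-length peptides,
    indexed by alphabet order; frequencies sum to 1."""

    frequencies: np.ndarray
    n_peptides: int
    n_residues: int
    alphabet: Alphabet = CANONICAL

    def as_dict(self) -> dict[str, float]:
        return {
            letter: float(f)
            for letter, f in zip(self.alphabet.letters, self.frequencies)
        }


def novelty(designs: Sequence[str], reference: Iterable[str], k: int) -> float:
    """Fraction of the top-k designs absent from a reference sequence set.

    ``designs`` must be pre-sorted best-first; matching is exact string
    equality.  Against an empty reference the novelty is 1 by convention.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(designs):
        raise ValueError(f"k={k} exceeds {len(designs)} designs")
    ref = set(reference)
    top = designs[:k]
    return sum(1 for s in top if s not in ref) / k


@dataclass
class SelectionResult:
    """Outcome of greedy diversity selection; ``shortfall`` is set when
    fewer than the requested k candidates satisfied the distance
    constraint."""

    peptides: list[Peptide]
    values: list[float]
    shortfall: bool

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)


def select_diverse(
    candidates: Sequence[tuple[str, float]],
    k: int = 12,
    min_distance: int = 3,
) -> SelectionResult:
    """Greedy diversity selection from an objective-sorted candidate list.

    Scans candidates in rank order (best first) and selects one iff its
    Hamming distance to every already-selected peptide is at least
    ``min_distance``, stopping after ``k`` selections or the end of the
    list.  The default panel of 12 at distance >= 3 mirrors the candidate
    panels assembled for downstream validation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    chosen: list[Peptide] = []
    values: list[float] = []
    for seq, value in candidates:
        if all(hamming(seq, prev) >= min_distance for prev in chosen):
            chosen.append(Peptide(seq))
            values.append(float(value))
            if len(chosen) == k:
                break
    return SelectionResult(peptides=chosen, values=values, shortfall=len(chosen) < k)


def composition_frequencies(
    peptides: Sequence[str], alphabet: Alphabet = CANONICAL
) -> CompositionProfile:
    """Residue frequencies pooled over all positions of all peptides."""
    if len(peptides) == 0:
        raise ValueError("composition of an empty peptide set is undefined")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError("peptides must share one length")
    counts = np.zeros(len(alphabet), dtype=float)
    for p in peptides:
        counts += np.bincount(alphabet.to_indices(p), minlength=len(alphabet))
    total = counts.sum()
    return CompositionProfile(
        frequencies=counts / total,
        n_peptides=len(peptides),
        n_residues=int(total),
        alphabet=alphabet,
    )


def _as_vector(x) -> np.ndarray:
    if isinstance(x, CompositionProfile):
        return np.asarray(x.frequencies, dtype=float)
    return np.asarray(x, dtype=float)


def frequency_correlation(a, b) -> tuple[float, float]:
    """Squared Pearson correlation between two frequency vectors and the
    two-sided p-value of the t-transform with n - 2 degrees of freedom."""
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ValueError("vectors must have equal length")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(va, vb)
    return float(r**2), float(p)


def composition_ratio(a, b, pseudocount: float = 0.0) -> np.ndarray:
    """Elementwise frequency ratio (a_i + pseudocount) / (b_i + pseudocount).

    With the default pseudocount of 0 a zero denominator yields ``inf``; a
    small positive pseudocount keeps every ratio finite.
    """
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ValueError("profiles must share an alphabet")
    with np.errstate(divide="ignore", invalid="ignore"):
        return (va + pseudocount) / (vb + pseudocount)
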