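"""Amino-acid alphabets and residue <-> index maps.

The canonical alphabet is the 20 proteinogenic one-letter codes in
alphabetical order.  The ordering is part of every trained model artifact:
one-hot column *j* always refers to ``alphabet.letters[j]``, so an artifact
carries its alphabet string and refuses to score peptides under a different
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: One-letter codes that are IUPAC-legal in some context but not canonical
#: residues (ambiguity codes, Sec/Pyl, stop).  Always rejected for design.
NON_CANONICAL = set("BJOUXZ*")


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet.

    Parameters
    ----------
    letters : str
        Distinct uppercase letters; the canonical alphabet has exactly 20.
        Reduced alphabets (e.g. a 3-letter toy alphabet for exhaustive
        enumeration) are permitted for testing and benchmarking.
    """

    letters: str = CANONICAL_LETTERS
    _lut: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be distinct")
        if not self.letters.isupper():
            raise ValueError("alphabet letters must be uppercase")
        # byte -> index lookup table; 255 marks letters outside the alphabet
        lut = np.full(256, 255, dtype=np.uint8)
        for i, ch in enumerate(self.letters):
            lut[ord(ch)] = i
        object.__setattr__(self, "_lut", lut)

    def __len__(self) -> int:
        return len(self.letters)

    def index_of(self, letter: str) -> int:
        idx = self._lut[ord(letter)]
        if idx == 255:
            raise KeyError(f"letter {letter!r} not in alphabet")
        return int(idx)

    def __contains__(self, letter: str) -> bool:
        return len(letter) == 1 and self._lut[ord(letter)] != 255

    def to_indices(self, sequence: str) -> np.ndarray:
        """Encode a sequence as an index vector (uint8)."""
        raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        idx = self._lut[raw]
        if (idx == 255).any():
            pos = int(np.argmax(idx == 255))
            raise ValueError(
                f"letter {sequence[pos]!r} at position {pos + 1} not in alphabet"
            )
        return idx

    def to_sequence(self, indices: np.ndarray) -> str:
        return "".join(self.letters[int(i)] for i in indices)


CANONICAL = Alphabet(CANONICAL_LETTERS)
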