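"""Nucleotide sequence container.

Sequences are stored as uppercase strings over {A, C, G, T, N}.  ``N`` marks
a masked base: it scores zero against every profile column and never starts
or ends a local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGTN"
_CODE = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the {A,C,G,T,N} alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues.upper()
        bad = set(res) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains symbols outside ACGTN: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """Integer codes A=0, C=1, G=2, T=3, N=4 as an int8 array."""
        return np.frombuffer(
            self.residues.encode().translate(_TRANSLATE), dtype=np.int8
        ).copy()

    def subsequence(self, start: int, end: int, id: str | None = None) -> "NucleotideSequence":
        """Extract the 1-based inclusive slice [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(f"invalid slice [{start}, {end}] for length {len(self)}")
        return NucleotideSequence(id or f"{self.id}:{start}-{end}", self.residues[start - 1 : end])


_TRANSLATE = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))


def from_codes(codes: np.ndarray, id: str = "seq") -> NucleotideSequence:
    """Inverse of :attr:`NucleotideSequence.codes`."""
    return NucleotideSequence(id, "".join(ALPHABET[c] for c in codes))


def random_sequence(
    length: int,
    rng: np.random.Generator,
    composition: np.ndarray | None = None,
    id: str = "random",
) -> NucleotideSequence:
    """Draw an i.i.d. sequence; ``composition`` is (pA, pC, pG, pT), default uniform."""
    p = np.full(4, 0.25) if composition is None else np.asarray(composition, dtype=float)
    if p.shape != (4,) or np.any(p < 0):
        raise ValueError("composition must be 4 non-negative frequencies")
    p = p / p.sum()
    codes = rng.choice(4, size=length, p=p)
    return from_codes(codes.astype(np.int8), id=id)
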