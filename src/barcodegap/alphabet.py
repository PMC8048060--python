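"""IUPAC nucleotide alphabet helpers.

Residues are modelled as 4-bit masks over the base set {A, C, G, T}
(A=1, C=2, G=4, T=8).  Ambiguity codes are the bitwise OR of their base
sets; the gap character ``-`` carries the empty mask.  Masks make residue-set
union/intersection (the core of diagnostic-column detection) cheap numpy
bit-ops instead of Python set algebra.
"""

from __future__ import annotations

import numpy as np

GAP = "-"

#: IUPAC code -> set of concrete bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ALPHABET: frozenset[str] = frozenset(IUPAC_SETS) | {GAP}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: IUPAC code (or gap) -> 4-bit mask
CODE_TO_MASK: dict[str, int] = {GAP: 0}
for _code, _bases in IUPAC_SETS.items():
    CODE_TO_MASK[_code] = sum(_BASE_BIT[b] for b in _bases)

#: 4-bit mask -> minimal IUPAC code ('-' for the empty mask)
MASK_TO_CODE: dict[int, str] = {m: c for c, m in CODE_TO_MASK.items()}

BASES = "ACGT"

# Lookup table from ASCII byte to mask; 255 marks an illegal character.
_MASK_LUT = np.full(256, 255, dtype=np.uint8)
for _code, _mask in CODE_TO_MASK.items():
    _MASK_LUT[ord(_code)] = _mask

# Lookup table from ASCII byte to base index 0..3; 255 = missing (gap,
# ambiguity, anything non-ACGT).  This is the p-distance view of a residue.
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i


def encode_masks(row: str) -> np.ndarray:
    """Encode a sequence row as a uint8 array of IUPAC bit masks."""
    arr = _MASK_LUT[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        col = int(np.argmax(arr == 255))
        raise ValueError(f"illegal character {row[col]!r} at column {col + 1}")
    return arr


def encode_bases(row: str) -> np.ndarray:
    """Encode a row for distance work: 0..3 for A/C/G/T, 255 for missing."""
    return _BASE_LUT[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


def mask_to_set(mask: int) -> frozenset[str]:
    """Expand a bit mask back to its base set."""
    return frozenset(b for b, bit in _BASE_BIT.items() if mask & bit)
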