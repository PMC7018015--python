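"""Shared nucleotide-alphabet helpers.

Residues are handled as sets of possible bases: IUPAC ambiguity codes expand
to their base sets, 'N' to all four bases, and '-' (gap) to the empty set.
Bitmask encoding (A=1, C=2, G=4, T=8) lets whole alignments be compared with
vectorised numpy operations.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
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
    "?": frozenset("ACGT"),
    "-": frozenset(),
}

# two-base set -> ambiguity code, for building consensus sequences
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items() if k not in "U?N-"}
SET_TO_CODE[frozenset("ACGT")] = "N"

VALID_CHARS = frozenset(IUPAC_SETS) - {"?"}

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

# bitmask per character; 0 means unscorable (gap or fully missing)
CHAR_TO_MASK = np.zeros(256, dtype=np.uint8)
for _c, _s in IUPAC_SETS.items():
    _m = sum(_BITS[b] for b in _s)
    if _c == "N" or _c == "?":
        _m = 0  # N is unscorable for distance purposes
    CHAR_TO_MASK[ord(_c)] = _m
    CHAR_TO_MASK[ord(_c.lower())] = _m


def seq_to_masks(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 bitmask vector (0 = gap/missing)."""
    return CHAR_TO_MASK[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def expand(char: str) -> frozenset[str]:
    """Set of bases a residue may represent ('-' -> empty set)."""
    try:
        return IUPAC_SETS[char.upper()]
    except KeyError:
        raise ValueError(f"invalid residue {char!r}") from None


def consensus_char(a: str, b: str) -> str:
    """IUPAC consensus of two allele residues at one site.

    Identical residues pass through; two different bases give the ambiguity
    code; a gap paired with a base, or anything involving 'N', gives 'N';
    a gap in both alleles stays a gap.
    """
    a, b = a.upper(), b.upper()
    if a == b:
        return a
    if a == "N" or b == "N":
        return "N"
    if a == "-" or b == "-":
        return "N"  # gap/base conflict: conservative missing call
    union = frozenset(expand(a) | expand(b))
    return SET_TO_CODE.get(union, "N")


def canonical_bipartition(side, universe) -> frozenset:
    """Canonical form of a bipartition of `universe`: the side that does NOT
    contain the reference (first, in sorted order) taxon."""
    universe = frozenset(universe)
    side = frozenset(side)
    if not side or side == universe:
        raise ValueError("bipartition side must be a proper non-empty subset")
    if not side <= universe:
        raise ValueError(f"unknown taxa in bipartition: {sorted(side - universe)}")
    ref = min(universe)
    return universe - side if ref in side else side
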