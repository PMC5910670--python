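"""Domain types and notation for chemically modified siRNA strands.

The duplexes handled here follow the 21/23-mer GalNAc-siRNA architecture: a
21-nt sense (passenger) strand carrying a 3' triantennary GalNAc ligand and a
23-nt antisense (guide) strand with a two-nucleotide 3' overhang.  Every
ribose carries one of two 2' sugar modifications, 2'-O-methyl (OMe) or
2'-deoxy-2'-fluoro (F), and a subset of backbone linkages are
phosphorothioate (PS).  Positions are 1-based from the 5' end of each strand,
so "AS2" is the second nucleotide of the antisense strand and "S11" the
eleventh of the sense strand.

Notation dialect
----------------
Strands are written in a compact shorthand common for modified
oligonucleotides:

* lowercase ``a c g u``  — 2'-OMe residue of that base
* ``Af Cf Gf Uf``        — 2'-F residue of that base
* ``s``                  — PS linkage between the flanking residues
* trailing ``-L96``      — triantennary GalNAc ligand on the 3' end

``"usAfsgc"`` is therefore a 4-mer u/A/g/c with 2'-F at position 2 and PS
linkages after residues 1 and 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ModifiedStrand",
    "Duplex",
    "ChemistryPattern",
    "NotationError",
    "parse_strand_notation",
    "write_strand_notation",
    "pattern_stats",
    "design_space_size",
    "SENSE_LENGTH",
    "ANTISENSE_LENGTH",
]

SENSE_LENGTH = 21
ANTISENSE_LENGTH = 23

_BASES = frozenset("ACGU")
_SUGARS = ("F", "OMe")

#: complementary RNA base pairs used for the (advisory) duplex check
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

GALNAC_TAG = "L96"


class NotationError(ValueError):
    """Raised when a strand notation string cannot be parsed."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (offset {offset})"
        super().__init__(message)


@dataclass(frozen=True)
class ModifiedStrand:
    """One strand: bases, per-position sugar chemistry, PS linkages.

    Parameters
    ----------
    bases : str
        Upper-case sequence over ``ACGU``, 5'→3'.
    sugar : tuple of {"F", "OMe"}
        Per-position 2' chemistry, same length as ``bases``.
    ps_after : frozenset of int
        1-based indices ``i`` with a PS linkage between residues ``i`` and
        ``i+1``; each must lie in ``[1, len-1]``.
    conjugate : str, optional
        Terminal ligand tag; ``"L96"`` denotes the 3' GalNAc ligand.
    """

    bases: str
    sugar: tuple
    ps_after: frozenset = field(default_factory=frozenset)
    conjugate: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "sugar", tuple(self.sugar))
        object.__setattr__(self, "ps_after", frozenset(self.ps_after))
        if len(self.sugar) != len(self.bases):
            raise ValueError(
                f"sugar vector length {len(self.sugar)} != sequence length {len(self.bases)}"
            )
        bad = set(self.bases) - _BASES
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)}; expected A/C/G/U")
        bad_sugar = set(self.sugar) - set(_SUGARS)
        if bad_sugar:
            raise ValueError(f"invalid sugar codes {sorted(bad_sugar)}; expected F/OMe")
        n = len(self.bases)
        for i in self.ps_after:
            if not (1 <= i <= n - 1):
                raise ValueError(f"PS linkage index {i} outside [1, {n - 1}]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_fluoro(self) -> int:
        return sum(1 for s in self.sugar if s == "F")

    @property
    def n_ome(self) -> int:
        return sum(1 for s in self.sugar if s == "OMe")

    def chem_string(self) -> str:
        """Compact chemistry string: ``F`` for 2'-F, ``M`` for 2'-OMe."""
        return "".join("F" if s == "F" else "M" for s in self.sugar)


@dataclass(frozen=True)
class Duplex:
    """A 21/23-mer siRNA duplex (21-nt sense, 23-nt antisense)."""

    duplex_id: str
    sense: ModifiedStrand
    antisense: ModifiedStrand

    def __post_init__(self):
        if len(self.sense) != SENSE_LENGTH:
            raise ValueError(f"sense strand must be {SENSE_LENGTH} nt, got {len(self.sense)}")
        if len(self.antisense) != ANTISENSE_LENGTH:
            raise ValueError(
                f"antisense strand must be {ANTISENSE_LENGTH} nt, got {len(self.antisense)}"
            )

    def check_complementarity(self) -> bool:
        """Advisory check that antisense 1–21 reverse-complements sense 1–21.

        Returns True when fully complementary; otherwise emits a warning and
        returns False.  A warning rather than an error because fixtures may
        carry placeholder bases when the underlying sequences are redacted.
        """
        mismatches = []
        for i in range(1, SENSE_LENGTH + 1):
            a = self.antisense.bases[i - 1]
            s = self.sense.bases[SENSE_LENGTH + 1 - i - 1]
            if _COMPLEMENT.get(s) != a:
                mismatches.append(i)
        if mismatches:
            warnings.warn(
                f"duplex {self.duplex_id}: antisense positions {mismatches} are not "
                "reverse-complementary to the sense strand",
                stacklevel=2,
            )
            return False
        return True

    def chemistry_pattern(self) -> "ChemistryPattern":
        return ChemistryPattern(self.sense.sugar, self.antisense.sugar)


@dataclass(frozen=True)
class ChemistryPattern:
    """Per-position sugar chemistry of a duplex, with base identity erased."""

    sense_chem: tuple
    antisense_chem: tuple

    def __post_init__(self):
        object.__setattr__(self, "sense_chem", tuple(self.sense_chem))
        object.__setattr__(self, "antisense_chem", tuple(self.antisense_chem))
        if len(self.sense_chem) != SENSE_LENGTH:
            raise ValueError(f"sense chemistry must have {SENSE_LENGTH} entries")
        if len(self.antisense_chem) != ANTISENSE_LENGTH:
            raise ValueError(f"antisense chemistry must have {ANTISENSE_LENGTH} entries")
        bad = (set(self.sense_chem) | set(self.antisense_chem)) - set(_SUGARS)
        if bad:
            raise ValueError(f"invalid sugar codes {sorted(bad)}")

    @classmethod
    def from_chem_strings(cls, sense: str, antisense: str) -> "ChemistryPattern":
        """Build from compact ``F``/``M`` strings (``M`` = 2'-OMe)."""
        decode = {"F": "F", "M": "OMe"}
        return cls(
            tuple(decode[c] for c in sense),
            tuple(decode[c] for c in antisense),
        )

    def chem_strings(self) -> tuple:
        enc = {"F": "F", "OMe": "M"}
        return (
            "".join(enc[c] for c in self.sense_chem),
            "".join(enc[c] for c in self.antisense_chem),
        )

    @property
    def n_fluoro(self) -> int:
        return sum(1 for c in self.sense_chem + self.antisense_chem if c == "F")


def parse_strand_notation(text: str) -> ModifiedStrand:
    """Parse a shorthand notation string into a :class:`ModifiedStrand`.

    See the module docstring for the dialect.  Offsets in error messages are
    1-based character positions in the input.
    """
    if not text:
        raise NotationError("empty notation string")
    conjugate = None
    body = text
    if body.endswith(f"-{GALNAC_TAG}"):
        conjugate = GALNAC_TAG
        body = body[: -len(GALNAC_TAG) - 1]
    if not body:
        raise NotationError("notation contains only a conjugate tag")

    bases = []
    sugar = []
    ps_after = set()
    i = 0
    prev_was_linkage = False
    while i < len(body):
        ch = body[i]
        offset = i + 1
        if ch == "s":
            if not bases:
                raise NotationError("PS linkage 's' before any residue", offset)
            if prev_was_linkage:
                raise NotationError("doubled PS linkage 's'", offset)
            ps_after.add(len(bases))
            prev_was_linkage = True
            i += 1
            continue
        if ch in "acgu":
            bases.append(ch.upper())
            sugar.append("OMe")
            prev_was_linkage = False
            i += 1
            continue
        if ch in "ACGU":
            if i + 1 < len(body) and body[i + 1] == "f":
                bases.append(ch)
                sugar.append("F")
                prev_was_linkage = False
                i += 2
                continue
            raise NotationError(f"uppercase residue {ch!r} must be followed by 'f'", offset)
        raise NotationError(f"unknown token {ch!r}", offset)
    if prev_was_linkage:
        raise NotationError("PS linkage 's' after the final residue", len(body))
    return ModifiedStrand("".join(bases), tuple(sugar), frozenset(ps_after), conjugate)


def write_strand_notation(strand: ModifiedStrand) -> str:
    """Inverse of :func:`parse_strand_notation` (exact round-trip)."""
    out = []
    for i, (b, s) in enumerate(zip(strand.bases, strand.sugar), start=1):
        out.append(b + "f" if s == "F" else b.lower())
        if i in strand.ps_after:
            out.append("s")
    if strand.conjugate is not None:
        out.append(f"-{strand.conjugate}")
    return "".join(out)


def pattern_stats(strand: ModifiedStrand) -> dict:
    """Counts of 2'-F, 2'-OMe residues and PS linkages for one strand."""
    return {
        "n_F": strand.n_fluoro,
        "n_OMe": strand.n_ome,
        "n_PS": len(strand.ps_after),
    }


def design_space_size(strand_length: int) -> int:
    """Number of two-chemistry (F/OMe) patterns on a strand of given length.

    Exact integer ``2**strand_length``; a 21-nt sense strand admits 2,097,152
    patterns and a 23-nt antisense strand 8,388,608.
    """
    if strand_length < 0:
        raise ValueError(f"strand length must be non-negative, got {strand_length}")
    return 2 ** int(strand_length)


def strand_from_pattern(
    bases: str,
    fluoro_positions: Iterable[int],
    ps_after: Iterable[int] = (),
    conjugate: Optional[str] = None,
) -> ModifiedStrand:
    """Build a strand from a base sequence and the set of 2'-F positions."""
    fluoro = set(fluoro_positions)
    n = len(bases)
    bad = [p for p in fluoro if not 1 <= p <= n]
    if bad:
        raise ValueError(f"2'-F positions {bad} outside strand of length {n}")
    sugar = tuple("F" if i in fluoro else "OMe" for i in range(1, n + 1))
    return ModifiedStrand(bases, sugar, frozenset(ps_after), conjugate)
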