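"""Reference modification patterns: parent (ESC) and advanced design variants.

The published figures depict the parent and design-variant (DV) modification
patterns only graphically, and the underlying sequences are not released in a
machine-readable form.  The patterns here are therefore *figure-derived
reconstructions*, pinned down by the printed aggregate facts:

* the parent antisense strand carries nine 2'-F residues, reduced to six
  (DV 7) and four (DV 6) by pairing 2'-F or 2'-OMe at AS8/AS9;
* critical 2'-F positions are AS2, AS6, AS14 and S11;
* the best sense design (shared by DV 18 and DV 22) carries four 2'-F;
* PS linkages sit after antisense residues 1, 2, 21, 22 and sense residues
  1, 2; the GalNAc ligand is on the sense 3' end.

Bases are SYNTHETIC placeholders (an arbitrary complementary 21/23-mer), not
any published sequence — only the chemistry patterns and their aggregate
counts are meaningful.
"""

from __future__ import annotations

from .strands import (
    ANTISENSE_LENGTH,
    SENSE_LENGTH,
    Duplex,
    GALNAC_TAG,
    strand_from_pattern,
)

__all__ = [
    "PARENT_SENSE_F",
    "PARENT_ANTISENSE_F",
    "DV18_SENSE_F",
    "DV18_ANTISENSE_F",
    "DV22_ANTISENSE_F",
    "SENSE_PS_AFTER",
    "ANTISENSE_PS_AFTER",
    "reference_designs",
]

# 2'-F position sets (1-based from the 5' end of each strand)
PARENT_SENSE_F = frozenset({1, 3, 5, 7, 9, 10, 11, 17, 19, 21})
PARENT_ANTISENSE_F = frozenset({2, 4, 6, 8, 9, 10, 14, 16, 20})  # nine 2'-F
DV18_SENSE_F = frozenset({7, 9, 10, 11})  # four 2'-F, shared by DV 22
DV18_ANTISENSE_F = frozenset({2, 6, 8, 9, 14, 16})  # 2'-F pair at AS8/AS9
DV22_ANTISENSE_F = frozenset({2, 6, 14, 16})  # 2'-OMe pair at AS8/AS9

# terminal PS protection of the 21/23-mer architecture
SENSE_PS_AFTER = frozenset({1, 2})
ANTISENSE_PS_AFTER = frozenset({1, 2, 21, 22})

# synthetic placeholder bases: arbitrary 21-mer and its reverse complement
# guide with a 3' UU overhang
_SENSE_BASES = "ACGUAGCUGAUCCGAAUGCUA"
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_ANTISENSE_BASES = "".join(_COMP[b] for b in reversed(_SENSE_BASES)) + "UU"

assert len(_SENSE_BASES) == SENSE_LENGTH
assert len(_ANTISENSE_BASES) == ANTISENSE_LENGTH


def _duplex(duplex_id: str, sense_f: frozenset, antisense_f: frozenset) -> Duplex:
    sense = strand_from_pattern(
        _SENSE_BASES, sense_f, SENSE_PS_AFTER, conjugate=GALNAC_TAG
    )
    antisense = strand_from_pattern(_ANTISENSE_BASES, antisense_f, ANTISENSE_PS_AFTER)
    return Duplex(duplex_id, sense, antisense)


def reference_designs() -> dict:
    """Figure-derived parent / DV18 / DV22 duplexes on synthetic bases.

    Returns a dict keyed by ``"parent"``, ``"DV18"``, ``"DV22"``.  Treat the
    chemistry patterns as best-effort reconstructions; only the aggregate
    counts documented above are asserted facts.
    """
    return {
        "parent": _duplex("parent", PARENT_SENSE_F, PARENT_ANTISENSE_F),
        "DV18": _duplex("DV18", DV18_SENSE_F, DV18_ANTISENSE_F),
        "DV22": _duplex("DV22", DV18_SENSE_F, DV22_ANTISENSE_F),
    }
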