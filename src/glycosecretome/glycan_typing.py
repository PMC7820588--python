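"""Glycan composition parsing and maturity-ordered glycan typing.

Intact glycopeptide searches report each glycan as a monosaccharide
composition string in the ``Residue(count)`` dialect used by mammalian
N-glycan databases, e.g. ``HexNAc(2)Hex(9)`` for the Man9 high-mannose
glycan or ``HexNAc(4)Hex(5)Fuc(1)NeuAc(2)`` for a biantennary sialylated
structure.  Every composition is assigned to exactly one of five glycan
types that track maturation through the ER and Golgi, from least to most
mature: high mannose, paucimannose, complex/hybrid, fucosylated, and
sialylated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "GlycanComposition",
    "GlycanType",
    "GlycanParseError",
    "parse_composition",
    "format_composition",
    "classify_glycan",
    "maturity_order",
    "MATURITY_RANK",
]

#: Canonical residue names recognised by the parser (case-sensitive).
CANONICAL_RESIDUES = ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc")

#: Glycan type labels from least to most mature.
_MATURITY_ORDER = (
    "high_mannose",
    "paucimannose",
    "complex_hybrid",
    "fucose",
    "sialic_acid",
)

#: label -> maturity rank (1 = least mature).
MATURITY_RANK: Mapping[str, int] = {
    label: rank for rank, label in enumerate(_MATURITY_ORDER, start=1)
}


class GlycanParseError(ValueError):
    """Raised when a composition string does not match the Residue(count) dialect."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one N-glycan composition.

    Residues outside the canonical five (HexNAc, Hex, Fuc, NeuAc, NeuGc)
    are carried in ``other`` and do not influence type classification.
    """

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0
    other: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, count in self._counts().items():
            if not isinstance(count, (int,)) or isinstance(count, bool):
                raise ValueError(f"count for {name!r} must be an integer, got {count!r}")
            if count < 0:
                raise ValueError(f"count for {name!r} must be non-negative, got {count}")
        if self.total() < 1:
            raise ValueError("composition must contain at least one residue")

    def _counts(self) -> dict[str, int]:
        counts = {
            "HexNAc": self.hexnac,
            "Hex": self.hex,
            "Fuc": self.fuc,
            "NeuAc": self.neuac,
            "NeuGc": self.neugc,
        }
        counts.update(self.other)
        return counts

    def total(self) -> int:
        """Total residue count, including non-canonical residues."""
        return sum(self._counts().values())


@dataclass(frozen=True)
class GlycanType:
    """One of the five maturity-ordered glycan types."""

    label: str
    maturity_rank: int

    def __post_init__(self) -> None:
        if self.label not in MATURITY_RANK:
            raise ValueError(f"unknown glycan type label {self.label!r}")
        if self.maturity_rank != MATURITY_RANK[self.label]:
            raise ValueError(
                f"maturity_rank {self.maturity_rank} inconsistent with label "
                f"{self.label!r} (expected {MATURITY_RANK[self.label]})"
            )


_TOKEN_RE = re.compile(r"([A-Za-z][A-Za-z0-9]*)\((\d+)\)")
_FIELD_BY_RESIDUE = {
    "HexNAc": "hexnac",
    "Hex": "hex",
    "Fuc": "fuc",
    "NeuAc": "neuac",
    "NeuGc": "neugc",
}


def parse_composition(text: str) -> GlycanComposition:
    """Parse a ``Residue(count)`` composition string.

    Residue names are case-sensitive; the canonical five map onto the
    named fields, anything else (e.g. ``Pent``, ``Sulfo``) goes into
    ``other``.  Counts must be positive integers without zero padding.

    Raises
    ------
    GlycanParseError
        On an empty string, a malformed token, a zero or zero-padded
        count, or a repeated residue name.
    """
    if not isinstance(text, str):
        raise GlycanParseError(f"composition must be a string, got {type(text).__name__}")
    if text == "":
        raise GlycanParseError("empty composition string")

    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise GlycanParseError(
                f"malformed token at position {pos}: {text[pos:pos + 20]!r}"
            )
        name, digits = match.group(1), match.group(2)
        if digits != str(int(digits)):
            raise GlycanParseError(f"zero-padded count in token {match.group(0)!r}")
        count = int(digits)
        if count < 1:
            raise GlycanParseError(f"count must be >= 1 in token {match.group(0)!r}")
        if name in counts:
            raise GlycanParseError(f"repeated residue {name!r}")
        counts[name] = count
        pos = match.end()

    kwargs = {field_name: counts.pop(residue, 0)
              for residue, field_name in _FIELD_BY_RESIDUE.items()}
    return GlycanComposition(other=dict(counts), **kwargs)


def format_composition(comp: GlycanComposition) -> str:
    """Render a composition back to the canonical ``Residue(count)`` dialect.

    Canonical residues are emitted in fixed order (HexNAc, Hex, Fuc, NeuAc,
    NeuGc), zero counts omitted, then ``other`` residues in sorted order;
    ``parse_composition(format_composition(c)) == c``.
    """
    parts = []
    for residue, field_name in _FIELD_BY_RESIDUE.items():
        count = getattr(comp, field_name)
        if count > 0:
            parts.append(f"{residue}({count})")
    for name in sorted(comp.other):
        count = comp.other[name]
        if count > 0:
            parts.append(f"{name}({count})")
    return "".join(parts)


def classify_glycan(comp: GlycanComposition) -> GlycanType:
    """Assign a composition to exactly one of the five glycan types.

    Precedence (highest first):

    1. sialic_acid — any NeuAc or NeuGc;
    2. fucose — any Fuc (and no sialic acid);
    3. complex_hybrid — more than 2 HexNAc;
    4. high_mannose — at most 2 HexNAc and >= 5 Hex (Man5 is counted as
       high mannose);
    5. paucimannose — at most 2 HexNAc and < 5 Hex.

    The five branches are exhaustive, so every valid composition receives
    exactly one label.
    """
    if comp.total() < 1:
        raise ValueError("cannot classify an empty composition")
    if comp.neuac + comp.neugc >= 1:
        label = "sialic_acid"
    elif comp.fuc >= 1:
        label = "fucose"
    elif comp.hexnac > 2:
        label = "complex_hybrid"
    elif comp.hex >= 5:
        label = "high_mannose"
    else:
        label = "paucimannose"
    return GlycanType(label=label, maturity_rank=MATURITY_RANK[label])


def maturity_order() -> list[str]:
    """The five glycan type labels from least to most mature."""
    return list(_MATURITY_ORDER)
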