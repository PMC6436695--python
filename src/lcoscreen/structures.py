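"""Lipochitooligosaccharide (LCO / Nod factor) structures.

An LCO is a short beta-1,4-linked chitin oligomer (GlcNAc backbone) whose
non-reducing terminal residue carries a fatty acyl chain in place of the
acetyl group, optionally decorated with an N-methyl group (non-reducing
terminus), a sulfate (reducing terminus), a carbamoyl group, an extra
hexose, or a de-N-acetylation at one backbone residue.

Structures are written in the compact nomenclature of Spaink (1992), e.g.
``V (C18:1, NMe, S)`` — Roman-numeral backbone length, acyl chain
carbons:unsaturations, then substituents.  ``-Hex`` attaches to the Roman
numeral (``IV-Hex (C18:1)``) and a trailing ``dNAc`` marks a deacetylated
residue whose position is carried separately (the printed tables encode it
in a footnote).

This module parses and serializes that nomenclature and derives elemental
formulas from fixed composition rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Optional, Tuple

__all__ = [
    "AcylChain",
    "ElementalFormula",
    "LCOStructure",
    "StructureParseError",
    "parse_structure",
    "format_structure",
    "elemental_formula",
    "GLCNAC",
    "WATER",
]


class StructureParseError(ValueError):
    """Raised when a nomenclature string or structure is malformed."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map with checked addition and subtraction."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for elem, n in self.counts.items():
            if not isinstance(n, int):
                raise ValueError(f"count for {elem} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {elem}: {n}")
            if n > 0:
                clean[elem] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C6H14O6``."""
        if text == "":
            return cls({})
        counts: Dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if m.start() != pos or m.group(0) == "":
                break
            elem, num = m.group(1), m.group(2)
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise StructureParseError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __getitem__(self, elem: str) -> int:
        return self.counts.get(elem, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            merged[elem] = merged.get(elem, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            new = merged.get(elem, 0) - n
            if new < 0:
                raise ValueError(
                    f"formula subtraction underflow on element {elem}: "
                    f"{merged.get(elem, 0)} - {n}"
                )
            merged[elem] = new
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("cannot multiply a formula by a negative integer")
        return ElementalFormula({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Hill notation: C, then H, then other elements alphabetically."""
        order = [e for e in ("C", "H") if e in self.counts]
        order += sorted(e for e in self.counts if e not in ("C", "H"))
        return "".join(f"{e}{self.counts[e] if self.counts[e] != 1 else ''}" for e in order)

    def __str__(self) -> str:
        return self.hill()


# Building blocks of the composition rules.
GLCNAC = ElementalFormula.parse("C8H15NO6")      # free N-acetyl-glucosamine
WATER = ElementalFormula.parse("H2O")
ACETYL = ElementalFormula.parse("C2H3O")         # the N-acetyl group displaced by the acyl
N_METHYL = ElementalFormula.parse("CH2")
SULFATE = ElementalFormula.parse("SO3")
CARBAMOYL = ElementalFormula.parse("CHNO")
HEXOSE = ElementalFormula.parse("C6H10O5")       # anhydro-hexose (glycosidically bound)
DEACETYL = ElementalFormula.parse("C2H2O")       # loss of ketene on de-N-acetylation
ANHYDRO_GLCNAC = GLCNAC - WATER                  # one backbone residue, C8H13NO5


@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl chain: ``carbons`` C atoms with ``unsaturations`` C=C bonds."""

    carbons: int
    unsaturations: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.unsaturations < 0:
            raise ValueError("unsaturation count must be non-negative")
        if self.hydrogens < 0:
            raise ValueError(
                f"C{self.carbons}:{self.unsaturations} has a negative hydrogen count"
            )

    @property
    def hydrogens(self) -> int:
        # acyl group C_c H_{2c-1-2u} O: one H per saturated carbon pair minus
        # the carbonyl, two fewer per double bond
        return 2 * self.carbons - 1 - 2 * self.unsaturations

    @property
    def formula(self) -> ElementalFormula:
        return ElementalFormula({"C": self.carbons, "H": self.hydrogens, "O": 1})

    def __str__(self) -> str:
        return f"C{self.carbons}:{self.unsaturations}"


@dataclass(frozen=True)
class LCOStructure:
    """One Nod factor: backbone length, acyl chain and substituent flags.

    ``deacetylated_residue`` counts from the non-reducing (acylated)
    terminus, residue 1 being the acylated residue itself; a value is
    required iff the structure is deacetylated.  The acylated residue cannot
    be the deacetylated one (it carries the acyl chain, not an acetyl).
    """

    backbone_n: int
    acyl: AcylChain
    n_methyl: bool = False
    sulfate: bool = False
    carbamoyl: bool = False
    hexose: bool = False
    deacetylated_residue: Optional[int] = None

    def __post_init__(self) -> None:
        if self.backbone_n < 2:
            raise ValueError(f"backbone needs >= 2 GlcNAc residues, got {self.backbone_n}")
        r = self.deacetylated_residue
        if r is not None:
            if not 1 <= r <= self.backbone_n:
                raise ValueError(
                    f"deacetylated residue {r} outside backbone 1..{self.backbone_n}"
                )
            if r == 1:
                raise StructureParseError(
                    "residue 1 is the acylated non-reducing terminus and carries "
                    "no acetyl group; it cannot be deacetylated"
                )

    @property
    def name(self) -> str:
        return format_structure(self)

    @property
    def identifier(self) -> str:
        """Unique label; disambiguates positional dNAc isomers that share a name."""
        if self.deacetylated_residue is None:
            return self.name
        return f"{self.name}@{self.deacetylated_residue}"

    def __str__(self) -> str:
        return self.identifier


_ROMAN = {"II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7, "VIII": 8, "IX": 9, "X": 10}
_ROMAN_INV = {v: k for k, v in _ROMAN.items()}

_NAME_RE = re.compile(
    r"""^\s*
    (?P<roman>[IVX]+)
    (?P<hex>-Hex)?
    \s*\(\s*
    C(?P<carbons>\d+):(?P<unsat>\d+)
    (?P<subs>(?:\s*,\s*[A-Za-z]+)*)
    \s*\)\s*
    (?P<dnac>dNAc)?
    \s*$""",
    re.VERBOSE,
)

_SUBSTITUENTS = {"NMe": "n_methyl", "Cb": "carbamoyl", "S": "sulfate"}


def parse_structure(text: str, deacetyl_position: Optional[int] = None) -> LCOStructure:
    """Parse a Spaink-nomenclature name into an :class:`LCOStructure`.

    Parameters
    ----------
    text:
        Name such as ``"V (C18:1, NMe, S)"`` or ``"IV-Hex (C18:1)"``; a
        trailing ``dNAc`` marks deacetylation.
    deacetyl_position:
        Residue index of the deacetylated residue, counted from the
        non-reducing terminus.  Must be given iff the name carries ``dNAc``.
    """
    m = _NAME_RE.match(text)
    if m is None:
        raise StructureParseError(f"cannot parse structure name {text!r}")
    roman = m.group("roman")
    if roman not in _ROMAN:
        raise StructureParseError(f"malformed Roman numeral {roman!r} in {text!r}")
    flags = {"n_methyl": False, "carbamoyl": False, "sulfate": False}
    subs = m.group("subs")
    for token in (t.strip() for t in subs.split(",") if t.strip()):
        if token not in _SUBSTITUENTS:
            raise StructureParseError(f"unknown substituent token {token!r} in {text!r}")
        attr = _SUBSTITUENTS[token]
        if flags[attr]:
            raise StructureParseError(f"duplicate substituent token {token!r} in {text!r}")
        flags[attr] = True
    has_dnac = m.group("dnac") is not None
    if has_dnac and deacetyl_position is None:
        raise StructureParseError(f"{text!r} carries dNAc but no deacetyl position was given")
    if not has_dnac and deacetyl_position is not None:
        raise StructureParseError(
            f"deacetyl position given but {text!r} carries no dNAc token"
        )
    return LCOStructure(
        backbone_n=_ROMAN[roman],
        acyl=AcylChain(int(m.group("carbons")), int(m.group("unsat"))),
        hexose=m.group("hex") is not None,
        deacetylated_residue=deacetyl_position,
        **flags,
    )


def format_structure(s: LCOStructure) -> str:
    """Serialize to the canonical name (substituent order NMe, Cb, S)."""
    head = _ROMAN_INV[s.backbone_n]
    if s.hexose:
        head += "-Hex"
    parts = [str(s.acyl)]
    if s.n_methyl:
        parts.append("NMe")
    if s.carbamoyl:
        parts.append("Cb")
    if s.sulfate:
        parts.append("S")
    name = f"{head} ({', '.join(parts)})"
    if s.deacetylated_residue is not None:
        name += " dNAc"
    return name


def elemental_formula(s: LCOStructure) -> ElementalFormula:
    """Elemental formula of a structure from the composition rules.

    The backbone is the chito-oligosaccharide ``n x GlcNAc - (n-1) x H2O``;
    acylation exchanges the non-reducing terminal N-acetyl for the fatty
    acyl group; substituents add NMe +CH2, S +SO3, Cb +CHNO, Hex +C6H10O5;
    deacetylation removes C2H2O regardless of position (positional isomers
    share a formula by construction).
    """
    f = s.backbone_n * GLCNAC - (s.backbone_n - 1) * WATER
    f = f - ACETYL + s.acyl.formula
    if s.n_methyl:
        f = f + N_METHYL
    if s.sulfate:
        f = f + SULFATE
    if s.carbamoyl:
        f = f + CARBAMOYL
    if s.hexose:
        f = f + HEXOSE
    if s.deacetylated_residue is not None:
        f = f - DEACETYL
    return f


def with_flags(s: LCOStructure, **changes) -> LCOStructure:
    """Convenience: a copy of ``s`` with the given fields replaced."""
    return replace(s, **changes)
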