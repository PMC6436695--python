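"""Formula-level mass calculus for LCO screening.

Monoisotopic and average masses, adduct m/z, ppm error, nominal-mass
isotope envelopes with a cosine pattern score, and B/Y glycosidic fragment
ions.  Isotope masses and abundances come from the NIST table shipped with
pyteomics; average atomic weights are the abundance-weighted means of that
same table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from pyteomics import mass as _ptmass

from .structures import (
    ACETYL,
    CARBAMOYL,
    DEACETYL,
    GLCNAC,
    HEXOSE,
    N_METHYL,
    SULFATE,
    WATER,
    ElementalFormula,
    LCOStructure,
)

__all__ = [
    "PROTON_MASS",
    "AdductSpec",
    "M_PLUS_H",
    "M_PLUS_NA",
    "DEFAULT_ADDUCTS",
    "IsotopePattern",
    "FragmentIon",
    "monoisotopic_mass",
    "average_mass",
    "adduct_mz",
    "ppm_error",
    "isotope_pattern",
    "isotope_score",
    "fragment_ions",
]

PROTON_MASS = 1.007276466
ELECTRON_MASS = 0.000548580


def _isotopes(element: str) -> List[Tuple[float, float]]:
    """(mass, abundance) pairs for one element, most abundant table, no zeros."""
    try:
        table = _ptmass.nist_mass[element]
    except KeyError:
        raise KeyError(f"no isotope data for element {element!r}") from None
    pairs = [(m, ab) for key, (m, ab) in table.items() if key != 0 and ab > 0]
    if not pairs:
        raise KeyError(f"element {element!r} has no natural isotope abundances")
    return sorted(pairs)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of count x lightest-natural-isotope mass, in Da."""
    return sum(n * _isotopes(e)[0][0] for e, n in f)


def average_mass(f: ElementalFormula) -> float:
    """Sum of count x abundance-weighted atomic weight, in Da."""
    total = 0.0
    for e, n in f:
        iso = _isotopes(e)
        weight = sum(m * ab for m, ab in iso) / sum(ab for _, ab in iso)
        total += n * weight
    return total


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: observed m/z = (M + delta) / charge."""

    name: str
    delta: float
    charge: int = 1
    element: str | None = None  # element added to the formula for envelope purposes

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")
        if not math.isfinite(self.delta):
            raise ValueError("adduct mass delta must be finite")


M_PLUS_H = AdductSpec("M+H", PROTON_MASS, 1, element="H")
M_PLUS_NA = AdductSpec("M+Na", 22.9897692809 - ELECTRON_MASS, 1, element="Na")
DEFAULT_ADDUCTS: Tuple[AdductSpec, ...] = (M_PLUS_H, M_PLUS_NA)


def adduct_mz(f: ElementalFormula, a: AdductSpec) -> float:
    return (monoisotopic_mass(f) + a.delta) / a.charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class IsotopePattern:
    """Nominal-mass isotope envelope: (integer Da offset, relative abundance)."""

    peaks: Tuple[Tuple[int, float], ...]

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.peaks]
        if offsets != sorted(set(offsets)):
            raise ValueError("isotope pattern offsets must be strictly increasing")
        if any(a < 0 for _, a in self.peaks):
            raise ValueError("isotope abundances must be non-negative")
        total = sum(a for _, a in self.peaks)
        if self.peaks and abs(total - 1.0) > 1e-9:
            raise ValueError(f"isotope abundances must sum to 1, got {total}")

    @property
    def offsets(self) -> Tuple[int, ...]:
        return tuple(o for o, _ in self.peaks)

    @property
    def abundances(self) -> Tuple[float, ...]:
        return tuple(a for _, a in self.peaks)

    @classmethod
    def from_abundances(cls, abundances: Sequence[float],
                        offsets: Sequence[int] | None = None) -> "IsotopePattern":
        """Build a normalized pattern from raw abundances (offsets default 0,1,2...)."""
        ab = np.asarray(abundances, dtype=float)
        if offsets is None:
            offsets = range(len(ab))
        total = ab.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero envelope")
        ab = ab / total
        return cls(tuple((int(o), float(a)) for o, a in zip(offsets, ab)))


def _element_nominal_dist(element: str) -> np.ndarray:
    """Abundance vector over neutron-count offsets (0, 1, 2, ...) for one atom."""
    iso = _isotopes(element)
    base = iso[0][0]
    max_off = int(round(iso[-1][0] - base))
    vec = np.zeros(max_off + 1)
    for m, ab in iso:
        vec[int(round(m - base))] += ab
    return vec / vec.sum()


def _conv_power(vec: np.ndarray, n: int, cap: int) -> np.ndarray:
    """vec convolved with itself n times, truncated to length cap."""
    result = np.zeros(cap)
    result[0] = 1.0
    base = vec[:cap].copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:cap]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:cap]
    return result


def isotope_pattern(f: ElementalFormula, n_peaks: int = 4) -> IsotopePattern:
    """Aggregated nominal-mass isotopologue distribution.

    Per-element multinomial distributions over neutron-count offsets are
    convolved (exact within floating point), truncated to ``n_peaks`` and
    renormalized.  Fine isotope structure within one nominal mass is
    deliberately merged — sufficient at orbitrap resolutions for envelope
    scoring.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if not f:
        return IsotopePattern(((0, 1.0),))
    dist = np.array([1.0])
    for elem, count in f:
        evec = _element_nominal_dist(elem)
        dist = np.convolve(dist, _conv_power(evec, count, n_peaks))[:n_peaks]
    return IsotopePattern.from_abundances(dist)


def isotope_score(theoretical: IsotopePattern, observed: IsotopePattern) -> float:
    """Cosine similarity of nominal-offset-aligned envelopes, in percent.

    Peaks present in one pattern but absent in the other count as zeros, so
    disjoint envelopes score 0 and proportional envelopes score 100.
    """
    if not theoretical.peaks or not observed.peaks:
        raise ValueError("cannot score an empty isotope pattern")
    offsets = sorted(set(theoretical.offsets) | set(observed.offsets))
    t = np.array([dict(theoretical.peaks).get(o, 0.0) for o in offsets])
    o = np.array([dict(observed.peaks).get(o, 0.0) for o in offsets])
    denom = np.linalg.norm(t) * np.linalg.norm(o)
    if denom == 0:
        return 0.0
    cos = float(np.dot(t, o) / denom)
    return 100.0 * min(max(cos, 0.0), 1.0)


@dataclass(frozen=True)
class FragmentIon:
    """A glycosidic B or Y fragment ion of a singly charged LCO precursor."""

    series: str           # "B" (non-reducing, oxocarbenium) or "Y" (reducing)
    index: int            # number of backbone residues retained, 1..n-1
    mz: float
    cleavage_site: int    # glycosidic bond index from the non-reducing end, 1..n-1
    formula: ElementalFormula  # neutral (hydrolyzed) fragment formula


def _fragment_neutral_formulas(s: LCOStructure, i: int) -> Tuple[ElementalFormula, ElementalFormula]:
    """Neutral hydrolysis products of cleaving glycosidic bond ``i``.

    Bond ``i`` separates residues 1..i (non-reducing side, carries the acyl
    chain, NMe and Cb) from residues i+1..n (reducing side, carries S and
    Hex).  The deacetylation travels with whichever side holds its residue.
    The two neutral formulas sum to M + H2O.
    """
    n = s.backbone_n
    b = i * GLCNAC - (i - 1) * WATER
    b = b - ACETYL + s.acyl.formula
    y = (n - i) * GLCNAC - (n - i - 1) * WATER
    if s.n_methyl:
        b = b + N_METHYL
    if s.carbamoyl:
        b = b + CARBAMOYL
    if s.sulfate:
        y = y + SULFATE
    if s.hexose:
        y = y + HEXOSE
    r = s.deacetylated_residue
    if r is not None:
        if r <= i:
            b = b - DEACETYL
        else:
            y = y - DEACETYL
    return b, y


def fragment_ions(s: LCOStructure, adduct: AdductSpec = M_PLUS_H) -> List[FragmentIon]:
    """B and Y glycosidic fragment ions for every backbone cleavage site.

    B ions are the non-reducing oxocarbenium fragments (neutral mass − H2O
    + charge carrier); Y ions are the reducing fragments (neutral mass +
    charge carrier).  Complementary pairs obey
    ``m(B_i) + m(Y_{n-i}) = M + 2 x delta``.
    """
    if adduct.charge != 1:
        raise ValueError(
            f"fragment prediction supports singly charged adducts only, "
            f"got charge {adduct.charge}"
        )
    water_mass = monoisotopic_mass(WATER)
    ions: List[FragmentIon] = []
    for i in range(1, s.backbone_n):
        b_neutral, y_neutral = _fragment_neutral_formulas(s, i)
        ions.append(FragmentIon(
            "B", i, monoisotopic_mass(b_neutral) - water_mass + adduct.delta, i, b_neutral))
        ions.append(FragmentIon(
            "Y", s.backbone_n - i, monoisotopic_mass(y_neutral) + adduct.delta, i, y_neutral))
    return ions
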