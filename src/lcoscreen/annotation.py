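"""Precursor matching, hit evaluation and presence-matrix construction.

The identification contract mirrors targeted exact-mass screening of LCO
extracts: an observed precursor is matched to enumerated candidates within
a ppm tolerance (default 5), gated on an isotope-envelope cosine score
(default >= 80%) and, when an MS2 scan was acquired, on a minimum number of
matched B/Y glycosidic fragments.  Accepted hits are reported per isomer
group — candidates sharing an elemental formula are indistinguishable by
mass alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .candidates import CandidateDB, CandidateEntry, group_isomers
from .masscalc import (
    DEFAULT_ADDUCTS,
    AdductSpec,
    IsotopePattern,
    M_PLUS_H,
    fragment_ions,
    isotope_pattern,
    isotope_score,
    ppm_error,
)
from .structures import ElementalFormula, LCOStructure

__all__ = [
    "Peak",
    "PrecursorRecord",
    "SpectrumRun",
    "MatchParams",
    "ProvisionalHit",
    "AnnotationHit",
    "PresenceMatrix",
    "match_precursor",
    "evaluate_hit",
    "annotate_run",
    "build_presence_matrix",
    "compare_conditions",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class PrecursorRecord:
    """One selected precursor: its m/z, isotope envelope and optional MS2 scan."""

    mz: float
    intensity: float = 1.0
    envelope: Tuple[Peak, ...] = ()
    ms2: Optional[Tuple[Peak, ...]] = None

    def __post_init__(self) -> None:
        env = tuple(self.envelope)
        if any(env[i].mz >= env[i + 1].mz for i in range(len(env) - 1)):
            raise ValueError("isotope envelope must be sorted by m/z")
        object.__setattr__(self, "envelope", env)
        if self.ms2 is not None:
            object.__setattr__(self, "ms2", tuple(self.ms2))


@dataclass(frozen=True)
class SpectrumRun:
    """A labeled collection of precursor records for one sample/condition."""

    sample: str
    condition: str
    precursors: Tuple[PrecursorRecord, ...]

    def __post_init__(self) -> None:
        if not self.sample or not self.condition:
            raise ValueError("sample and condition labels must be nonempty")
        object.__setattr__(self, "precursors", tuple(self.precursors))


@dataclass(frozen=True)
class MatchParams:
    """Identification gates.

    ``min_fragments`` applies only when a precursor has an MS2 scan; spectra
    without MS2 are judged on precursor mass and isotope score alone.
    """

    tolerance_ppm: float = 5.0
    min_isotope_score: float = 80.0
    adducts: Tuple[AdductSpec, ...] = DEFAULT_ADDUCTS
    min_fragments: int = 1
    fragment_tolerance_ppm: float = 10.0
    envelope_peaks: int = 4

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("ppm tolerance must be positive")
        if not 0 <= self.min_isotope_score <= 100:
            raise ValueError("minimum isotope score must lie in [0, 100]")


@dataclass(frozen=True)
class ProvisionalHit:
    precursor_index: int
    candidate_index: int
    adduct: AdductSpec
    theoretical_mz: float
    observed_mz: float
    ppm: float


@dataclass(frozen=True)
class AnnotationHit:
    """An evaluated identification, reported at isomer-group granularity."""

    group_key: str                       # Hill formula string of the isomer group
    structures: Tuple[LCOStructure, ...]  # all group members in the database
    adduct: str
    theoretical_mz: float
    observed_mz: float
    ppm: float
    isotope_score: float
    matched_fragments: Optional[int]     # None when no MS2 scan was acquired
    accepted: bool
    precursor_index: int = -1

    @property
    def best_name(self) -> str:
        return min(s.identifier for s in self.structures)


def match_precursor(run: SpectrumRun, db: CandidateDB,
                    p: MatchParams = MatchParams()) -> List[ProvisionalHit]:
    """All (precursor, candidate, adduct) pairs within the ppm tolerance.

    Candidates are located through the database's sorted-m/z index (binary
    search window per adduct), equivalent to — but much cheaper than — an
    all-pairs scan.
    """
    if len(db) == 0:
        raise ValueError("candidate database is empty")
    tol = p.tolerance_ppm * 1e-6
    hits: List[ProvisionalHit] = []
    for pi, prec in enumerate(run.precursors):
        for adduct in p.adducts:
            if adduct.name not in db.adduct_names():
                continue
            lo = prec.mz / (1.0 + tol)
            hi = prec.mz / (1.0 - tol)
            for ci in db.window(adduct.name, lo, hi):
                theo = db.entries[int(ci)].adduct_mz[adduct.name]
                err = ppm_error(prec.mz, theo)
                if abs(err) <= p.tolerance_ppm:
                    hits.append(ProvisionalHit(pi, int(ci), adduct, theo, prec.mz, err))
    return hits


def _observed_pattern(prec: PrecursorRecord) -> Optional[IsotopePattern]:
    if not prec.envelope:
        return None
    offsets = [int(round(pk.mz - prec.envelope[0].mz)) for pk in prec.envelope]
    # collapse duplicate nominal offsets (can arise from noisy envelopes)
    agg: Dict[int, float] = {}
    for o, pk in zip(offsets, prec.envelope):
        agg[o] = agg.get(o, 0.0) + pk.intensity
    items = sorted(agg.items())
    total = sum(v for _, v in items)
    if total <= 0:
        return None
    return IsotopePattern(tuple((o, v / total) for o, v in items))


def _ion_formula(f: ElementalFormula, adduct: AdductSpec) -> ElementalFormula:
    if adduct.element is None:
        return f
    return f + ElementalFormula({adduct.element: adduct.charge})


def evaluate_hit(hit: ProvisionalHit, run: SpectrumRun, db: CandidateDB,
                 p: MatchParams = MatchParams(),
                 groups: Optional[Mapping[str, List[CandidateEntry]]] = None) -> AnnotationHit:
    """Score a provisional hit and apply the acceptance gates."""
    prec = run.precursors[hit.precursor_index]
    entry = db.entries[hit.candidate_index]
    if groups is None:
        groups = group_isomers(db)
    key = entry.formula.hill()
    members = tuple(e.structure for e in groups[key])

    theo_pattern = isotope_pattern(_ion_formula(entry.formula, hit.adduct),
                                   n_peaks=p.envelope_peaks)
    obs_pattern = _observed_pattern(prec)
    if obs_pattern is None:
        score = 0.0
    else:
        score = isotope_score(theo_pattern, obs_pattern)

    matched: Optional[int] = None
    if prec.ms2 is not None:
        theo_frags = fragment_ions(entry.structure, M_PLUS_H)
        ftol = p.fragment_tolerance_ppm
        matched = 0
        for ion in theo_frags:
            if any(abs(ppm_error(pk.mz, ion.mz)) <= ftol for pk in prec.ms2):
                matched += 1

    accepted = (
        abs(hit.ppm) <= p.tolerance_ppm
        and score >= p.min_isotope_score
        and (matched is None or matched >= p.min_fragments)
    )
    return AnnotationHit(
        group_key=key,
        structures=members,
        adduct=hit.adduct.name,
        theoretical_mz=hit.theoretical_mz,
        observed_mz=hit.observed_mz,
        ppm=hit.ppm,
        isotope_score=score,
        matched_fragments=matched,
        accepted=accepted,
        precursor_index=hit.precursor_index,
    )


def annotate_run(run: SpectrumRun, db: CandidateDB,
                 p: MatchParams = MatchParams()) -> List[AnnotationHit]:
    """Accepted identifications, one per isomer group.

    Multiple precursors or adducts hitting one formula group collapse to the
    single best hit: minimal |ppm|, ties broken by higher isotope score,
    then lexicographically smallest candidate name.
    """
    groups = group_isomers(db)
    best: Dict[str, AnnotationHit] = {}
    for prov in match_precursor(run, db, p):
        hit = evaluate_hit(prov, run, db, p, groups)
        if not hit.accepted:
            continue
        prev = best.get(hit.group_key)
        if prev is None or _hit_rank(hit) < _hit_rank(prev):
            best[hit.group_key] = hit
    return sorted(best.values(), key=lambda h: h.best_name)


def _hit_rank(h: AnnotationHit) -> Tuple[float, float, str]:
    return (abs(h.ppm), -h.isotope_score, h.best_name)


@dataclass
class PresenceMatrix:
    """Boolean detection table: inventory structures x conditions."""

    table: pd.DataFrame                  # bool, index = structure identifiers
    mode: str                            # "provenance-aware" or "mass-only"
    provenance: Dict[Tuple[str, str], AnnotationHit] = field(default_factory=dict)

    def column_totals(self) -> Dict[str, int]:
        return {c: int(self.table[c].sum()) for c in self.table.columns}

    def detected(self, condition: str) -> List[str]:
        col = self.table[condition]
        return [str(i) for i in col.index[col]]


def build_presence_matrix(
    annotations: Mapping[str, Sequence[AnnotationHit]],
    inventory: Sequence[LCOStructure],
    planted: Optional[Mapping[str, Set[str]]] = None,
) -> PresenceMatrix:
    """Per-condition detection matrix over the structure inventory.

    ``annotations`` maps condition label -> accepted hits (union over the
    condition's runs).  In mass-only mode (``planted`` is None) a hit marks
    every inventory member of its isomer group; in provenance-aware mode a
    generator ground-truth mapping (condition -> planted identifiers)
    restricts the marking to group members that were actually planted —
    positional isomers are otherwise indistinguishable.
    """
    conditions = list(annotations.keys())
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition labels must be distinct")
    idx = [s.identifier for s in inventory]
    if len(set(idx)) != len(idx):
        raise ValueError("inventory identifiers must be unique")
    by_formula: Dict[str, List[LCOStructure]] = {}
    from .structures import elemental_formula
    for s in inventory:
        by_formula.setdefault(elemental_formula(s).hill(), []).append(s)

    table = pd.DataFrame(False, index=idx, columns=conditions)
    provenance: Dict[Tuple[str, str], AnnotationHit] = {}
    mode = "mass-only" if planted is None else "provenance-aware"
    for cond, hits in annotations.items():
        for hit in hits:
            if not hit.accepted:
                raise ValueError("presence matrix requires accepted hits only")
            for s in by_formula.get(hit.group_key, ()):
                if planted is not None and s.identifier not in planted.get(cond, set()):
                    continue
                table.loc[s.identifier, cond] = True
                cell = (s.identifier, cond)
                prev = provenance.get(cell)
                if prev is None or _hit_rank(hit) < _hit_rank(prev):
                    provenance[cell] = hit
    return PresenceMatrix(table=table, mode=mode, provenance=provenance)


def compare_conditions(m: PresenceMatrix,
                       flags: Optional[Mapping[str, bool]] = None) -> Dict[str, object]:
    """Column totals, pairwise intersections, and external-flag overlaps.

    ``flags`` maps structure identifier -> bool (e.g. "also detected under
    salt stress"); the overlap is the count of detected structures carrying
    the flag, per condition.
    """
    totals = m.column_totals()
    conds = list(m.table.columns)
    intersections = {
        (a, b): int((m.table[a] & m.table[b]).sum())
        for i, a in enumerate(conds) for b in conds[i:]
    }
    summary: Dict[str, object] = {"totals": totals, "intersections": intersections}
    if flags is not None:
        fvec = pd.Series({i: bool(flags.get(str(i), False)) for i in m.table.index})
        summary["flag_overlap"] = {
            c: int((m.table[c] & fvec).sum()) for c in conds
        }
    return summary
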