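"""Combinatorial LCO candidate database.

Targeted screening matches observed precursor masses against an enumerated
set of plausible LCO structures.  The enumeration is configuration-driven:
backbone lengths, acyl chains, allowed substituent combinations, optional
deacetylation positions and exclusion constraints.  The shipped default
covers every structure printed in the source inventory without claiming to
reproduce any particular published database size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .masscalc import DEFAULT_ADDUCTS, AdductSpec, adduct_mz, monoisotopic_mass
from .structures import AcylChain, ElementalFormula, LCOStructure, elemental_formula

__all__ = [
    "EnumerationConfig",
    "CandidateEntry",
    "CandidateDB",
    "DEFAULT_CONFIG",
    "enumerate_candidates",
    "group_isomers",
]

_KNOWN_FLAGS = frozenset({"NMe", "S", "Cb", "Hex"})
_FLAG_ATTR = {"NMe": "n_methyl", "S": "sulfate", "Cb": "carbamoyl", "Hex": "hexose"}


@dataclass(frozen=True)
class EnumerationConfig:
    """Rules generating the candidate space.

    ``substituent_sets`` lists the allowed flag combinations explicitly (each
    a subset of {NMe, S, Cb, Hex}); ``exclusions`` removes any combination
    containing one of the listed flag sets.  ``dnac_positions`` maps backbone
    length -> allowed deacetylation residue indices (non-reducing numbering,
    residue 1 excluded because it is acylated); every structure is also
    emitted without deacetylation.
    """

    backbone_lengths: Tuple[int, ...]
    acyl_chains: Tuple[Tuple[int, int], ...]
    substituent_sets: Tuple[FrozenSet[str], ...]
    dnac_positions: Mapping[int, Tuple[int, ...]] = field(default_factory=dict)
    exclusions: Tuple[FrozenSet[str], ...] = ()

    def __post_init__(self) -> None:
        if not self.backbone_lengths:
            raise ValueError("backbone length set must be nonempty")
        if not self.acyl_chains:
            raise ValueError("acyl chain set must be nonempty")
        for combo in itertools.chain(self.substituent_sets, self.exclusions):
            unknown = set(combo) - _KNOWN_FLAGS
            if unknown:
                raise ValueError(f"unknown substituent flags {sorted(unknown)}")

    def allowed(self, combo: FrozenSet[str]) -> bool:
        return not any(excl <= combo for excl in self.exclusions)


def default_config() -> EnumerationConfig:
    """Shipped default: covers the full printed structure inventory.

    Backbones of 3-5 residues, the acyl chains observed for this strain,
    any substituent subset with sulfate and carbamoyl mutually exclusive,
    and deacetylation at internal residues of pentamers.
    """
    subsets = tuple(
        frozenset(c)
        for r in range(len(_KNOWN_FLAGS) + 1)
        for c in itertools.combinations(sorted(_KNOWN_FLAGS), r)
    )
    return EnumerationConfig(
        backbone_lengths=(3, 4, 5),
        acyl_chains=((14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (20, 0), (20, 1)),
        substituent_sets=subsets,
        dnac_positions={5: (2, 3, 4)},
        exclusions=(frozenset({"S", "Cb"}),),
    )


DEFAULT_CONFIG = default_config()


@dataclass(frozen=True)
class CandidateEntry:
    structure: LCOStructure
    formula: ElementalFormula
    monoisotopic: float
    adduct_mz: Mapping[str, float]


class CandidateDB:
    """Enumerated candidates with a sorted per-adduct m/z index."""

    def __init__(self, entries: Sequence[CandidateEntry],
                 adducts: Sequence[AdductSpec] = DEFAULT_ADDUCTS):
        self.entries: List[CandidateEntry] = list(entries)
        self.adducts: Tuple[AdductSpec, ...] = tuple(adducts)
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for a in self.adducts:
            mzs = np.array([e.adduct_mz[a.name] for e in self.entries])
            order = np.argsort(mzs)
            self._index[a.name] = (mzs[order], order)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def adduct_names(self) -> Tuple[str, ...]:
        return tuple(a.name for a in self.adducts)

    def sorted_mz(self, adduct_name: str) -> Tuple[np.ndarray, np.ndarray]:
        """(sorted m/z array, candidate indices in that order) for one adduct."""
        return self._index[adduct_name]

    def window(self, adduct_name: str, lo: float, hi: float) -> np.ndarray:
        """Candidate indices whose adduct m/z lies in [lo, hi] (binary search)."""
        mzs, order = self._index[adduct_name]
        i = int(np.searchsorted(mzs, lo, side="left"))
        j = int(np.searchsorted(mzs, hi, side="right"))
        return order[i:j]

    def find(self, structure: LCOStructure) -> Optional[CandidateEntry]:
        for e in self.entries:
            if e.structure == structure:
                return e
        return None

    def __contains__(self, structure: LCOStructure) -> bool:
        return self.find(structure) is not None


def enumerate_candidates(cfg: EnumerationConfig = DEFAULT_CONFIG,
                         adducts: Sequence[AdductSpec] = DEFAULT_ADDUCTS) -> CandidateDB:
    """Cartesian product of config options minus exclusions.

    Deterministic ordering: backbone length, acyl chain, substituent flags,
    deacetylation position (no-dNAc first).
    """
    entries: List[CandidateEntry] = []
    seen = set()
    for n in sorted(cfg.backbone_lengths):
        for (c, u) in sorted(cfg.acyl_chains):
            for combo in sorted(cfg.substituent_sets, key=lambda s: tuple(sorted(s))):
                if not cfg.allowed(combo):
                    continue
                flags = {attr: (flag in combo) for flag, attr in _FLAG_ATTR.items()}
                positions: List[Optional[int]] = [None]
                positions += [p for p in sorted(cfg.dnac_positions.get(n, ())) if p != 1]
                for pos in positions:
                    s = LCOStructure(backbone_n=n, acyl=AcylChain(c, u),
                                     deacetylated_residue=pos, **flags)
                    if s in seen:
                        continue
                    seen.add(s)
                    f = elemental_formula(s)
                    entries.append(CandidateEntry(
                        structure=s,
                        formula=f,
                        monoisotopic=monoisotopic_mass(f),
                        adduct_mz={a.name: adduct_mz(f, a) for a in adducts},
                    ))
    if not entries:
        import warnings
        warnings.warn("enumeration produced an empty candidate database", stacklevel=2)
    return CandidateDB(entries, adducts)


def group_isomers(db: CandidateDB) -> Dict[str, List[CandidateEntry]]:
    """Partition candidates by exact elemental formula (Hill string keys).

    Mass-only matching cannot separate candidates within one group (e.g.
    positional deacetylation isomers), so downstream annotation reports hits
    at group granularity.
    """
    groups: Dict[str, List[CandidateEntry]] = {}
    for e in db:
        groups.setdefault(e.formula.hill(), []).append(e)
    return groups
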