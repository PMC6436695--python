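"""Synthetic inputs with known ground truth.

Two generators: DDA-style (top-N) positive-mode LCO spectrum runs, and
differential-expression tables with planted effects.  Everything is driven
by a single seeded NumPy generator, so a run is reproducible byte-for-byte
from its seed.

The spectra emulate what a targeted screen of an LCO extract sees: per
planted structure one precursor at its [M+H]+ or [M+Na]+ m/z with a
relative mass error drawn uniformly within a configurable ppm window, the
theoretical isotope envelope optionally distorted multiplicatively
(log-normal), B/Y glycosidic fragments as the MS2 scan for precursors that
win a top-N slot in their acquisition cycle, decoy compounds built as
formula perturbations of real candidates kept at a minimum ppm distance
from every candidate, and uniform background noise precursors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import Peak, PrecursorRecord, SpectrumRun
from .candidates import CandidateDB, DEFAULT_CONFIG, enumerate_candidates
from .deg import bh_adjust
from .masscalc import (
    DEFAULT_ADDUCTS,
    AdductSpec,
    fragment_ions,
    isotope_pattern,
    M_PLUS_H,
    monoisotopic_mass,
    ppm_error,
)
from .structures import ElementalFormula, LCOStructure

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_run",
    "simulate_table3_runs",
    "simulate_deg_table",
    "C13_SPACING",
]

C13_SPACING = 1.0033548378  # Da between adjacent isotopologue peaks, charge 1


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the spectrum generator; defaults mirror the study conditions.

    ``jitter_ppm`` is the half-width of the uniform relative mass error
    (instrument accuracy well inside the 5 ppm matching tolerance);
    ``distortion`` is the sigma of the log-normal multiplicative envelope
    noise; ``n_decoys`` near-miss compounds are planted at least
    ``decoy_floor_ppm`` away from every candidate; noise precursors are
    Poisson with mean ``noise_rate``; each acquisition cycle holds
    ``cycle_width`` co-eluting precursors of which the ``top_n`` most
    intense receive an MS2 scan.
    """

    structures: Tuple[LCOStructure, ...] = ()
    sample: str = "synthetic"
    condition: str = "condition"
    adducts: Tuple[AdductSpec, ...] = DEFAULT_ADDUCTS
    adduct_weights: Tuple[float, ...] = (0.8, 0.2)
    jitter_ppm: float = 2.0
    distortion: float = 0.05
    n_decoys: int = 20
    decoy_floor_ppm: float = 20.0
    noise_rate: float = 10.0
    top_n: int = 5
    cycle_width: int = 8
    envelope_peaks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_ppm < 0:
            raise ValueError("jitter must be non-negative")
        if len(self.adduct_weights) != len(self.adducts):
            raise ValueError("one adduct weight per adduct required")
        if self.n_decoys < 0 or self.noise_rate < 0:
            raise ValueError("decoy and noise counts must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, keyed by structure identifier."""

    planted: Mapping[str, Tuple[str, float]]   # identifier -> (adduct name, true m/z)
    decoys: Tuple[Tuple[str, float], ...]      # (formula Hill string, m/z)
    seed: int

    @property
    def planted_identifiers(self) -> Set[str]:
        return set(self.planted)


def _jittered(rng: np.random.Generator, mz: float, ppm: float) -> float:
    return mz * (1.0 + rng.uniform(-ppm, ppm) * 1e-6)


def _envelope(rng: np.random.Generator, formula: ElementalFormula,
              adduct: AdductSpec, mz: float, intensity: float,
              params: SimulationParams) -> Tuple[Peak, ...]:
    ion = formula
    if adduct.element is not None:
        ion = formula + ElementalFormula({adduct.element: adduct.charge})
    pattern = isotope_pattern(ion, n_peaks=params.envelope_peaks)
    peaks = []
    for offset, ab in pattern.peaks:
        distorted = ab * math.exp(rng.normal(0.0, params.distortion)) if params.distortion else ab
        pk_mz = _jittered(rng, mz + offset * C13_SPACING / adduct.charge, params.jitter_ppm)
        peaks.append(Peak(pk_mz, intensity * distorted))
    return tuple(sorted(peaks, key=lambda p: p.mz))


def _make_decoys(rng: np.random.Generator, db: CandidateDB,
                 params: SimulationParams) -> List[Tuple[ElementalFormula, float]]:
    """Formula perturbations (+-CH2, +-O) kept >= the ppm floor from all candidates."""
    deltas = [ElementalFormula.parse("CH2"), ElementalFormula.parse("O")]
    all_mzs = np.sort(np.concatenate([
        db.sorted_mz(name)[0] for name in db.adduct_names()
    ]))
    decoys: List[Tuple[ElementalFormula, float]] = []
    attempts = 0
    max_attempts = 200 * max(params.n_decoys, 1)
    while len(decoys) < params.n_decoys:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "decoy construction failed: candidate space too dense for "
                f"a {params.decoy_floor_ppm} ppm exclusion floor"
            )
        base = db.entries[int(rng.integers(len(db)))].formula
        delta = deltas[int(rng.integers(len(deltas)))]
        try:
            formula = base + delta if rng.random() < 0.5 else base - delta
        except ValueError:
            continue
        mz = monoisotopic_mass(formula) + M_PLUS_H.delta
        i = int(np.searchsorted(all_mzs, mz))
        nearest = min(
            (abs(ppm_error(mz, float(all_mzs[j])))
             for j in (i - 1, i) if 0 <= j < len(all_mzs)),
            default=float("inf"),
        )
        if nearest >= params.decoy_floor_ppm:
            decoys.append((formula, mz))
    return decoys


def simulate_run(params: SimulationParams,
                 db: Optional[CandidateDB] = None) -> Tuple[SpectrumRun, GroundTruth]:
    """One DDA run: planted structures + decoys + noise, with ground truth."""
    rng = np.random.default_rng(params.seed)
    if db is None:
        db = enumerate_candidates(DEFAULT_CONFIG, params.adducts)

    weights = np.asarray(params.adduct_weights, dtype=float)
    weights = weights / weights.sum()

    records: List[Tuple[PrecursorRecord, float]] = []  # (record template, intensity)
    planted: Dict[str, Tuple[str, float]] = {}
    frag_cache: Dict[str, List[float]] = {}

    from .structures import elemental_formula
    for s in params.structures:
        adduct = params.adducts[int(rng.choice(len(params.adducts), p=weights))]
        formula = elemental_formula(s)
        true_mz = (monoisotopic_mass(formula) + adduct.delta) / adduct.charge
        obs_mz = _jittered(rng, true_mz, params.jitter_ppm)
        intensity = float(rng.lognormal(mean=12.0, sigma=1.0))
        envelope = _envelope(rng, formula, adduct, obs_mz, intensity, params)
        frag_cache[s.identifier] = [ion.mz for ion in fragment_ions(s, M_PLUS_H)]
        records.append((PrecursorRecord(obs_mz, intensity, envelope, ms2=None), intensity))
        planted[s.identifier] = (adduct.name, true_mz)

    decoy_truth: List[Tuple[str, float]] = []
    if params.n_decoys:
        for formula, mz in _make_decoys(rng, db, params):
            obs_mz = _jittered(rng, mz, params.jitter_ppm)
            intensity = float(rng.lognormal(mean=10.0, sigma=1.0))
            envelope = _envelope(rng, formula, M_PLUS_H, obs_mz, intensity, params)
            records.append((PrecursorRecord(obs_mz, intensity, envelope, ms2=None), intensity))
            decoy_truth.append((formula.hill(), mz))

    n_noise = int(rng.poisson(params.noise_rate))
    if records:
        mz_lo = 0.8 * min(r.mz for r, _ in records)
        mz_hi = 1.1 * max(r.mz for r, _ in records)
    else:
        mz_lo, mz_hi = 300.0, 1500.0
    for _ in range(n_noise):
        mz = float(rng.uniform(mz_lo, mz_hi))
        intensity = float(rng.lognormal(mean=8.0, sigma=1.0))
        records.append((PrecursorRecord(mz, intensity, (Peak(mz, intensity),), None), intensity))

    # elution order, then top-N MS2 selection per acquisition cycle
    order = rng.permutation(len(records))
    mz_to_identifier: Dict[float, str] = {}
    for (rec, _), s in zip(records[: len(params.structures)], params.structures):
        mz_to_identifier[rec.mz] = s.identifier

    final: List[PrecursorRecord] = []
    ordered = [records[i] for i in order]
    for start in range(0, len(ordered), params.cycle_width):
        cycle = ordered[start:start + params.cycle_width]
        ranked = sorted(range(len(cycle)), key=lambda k: -cycle[k][1])
        selected = set(ranked[: params.top_n])
        for k, (rec, _inten) in enumerate(cycle):
            ident = mz_to_identifier.get(rec.mz)
            if k in selected and ident is not None:
                ms2 = tuple(
                    Peak(_jittered(rng, fmz, params.jitter_ppm),
                         float(rng.lognormal(9.0, 1.0)))
                    for fmz in frag_cache[ident]
                )
                rec = replace(rec, ms2=tuple(sorted(ms2, key=lambda p: p.mz)))
            final.append(rec)

    run = SpectrumRun(sample=params.sample, condition=params.condition,
                      precursors=tuple(final))
    truth = GroundTruth(planted=planted, decoys=tuple(decoy_truth), seed=params.seed)
    return run, truth


# Condition labels of the four experimental columns: wild type and nodD2
# mutant, each grown with and without 400 mM mannitol.
TABLE3_CONDITIONS = (
    "ciat899_control",
    "ciat899_mannitol",
    "nodd2_control",
    "nodd2_mannitol",
)


def simulate_table3_runs(
    inventory: Sequence["InventoryRecord"],
    params: SimulationParams = SimulationParams(),
    db: Optional[CandidateDB] = None,
) -> Dict[str, Tuple[SpectrumRun, GroundTruth]]:
    """One run per detection column, planting exactly that column's structures.

    Per-condition seeds are derived deterministically from ``params.seed``.
    """
    out: Dict[str, Tuple[SpectrumRun, GroundTruth]] = {}
    for k, cond in enumerate(TABLE3_CONDITIONS):
        structures = tuple(rec.structure for rec in inventory if rec.detection[cond])
        p = replace(
            params,
            structures=structures,
            sample=f"{cond}_run",
            condition=cond,
            seed=(params.seed * 1_000_003 + k) % (2**31),
        )
        out[cond] = simulate_run(p, db=db)
    return out


# Per-replicon CDS counts of the CIAT 899 genome (chromosome + 3 plasmids).
REPLICON_CDS = {
    "CP004015.1": 3672,
    "CP004016.1": 212,
    "CP004017.1": 500,
    "CP004018.1": 1905,
}

# Planted differentially-expressed gene counts per replicon x direction.
# Chromosome, symbiotic plasmid pB and pC carry the documented counts; the
# remainder needed to reach 743 total / 461 up-regulated sits on pA.
DEFAULT_DEG_PLAN = {
    "CP004015.1": (333, 135),
    "CP004016.1": (43, 129),
    "CP004017.1": (66, 1),
    "CP004018.1": (19, 17),
}


def simulate_deg_table(
    n_genes: int = 6289,
    deg_plan: Mapping[str, Tuple[int, int]] = DEFAULT_DEG_PLAN,
    replicon_cds: Mapping[str, int] = REPLICON_CDS,
    fc_threshold: float = 2.5,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """A DE table with planted signed fold-changes and p-values.

    Null genes get expression ratios log-normal around 1 and uniform raw
    p-values; planted genes get |FC| drawn above ``fc_threshold`` (sign per
    the plan) and raw p-values far below any FDR cut.  A BH-adjusted column
    is included.  Returns (table, truth) where truth lists the planted gene
    ids and the per-replicon (up, down) counts.
    """
    if sum(replicon_cds.values()) != n_genes:
        raise ValueError("replicon CDS counts must sum to n_genes")
    for acc, (up, down) in deg_plan.items():
        if up + down > replicon_cds.get(acc, 0):
            raise ValueError(f"planted DEG exceed CDS count on {acc}")
    rng = np.random.default_rng(seed)

    rows = []
    truth_genes: List[str] = []
    gene_counter = 0
    for acc in sorted(replicon_cds):
        n_cds = replicon_cds[acc]
        up, down = deg_plan.get(acc, (0, 0))
        directions = ["up"] * up + ["down"] * down + [None] * (n_cds - up - down)
        rng.shuffle(directions)
        for d in directions:
            gene_counter += 1
            gene = f"YP_{7333000 + gene_counter}.1"
            if d is None:
                ratio = float(np.exp(rng.normal(0.0, 0.1)))
                fc = ratio if ratio >= 1 else -1.0 / ratio
                p = float(rng.uniform())
            else:
                magnitude = fc_threshold + float(rng.exponential(2.0))
                fc = magnitude if d == "up" else -magnitude
                p = float(rng.uniform(1e-12, 1e-7))
                truth_genes.append(gene)
            rows.append((gene, acc, fc, p))

    df = pd.DataFrame(rows, columns=["gene_id", "replicon", "fold_change", "pvalue"])
    df["padj"] = bh_adjust(df["pvalue"].tolist())
    truth = {
        "deg_genes": truth_genes,
        "per_replicon": {acc: tuple(v) for acc, v in deg_plan.items()},
        "n_deg": sum(u + d for u, d in deg_plan.values()),
        "seed": seed,
    }
    return df, truth
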