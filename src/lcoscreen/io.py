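"""Readers and writers binding the pipeline stages together.

Formats: the tab-separated structure inventory (shipped digitized fixture),
MGF and CSV peak lists for spectrum runs, TSV candidate databases and hit
tables, and JSON run summaries.  MGF goes through pyteomics; the isotope
envelope of each precursor travels in a custom ``ENVELOPE`` header so a
round trip is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from pyteomics import mgf as _mgf

from .annotation import AnnotationHit, Peak, PrecursorRecord, PresenceMatrix, SpectrumRun
from .candidates import CandidateDB, CandidateEntry
from .masscalc import DEFAULT_ADDUCTS, adduct_mz, monoisotopic_mass
from .structures import LCOStructure, elemental_formula, parse_structure

__all__ = [
    "InventoryRecord",
    "read_structure_inventory",
    "bundled_inventory_path",
    "write_run_mgf",
    "read_run_mgf",
    "write_run_csv",
    "read_run_csv",
    "write_candidate_db",
    "read_candidate_db",
    "write_hits",
    "write_presence_matrix",
    "write_summary",
]

log = logging.getLogger(__name__)

CONDITION_COLUMNS = (
    "ciat899_control",
    "ciat899_mannitol",
    "nodd2_control",
    "nodd2_mannitol",
)


@dataclass(frozen=True)
class InventoryRecord:
    """One inventory row: a structure, its detection flags, the salt flag."""

    structure: LCOStructure
    detection: Mapping[str, bool]
    also_salt: bool

    @property
    def identifier(self) -> str:
        return self.structure.identifier


def bundled_inventory_path() -> Path:
    """Path of the digitized structure-inventory fixture shipped in the package."""
    return Path(str(resources.files("lcoscreen").joinpath("data/table3_inventory.tsv")))


def read_structure_inventory(path: str | Path | None = None) -> List[InventoryRecord]:
    """Parse the tab-separated structure inventory.

    Schema: ``name``, ``dnac_position`` (empty or integer), four 0/1
    detection columns, ``also_salt`` (0/1).  Duplicate (name, position)
    pairs and schema violations are errors.
    """
    if path is None:
        path = bundled_inventory_path()
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    required = {"name", "dnac_position", "also_salt", *CONDITION_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"inventory file {path} lacks columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"inventory file {path} contains no structures")

    records: List[InventoryRecord] = []
    seen = set()
    for _, row in df.iterrows():
        pos = None if pd.isna(row["dnac_position"]) else int(row["dnac_position"])
        key = (row["name"], pos)
        if key in seen:
            raise ValueError(f"duplicate inventory entry: {row['name']!r} (dNAc {pos})")
        seen.add(key)
        structure = parse_structure(row["name"], deacetyl_position=pos)
        detection = {c: bool(int(row[c])) for c in CONDITION_COLUMNS}
        records.append(InventoryRecord(
            structure=structure,
            detection=detection,
            also_salt=bool(int(row["also_salt"])),
        ))
    totals = {c: sum(r.detection[c] for r in records) for c in CONDITION_COLUMNS}
    log.info("inventory %s: %d structures, detection totals %s",
             Path(path).name, len(records), totals)
    return records


# ---------------------------------------------------------------- spectra --

def _envelope_header(env: Sequence[Peak]) -> str:
    return ";".join(f"{p.mz:.6f}:{p.intensity:.6g}" for p in env)


def _parse_envelope_header(text: str) -> Tuple[Peak, ...]:
    peaks = []
    for item in text.split(";"):
        if not item:
            continue
        mz, inten = item.split(":")
        peaks.append(Peak(float(mz), float(inten)))
    return tuple(peaks)


def write_run_mgf(run: SpectrumRun, path: str | Path) -> None:
    """Serialize a run as MGF, one BEGIN IONS block per precursor."""
    spectra = []
    for i, prec in enumerate(run.precursors):
        ms2 = prec.ms2 or ()
        spectra.append({
            "m/z array": [p.mz for p in ms2],
            "intensity array": [p.intensity for p in ms2],
            "params": {
                "title": f"{run.sample}.{i}",
                "pepmass": (prec.mz, prec.intensity),
                "envelope": _envelope_header(prec.envelope),
                "sample": run.sample,
                "condition": run.condition,
                "hasms2": "1" if prec.ms2 is not None else "0",
            },
        })
    _mgf.write(spectra, str(path), file_mode="w")


def read_run_mgf(path: str | Path) -> SpectrumRun:
    sample = condition = None
    precursors: List[PrecursorRecord] = []
    with _mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            sample = params.get("sample", sample)
            condition = params.get("condition", condition)
            pepmass = params["pepmass"]
            mz = float(pepmass[0])
            inten = float(pepmass[1]) if len(pepmass) > 1 and pepmass[1] else 1.0
            envelope = _parse_envelope_header(params.get("envelope", ""))
            has_ms2 = params.get("hasms2", "1") == "1"
            ms2 = tuple(
                Peak(float(m), float(i))
                for m, i in zip(spec["m/z array"], spec["intensity array"])
            ) if has_ms2 else None
            precursors.append(PrecursorRecord(mz, inten, envelope, ms2))
    if sample is None:
        raise ValueError(f"MGF file {path} contains no spectra")
    return SpectrumRun(sample=sample, condition=condition or "unknown",
                       precursors=tuple(precursors))


def write_run_csv(run: SpectrumRun, path: str | Path) -> None:
    """CSV dialect: columns scan, level, precursor_mz, mz, intensity.

    Level-1 rows carry the isotope envelope, level-2 rows the MS2 peaks;
    sample/condition labels ride in a comment header.
    """
    rows = []
    for i, prec in enumerate(run.precursors):
        for p in prec.envelope:
            rows.append((i, 1, prec.mz, p.mz, p.intensity))
        for p in (prec.ms2 or ()):
            rows.append((i, 2, prec.mz, p.mz, p.intensity))
        if not prec.envelope and prec.ms2 is None:
            rows.append((i, 1, prec.mz, prec.mz, prec.intensity))
    with open(path, "w") as fh:
        fh.write(f"# sample={run.sample} condition={run.condition}\n")
        pd.DataFrame(rows, columns=["scan", "level", "precursor_mz", "mz", "intensity"]) \
            .to_csv(fh, index=False)


def read_run_csv(path: str | Path, sample: Optional[str] = None,
                 condition: Optional[str] = None) -> SpectrumRun:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
            sample = sample or meta.get("sample")
            condition = condition or meta.get("condition")
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    precursors = []
    for _, group in df.groupby("scan", sort=True):
        prec_mz = float(group["precursor_mz"].iloc[0])
        env = group[group["level"] == 1]
        ms2 = group[group["level"] == 2]
        envelope = tuple(sorted(
            (Peak(float(m), float(i)) for m, i in zip(env["mz"], env["intensity"])),
            key=lambda p: p.mz))
        intensity = envelope[0].intensity if envelope else 1.0
        ms2_peaks = tuple(
            Peak(float(m), float(i)) for m, i in zip(ms2["mz"], ms2["intensity"])
        ) if len(ms2) else None
        precursors.append(PrecursorRecord(prec_mz, intensity, envelope, ms2_peaks))
    return SpectrumRun(sample=sample or "unknown", condition=condition or "unknown",
                       precursors=tuple(precursors))


# --------------------------------------------------------------- databases --

def write_candidate_db(db: CandidateDB, path: str | Path) -> None:
    rows = []
    for e in db:
        row = {
            "name": e.structure.name,
            "dnac_position": e.structure.deacetylated_residue,
            "formula": e.formula.hill(),
            "monoisotopic": f"{e.monoisotopic:.6f}",
        }
        for a, mz in e.adduct_mz.items():
            row[f"mz_{a}"] = f"{mz:.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_candidate_db(path: str | Path,
                      adducts=DEFAULT_ADDUCTS) -> CandidateDB:
    """Rebuild a CandidateDB from its TSV; masses recomputed from structures."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, row in df.iterrows():
        pos = None if pd.isna(row.get("dnac_position")) else int(row["dnac_position"])
        s = parse_structure(row["name"], deacetyl_position=pos)
        f = elemental_formula(s)
        entries.append(CandidateEntry(
            structure=s, formula=f, monoisotopic=monoisotopic_mass(f),
            adduct_mz={a.name: adduct_mz(f, a) for a in adducts},
        ))
    return CandidateDB(entries, adducts)


# -------------------------------------------------------------------- hits --

def hits_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group_formula": h.group_key,
        "structures": "|".join(s.identifier for s in h.structures),
        "adduct": h.adduct,
        "theoretical_mz": h.theoretical_mz,
        "observed_mz": h.observed_mz,
        "ppm": h.ppm,
        "isotope_score": h.isotope_score,
        "matched_fragments": h.matched_fragments,
        "accepted": h.accepted,
    } for h in hits])


def write_hits(hits: Sequence[AnnotationHit], path: str | Path) -> None:
    hits_frame(hits).to_csv(path, sep="\t", index=False)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    out = matrix.table.astype(int)
    out.index.name = "structure"
    out.to_csv(path, sep="\t")


def write_summary(summary: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
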