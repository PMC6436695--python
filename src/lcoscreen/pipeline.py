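"""End-to-end orchestration: build-db -> simulate -> annotate -> compare.

`run_pipeline` wires the stages into one deterministic run and writes every
artifact (candidate DB, per-condition MGF runs + ground truth, hit tables,
presence matrix, JSON summary with full parameter provenance).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

from . import __version__
from .annotation import MatchParams, annotate_run, build_presence_matrix, compare_conditions
from .candidates import DEFAULT_CONFIG, EnumerationConfig, enumerate_candidates
from .io import (
    read_structure_inventory,
    write_candidate_db,
    write_hits,
    write_presence_matrix,
    write_run_mgf,
    write_summary,
)
from .synth import SimulationParams, simulate_table3_runs

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: Path = Path("lco_pipeline_out")
    inventory_path: Optional[Path] = None      # None -> bundled digitized inventory
    enumeration: EnumerationConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    match: MatchParams = field(default_factory=MatchParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    provenance_aware: bool = True
    seed: int = 42

    def validate(self) -> None:
        if self.inventory_path is not None and not Path(self.inventory_path).exists():
            raise FileNotFoundError(f"inventory file {self.inventory_path} not found")


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the full synthetic screen and write all artifacts.

    Returns a dict with the in-memory results: ``db``, ``runs``, ``hits``,
    ``matrix``, ``comparison`` and ``summary``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    inventory = read_structure_inventory(config.inventory_path)
    db = enumerate_candidates(config.enumeration, config.match.adducts)
    write_candidate_db(db, out / "candidates.tsv")
    log.info("candidate database: %d structures", len(db))

    sim = replace(config.simulation, seed=config.seed, structures=())
    runs = simulate_table3_runs(inventory, sim, db=db)

    hits = {}
    planted = {}
    for cond, (run, truth) in runs.items():
        write_run_mgf(run, out / f"run_{cond}.mgf")
        write_summary(
            {"planted": dict(truth.planted), "decoys": list(truth.decoys),
             "seed": truth.seed},
            out / f"truth_{cond}.json",
        )
        accepted = annotate_run(run, db, config.match)
        hits[cond] = accepted
        planted[cond] = truth.planted_identifiers
        write_hits(accepted, out / f"hits_{cond}.tsv")
        log.info("condition %s: %d accepted isomer-group hits", cond, len(accepted))

    matrix = build_presence_matrix(
        hits, [r.structure for r in inventory],
        planted=planted if config.provenance_aware else None,
    )
    write_presence_matrix(matrix, out / "presence_matrix.tsv")

    salt_flags = {r.identifier: r.also_salt for r in inventory}
    comparison = compare_conditions(matrix, flags=salt_flags)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "mode": matrix.mode,
        "n_candidates": len(db),
        "match_params": asdict(config.match),
        "simulation_params": {k: v for k, v in asdict(sim).items() if k != "structures"},
        "column_totals": matrix.column_totals(),
        "salt_overlap": comparison.get("flag_overlap"),
    }
    write_summary(summary, out / "summary.json")
    return {"db": db, "runs": runs, "hits": hits, "matrix": matrix,
            "comparison": comparison, "summary": summary}
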