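"""Precursor matching, acceptance gates, dedup and presence accounting."""

import numpy as np
import pandas as pd
import pytest

from lcoscreen import (
    MatchParams,
    Peak,
    PrecursorRecord,
    PresenceMatrix,
    SpectrumRun,
    annotate_run,
    build_presence_matrix,
    compare_conditions,
    elemental_formula,
    evaluate_hit,
    isotope_pattern,
    match_precursor,
    parse_structure,
)
from lcoscreen.annotation import _observed_pattern
from lcoscreen.masscalc import M_PLUS_H, fragment_ions
from lcoscreen.synth import C13_SPACING, SimulationParams, simulate_run


def perfect_precursor(entry, adduct="M+H", ms2=None, n_peaks=4):
    """A noiseless precursor for a database entry: exact m/z, exact envelope."""
    mz = entry.adduct_mz[adduct]
    ion = entry.formula
    from lcoscreen import ElementalFormula
    ion = ion + ElementalFormula({"H": 1} if adduct == "M+H" else {"Na": 1})
    pattern = isotope_pattern(ion, n_peaks=n_peaks)
    env = tuple(Peak(mz + o * C13_SPACING, a) for o, a in pattern.peaks)
    return PrecursorRecord(mz, 1.0, env, ms2)


def run_of(precursors, condition="cond"):
    return SpectrumRun("sample", condition, tuple(precursors))


class TestMatchPrecursor:
    def test_exact_match_has_zero_ppm(self, default_db):
        entry = default_db.entries[10]
        hits = match_precursor(run_of([perfect_precursor(entry)]), default_db)
        mine = [h for h in hits if h.candidate_index == 10]
        assert len(mine) == 1 and mine[0].ppm == pytest.approx(0.0, abs=1e-9)

    def test_six_ppm_offset_misses_at_five_ppm(self, default_db):
        entry = default_db.entries[10]
        mz = entry.adduct_mz["M+H"] * (1 + 6e-6)
        # make sure no OTHER candidate sits within tolerance of the offset mass
        hits = match_precursor(run_of([PrecursorRecord(mz)]), default_db)
        assert all(abs(h.ppm) <= 5.0 for h in hits)
        assert not any(h.candidate_index == 10 for h in hits)

    def test_matches_brute_force_all_pairs(self, default_db):
        assert len(default_db) >= 200
        rng = np.random.default_rng(3)
        mzs = [float(rng.uniform(600, 1500)) for _ in range(200)]
        # include some exact candidate masses
        mzs += [default_db.entries[i].adduct_mz["M+H"] for i in range(0, 100, 7)]
        run = run_of([PrecursorRecord(m) for m in mzs])
        p = MatchParams()
        got = {(h.precursor_index, h.candidate_index, h.adduct.name)
               for h in match_precursor(run, default_db, p)}
        expected = set()
        for pi, mz in enumerate(mzs):
            for ci, e in enumerate(default_db.entries):
                for a in ("M+H", "M+Na"):
                    theo = e.adduct_mz[a]
                    if abs((mz - theo) / theo * 1e6) <= p.tolerance_ppm:
                        expected.add((pi, ci, a))
        assert got == expected

    def test_empty_database_rejected(self, default_db):
        from lcoscreen.candidates import CandidateDB
        with pytest.raises(ValueError, match="empty"):
            match_precursor(run_of([PrecursorRecord(500.0)]),
                            CandidateDB([], default_db.adducts))


class TestEvaluateHit:
    def test_undistorted_envelope_scores_100_and_accepts(self, default_db):
        entry = default_db.entries[5]
        run = run_of([perfect_precursor(entry)])
        hit = match_precursor(run, default_db)[0]
        out = evaluate_hit(hit, run, default_db)
        assert out.isotope_score == pytest.approx(100.0, abs=1e-6)
        assert out.accepted

    def test_flat_far_envelope_rejected_by_score_gate(self, default_db):
        entry = default_db.entries[5]
        mz = entry.adduct_mz["M+H"]
        # envelope pushed to offsets 5..8 where the theoretical pattern is ~0
        env = tuple(Peak(mz + k * C13_SPACING, 1.0) for k in range(5, 9))
        run = run_of([PrecursorRecord(mz, 1.0, env)])
        hits = [h for h in match_precursor(run, default_db) if h.candidate_index == 5]
        out = evaluate_hit(hits[0], run, default_db)
        assert out.isotope_score < 80.0
        assert not out.accepted

    def test_ms2_without_fragment_matches_rejected(self, default_db):
        entry = default_db.entries[5]
        ms2 = (Peak(150.0, 1.0), Peak(222.2, 1.0))  # far from any B/Y ion
        run = run_of([perfect_precursor(entry, ms2=ms2)])
        hits = [h for h in match_precursor(run, default_db) if h.candidate_index == 5]
        out = evaluate_hit(hits[0], run, default_db)
        assert out.matched_fragments == 0
        assert not out.accepted

    def test_matching_fragments_counted(self, default_db):
        entry = default_db.entries[5]
        frags = fragment_ions(entry.structure, M_PLUS_H)
        ms2 = tuple(Peak(f.mz, 1.0) for f in frags[:3])
        run = run_of([perfect_precursor(entry, ms2=ms2)])
        hits = [h for h in match_precursor(run, default_db) if h.candidate_index == 5]
        out = evaluate_hit(hits[0], run, default_db)
        assert out.matched_fragments >= 3
        assert out.accepted


class TestAnnotateRun:
    def test_planted_candidates_recovered_as_isomer_groups(self, default_db):
        params = SimulationParams(
            structures=tuple(parse_structure(n) for n in
                             ["III (C16:0)", "IV (C18:1)", "V (C18:1, NMe, S)"]),
            jitter_ppm=2.0, n_decoys=0, noise_rate=0.0, seed=11)
        run, truth = simulate_run(params, db=default_db)
        hits = annotate_run(run, default_db)
        planted_formulas = {
            elemental_formula(s).hill() for s in params.structures}
        assert planted_formulas <= {h.group_key for h in hits}

    def test_decoy_only_run_yields_nothing(self, default_db):
        params = SimulationParams(structures=(), jitter_ppm=0.0,
                                  n_decoys=15, noise_rate=0.0, seed=2)
        run, truth = simulate_run(params, db=default_db)
        assert annotate_run(run, default_db) == []

    def test_duplicate_precursors_deduplicate(self, default_db):
        entry = default_db.entries[7]
        run = run_of([perfect_precursor(entry), perfect_precursor(entry)])
        hits = annotate_run(run, default_db)
        assert len([h for h in hits if h.group_key == entry.formula.hill()]) == 1

    def test_soundness_on_random_runs(self, default_db):
        p = MatchParams()
        for seed in range(5):
            params = SimulationParams(
                structures=tuple(e.structure for e in default_db.entries[::40]),
                jitter_ppm=4.0, distortion=0.4, n_decoys=5, noise_rate=10.0,
                seed=seed)
            run, _ = simulate_run(params, db=default_db)
            for h in annotate_run(run, default_db, p):
                assert abs(h.ppm) <= p.tolerance_ppm
                assert h.isotope_score >= p.min_isotope_score
                if h.matched_fragments is not None:
                    assert h.matched_fragments >= p.min_fragments


class TestPresenceMatrix:
    def test_empty_annotations_give_all_false(self, inventory):
        m = build_presence_matrix({"a": [], "b": []},
                                  [r.structure for r in inventory])
        assert not m.table.to_numpy().any()
        assert m.mode == "mass-only"

    def test_row_order_follows_inventory(self, inventory):
        m = build_presence_matrix({"a": []}, [r.structure for r in inventory])
        assert list(m.table.index) == [r.identifier for r in inventory]

    def test_duplicate_condition_labels_rejected(self, inventory):
        # dict keys cannot collide, so exercise via the identifier check instead
        structures = [inventory[0].structure, inventory[0].structure]
        with pytest.raises(ValueError, match="unique"):
            build_presence_matrix({"a": []}, structures)

    def test_provenance_mode_restricts_to_planted_isomers(self, inventory, default_db):
        at3 = parse_structure("V (C18:1, NMe) dNAc", deacetyl_position=3)
        entry = default_db.find(at3)
        run = run_of([perfect_precursor(entry)], condition="c")
        hits = annotate_run(run, default_db)
        structures = [r.structure for r in inventory]
        mass_only = build_presence_matrix({"c": hits}, structures)
        aware = build_presence_matrix({"c": hits}, structures,
                                      planted={"c": {at3.identifier}})
        # both positional isomers share the formula: mass-only marks both
        assert mass_only.table["c"].sum() == 2
        assert aware.table["c"].sum() == 1
        assert aware.detected("c") == [at3.identifier]


def inventory_matrix(inventory):
    """Presence matrix straight from the digitized detection flags."""
    table = pd.DataFrame(
        {cond: [r.detection[cond] for r in inventory]
         for cond in inventory[0].detection},
        index=[r.identifier for r in inventory])
    return PresenceMatrix(table=table, mode="mass-only")


class TestCompareConditions:
    def test_salt_overlap_of_the_mannitol_column(self, inventory):
        m = inventory_matrix(inventory)
        flags = {r.identifier: r.also_salt for r in inventory}
        summary = compare_conditions(m, flags=flags)
        assert summary["flag_overlap"]["ciat899_mannitol"] == 25

    def test_self_intersection_equals_column_total(self, inventory):
        m = inventory_matrix(inventory)
        summary = compare_conditions(m)
        for cond, total in summary["totals"].items():
            assert summary["intersections"][(cond, cond)] == total

    def test_disjoint_conditions_have_zero_intersection(self, inventory):
        structures = [r.structure for r in inventory[:4]]
        ids = [s.identifier for s in structures]
        table = pd.DataFrame({"a": [True, True, False, False],
                              "b": [False, False, True, True]}, index=ids)
        summary = compare_conditions(PresenceMatrix(table, "mass-only"))
        assert summary["intersections"][("a", "b")] == 0


class TestObservedPattern:
    def test_envelope_collapses_to_nominal_offsets(self):
        env = (Peak(1000.0, 0.6), Peak(1001.003, 0.3), Peak(1002.007, 0.1))
        pat = _observed_pattern(PrecursorRecord(1000.0, 1.0, env))
        assert pat.offsets == (0, 1, 2)
        assert sum(pat.abundances) == pytest.approx(1.0, abs=1e-12)
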