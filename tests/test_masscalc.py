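"""Mass calculus: masses, adducts, isotope envelopes, B/Y fragments."""

import itertools
import math

import numpy as np
import pytest

from lcoscreen import (
    AdductSpec,
    ElementalFormula,
    IsotopePattern,
    PROTON_MASS,
    adduct_mz,
    average_mass,
    elemental_formula,
    fragment_ions,
    isotope_pattern,
    isotope_score,
    monoisotopic_mass,
    parse_structure,
    ppm_error,
)
from lcoscreen.masscalc import _isotopes

F = ElementalFormula.parse


class TestMasses:
    def test_monoisotopic_water(self):
        assert monoisotopic_mass(F("H2O")) == pytest.approx(18.010565, abs=1e-6)

    def test_monoisotopic_hexitol(self):
        assert monoisotopic_mass(F("C6H14O6")) == pytest.approx(182.07904, abs=1e-5)

    def test_empty_formula_is_massless(self):
        assert monoisotopic_mass(ElementalFormula({})) == 0.0
        assert average_mass(ElementalFormula({})) == 0.0

    def test_average_mass_hexitol(self):
        # mannitol/dulcitol molecular weight to the printed precision
        assert average_mass(F("C6H14O6")) == pytest.approx(182.172, abs=0.001)

    def test_average_mass_water(self):
        assert average_mass(F("H2O")) == pytest.approx(18.015, abs=0.001)

    def test_additivity(self):
        f1, f2 = F("C6H14O6"), F("C8H15NO6")
        combined = f1 + f2
        assert monoisotopic_mass(combined) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9)
        assert average_mass(combined) == pytest.approx(
            average_mass(f1) + average_mass(f2), abs=1e-9)

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            monoisotopic_mass(ElementalFormula({"Xx": 1}))


class TestAdductsAndPpm:
    def test_identity_adduct(self):
        f = F("C6H14O6")
        assert adduct_mz(f, AdductSpec("M", 0.0, 1)) == monoisotopic_mass(f)

    def test_protonated_water(self):
        assert adduct_mz(F("H2O"), AdductSpec("M+H", 1.007276, 1)) == pytest.approx(
            19.017841, abs=1e-6)

    def test_sodium_exchange_delta(self):
        # delta given literally; the function only does (M + delta)/z
        assert adduct_mz(F("C6H14O6"), AdductSpec("M+Na", 21.981944, 1)) == pytest.approx(
            204.060984, abs=1e-5)

    @pytest.mark.parametrize("obs, theo, expected", [
        (1000.0, 1000.0, 0.0),
        (1000.005, 1000.0, 5.0),
        (999.995, 1000.0, -5.0),
    ])
    def test_ppm_error_definition(self, obs, theo, expected):
        assert ppm_error(obs, theo) == pytest.approx(expected, abs=1e-9)

    def test_ppm_requires_positive_theoretical(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)

    def test_charge_must_be_positive(self):
        with pytest.raises(ValueError):
            AdductSpec("bad", 1.0, 0)


def enumerate_isotopologues(f: ElementalFormula, n_peaks: int) -> np.ndarray:
    """Brute-force oracle: walk every isotope assignment of every atom."""
    atoms = [elem for elem, n in f for _ in range(n)]
    agg = {}
    choices = []
    for elem in atoms:
        iso = _isotopes(elem)
        base = iso[0][0]
        choices.append([(int(round(m - base)), ab) for m, ab in iso])
    for combo in itertools.product(*choices):
        offset = sum(o for o, _ in combo)
        prob = math.prod(ab for _, ab in combo)
        agg[offset] = agg.get(offset, 0.0) + prob
    vec = np.zeros(n_peaks)
    for o, p in agg.items():
        if o < n_peaks:
            vec[o] += p
    return vec / vec.sum()


class TestIsotopePattern:
    def test_single_carbon(self):
        pat = isotope_pattern(F("C"), n_peaks=2)
        assert pat.abundances == pytest.approx(
            np.array([0.9893, 0.0107]) / (0.9893 + 0.0107), abs=1e-12)

    @pytest.mark.parametrize("formula", ["CH4", "C2H4O", "CHNOS", "S2", "C3NO2", "H8"])
    def test_matches_exhaustive_enumeration(self, formula):
        f = F(formula)
        assert sum(n for _, n in f) <= 8
        pat = isotope_pattern(f, n_peaks=5)
        oracle = enumerate_isotopologues(f, 5)
        assert np.abs(np.array(pat.abundances) - oracle).max() < 1e-9

    def test_abundances_normalized_after_truncation(self):
        s = parse_structure("V (C18:1, NMe, S)")
        pat = isotope_pattern(elemental_formula(s), n_peaks=3)
        assert sum(pat.abundances) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            IsotopePattern(((0, 0.5), (0, 0.5)))      # duplicate offsets
        with pytest.raises(ValueError):
            IsotopePattern(((0, 0.5), (1, 0.4)))      # does not sum to 1

    def test_n_peaks_must_be_positive(self):
        with pytest.raises(ValueError):
            isotope_pattern(F("C"), n_peaks=0)


class TestIsotopeScore:
    def test_identical_patterns_score_100(self):
        pat = isotope_pattern(F("C40H70N4O20"), n_peaks=4)
        assert isotope_score(pat, pat) == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_support_scores_0(self):
        a = IsotopePattern(((0, 1.0),))
        b = IsotopePattern(((1, 1.0),))
        assert isotope_score(a, b) == 0.0

    def test_two_peak_example(self):
        a = IsotopePattern.from_abundances([0.8, 0.2])
        b = IsotopePattern.from_abundances([0.6, 0.4])
        expected = 100 * 0.56 / (math.sqrt(0.68) * math.sqrt(0.52))
        assert isotope_score(a, b) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(94.17, abs=0.05)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = IsotopePattern.from_abundances(rng.uniform(0.01, 1, size=4))
            b = IsotopePattern.from_abundances(rng.uniform(0.01, 1, size=4))
            assert isotope_score(a, b) == pytest.approx(isotope_score(b, a), abs=1e-9)
            scaled = IsotopePattern.from_abundances(np.array(b.abundances) * 7.3)
            assert isotope_score(a, scaled) == pytest.approx(isotope_score(a, b), abs=1e-9)

    def test_100_iff_proportional(self):
        a = IsotopePattern.from_abundances([0.7, 0.2, 0.1])
        prop = IsotopePattern.from_abundances([7, 2, 1])
        other = IsotopePattern.from_abundances([0.7, 0.21, 0.09])
        assert isotope_score(a, prop) == pytest.approx(100.0, abs=1e-9)
        assert isotope_score(a, other) < 100.0 - 1e-9


class TestFragmentIons:
    def test_pentamer_has_four_sites(self):
        ions = fragment_ions(parse_structure("V (C18:1)"))
        assert sum(i.series == "B" for i in ions) == 4
        assert sum(i.series == "Y" for i in ions) == 4

    def test_complementarity_over_inventory(self, inventory):
        for rec in inventory:
            s = rec.structure
            M = monoisotopic_mass(elemental_formula(s))
            ions = {(i.series, i.cleavage_site): i.mz for i in fragment_ions(s)}
            for site in range(1, s.backbone_n):
                total = ions[("B", site)] + ions[("Y", site)]
                assert total == pytest.approx(M + 2 * PROTON_MASS, abs=1e-6)

    def test_sulfate_rides_the_reducing_fragment(self):
        plain = parse_structure("V (C18:1)")
        sulfated = parse_structure("V (C18:1, S)")
        y1 = {s.cleavage_site: s.mz for s in fragment_ions(sulfated) if s.series == "Y"}
        y0 = {s.cleavage_site: s.mz for s in fragment_ions(plain) if s.series == "Y"}
        # Y1 = reducing terminal residue, cleavage site n-1
        assert y1[4] - y0[4] == pytest.approx(79.95682, abs=1e-5)

    def test_acyl_rides_the_nonreducing_fragment(self):
        ions = fragment_ions(parse_structure("V (C18:1, NMe)"))
        b1 = next(i for i in ions if i.series == "B" and i.index == 1)
        assert b1.formula["C"] > 20  # single residue plus the C18 chain

    def test_multiply_charged_adducts_unsupported(self):
        with pytest.raises(ValueError, match="singly charged"):
            fragment_ions(parse_structure("V (C18:1)"), AdductSpec("M+2H", 2.0, 2))
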