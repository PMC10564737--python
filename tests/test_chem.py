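"""Thermodynamics, ligand efficiency, GSH decay and mass arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covalkit import (
    Composition,
    ThermoRecord,
    composition_mass,
    covalent_adduct_composition,
    delta_g,
    entropy_term,
    fit_gsh_decay,
    ligand_efficiency,
    parse_composition,
)
from covalkit.fixtures import HEADLINE, TABLE2


class TestFreeEnergy:
    def test_standard_state_is_zero(self):
        assert delta_g(1.0) == 0.0

    @pytest.mark.parametrize("kd,expected", [(0.38e-6, -8.75), (1.1e-6, -8.12)])
    def test_calorimetry_table_values(self, kd, expected):
        assert delta_g(kd, 298.0) == pytest.approx(expected, abs=0.05)

    def test_strictly_increasing_in_KD(self):
        kds = np.logspace(-9, -3, 20)
        dgs = [delta_g(k) for k in kds]
        assert np.all(np.diff(dgs) > 0)

    @pytest.mark.parametrize("dg,dh,expected", [
        (-8.75, -7.13, -1.62),
        (-8.12, -5.81, -2.31),
        (-5.0, -5.0, 0.0),
    ])
    def test_entropy_split(self, dg, dh, expected):
        assert entropy_term(dg, dh) == pytest.approx(expected, abs=1e-12)

    def test_full_calorimetry_table_consistency(self):
        # recomputed dG from K_D and the dG = dH - TdS identity both
        # reproduce the published columns to 0.05 kcal/mol
        for row in TABLE2:
            assert delta_g(row["KD_itc"], 298.0) == pytest.approx(
                row["dG"], abs=0.05), row["compound"]
            assert entropy_term(row["dG"], row["dH"]) == pytest.approx(
                row["minusTdS"], abs=0.05), row["compound"]


class TestLigandEfficiency:
    def test_phosphotyrosine(self):
        le = ligand_efficiency(HEADLINE["pY_K_D"], HEADLINE["pY_NHA"], 298.0)
        assert le == pytest.approx(0.29, abs=0.01)

    def test_capped_analog(self):
        assert ligand_efficiency(186e-6, 21, 298.0) == pytest.approx(0.24, abs=0.01)

    def test_molar_kd_gives_zero(self):
        assert ligand_efficiency(1.0, 30) == 0.0

    def test_strictly_decreasing_in_NHA(self):
        les = [ligand_efficiency(1e-6, n) for n in range(10, 40)]
        assert np.all(np.diff(les) < 0)

    def test_thermo_record_identities(self):
        rec = ThermoRecord(K_D=0.38e-6, NHA=33, dH=-7.13)
        R = 1.98720425e-3
        assert rec.dG == pytest.approx(R * 298.0 * math.log(0.38e-6), rel=1e-9)
        assert rec.minusTdS == pytest.approx(rec.dG - rec.dH, rel=1e-9)
        assert rec.LE == pytest.approx(-rec.dG / 33, rel=1e-9)


class TestGshDecay:
    def test_half_life_arithmetic(self):
        t = np.linspace(0.0, 120.0, 9)
        fit = fit_gsh_decay(t, np.exp(-0.00990 * t))
        assert fit.T_half == pytest.approx(70.0, abs=0.05)
        assert fit.T_half * fit.k_e == pytest.approx(math.log(2.0), rel=1e-12)

    def test_fitted_curve_halves_at_half_life(self):
        t = np.linspace(0.0, 200.0, 12)
        fit = fit_gsh_decay(t, 2.0 * np.exp(-0.005 * t))
        assert fit.C0 * math.exp(-fit.k_e * fit.T_half) == pytest.approx(
            fit.C0 / 2.0, rel=1e-9)

    def test_noisy_recovery(self, rng):
        t = np.linspace(0.0, 240.0, 13)
        y = np.exp(-0.005 * t) + rng.normal(0.0, 0.01, t.size)
        fit = fit_gsh_decay(t, y)
        assert fit.k_e == pytest.approx(0.005, rel=0.10)

    def test_increasing_series_flags_non_reactive(self):
        t = np.linspace(0.0, 60.0, 6)
        fit = fit_gsh_decay(t, 1.0 + 0.001 * t)
        assert math.isinf(fit.T_half)
        assert fit.flags["non_reactive"]


class TestCompositionParser:
    @pytest.mark.parametrize("text,expected", [
        ("H(2)O", {"H": 2, "O": 1}),
        ("Se(-1)S", {"Se": -1, "S": 1}),
        ("C(26)H(25)N(3)O(7)FPSe(-1)S",
         {"C": 26, "H": 25, "N": 3, "O": 7, "F": 1, "P": 1, "Se": -1, "S": 1}),
    ])
    def test_dialect(self, text, expected):
        assert parse_composition(text).as_dict() == expected

    def test_malformed_reports_position(self):
        with pytest.raises(ValueError, match="position"):
            parse_composition("C(26)H(2x)")

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            parse_composition("Xx(3)")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parse_composition("  ")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "P", "F", "Cl", "Se"]),
        st.integers(min_value=-5, max_value=40).filter(lambda n: n != 0),
        min_size=1, max_size=6))
    def test_serializer_round_trip(self, counts):
        comp = Composition.from_dict(counts)
        assert parse_composition(comp.serialize()).as_dict() == comp.as_dict()


class TestCompositionMass:
    def test_water_monoisotopic(self):
        assert composition_mass(parse_composition("H(2)O")) == pytest.approx(
            18.010565, abs=1e-4)

    def test_carbamidomethyl_monoisotopic(self):
        # the fixed cysteine alkylation used in proteomics searches
        assert composition_mass(parse_composition("C(2)H(3)NO")) == pytest.approx(
            57.02146, abs=1e-4)

    def test_adduct_average_mass_matches_reported_increase(self):
        comp = parse_composition(HEADLINE["adduct_composition"])
        assert composition_mass(comp, "average") == pytest.approx(
            HEADLINE["adduct_mass_Da"], abs=1.0)

    def test_additivity(self):
        a = parse_composition("C(6)H(12)O(6)")
        b = parse_composition("H(2)O")
        assert composition_mass(a) + composition_mass(b) == pytest.approx(
            composition_mass(a + b), rel=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            composition_mass(parse_composition("H(2)O"), "nominal")


class TestAdductBookkeeping:
    def test_ligand_minus_hcl_matches_search_modification(self):
        # chloroacetamide + thiol -> thioether + HCl; the adduct equals
        # the search engine's modification once its Se(-1)S placeholder
        # bookkeeping (U in place of C) is undone
        ligand = parse_composition(HEADLINE["ligand_composition"])
        adduct = covalent_adduct_composition(ligand, parse_composition("HCl"))
        assert adduct.as_dict() == parse_composition(
            HEADLINE["adduct_composition"]).as_dict()
        mq = parse_composition(HEADLINE["maxquant_modification"])
        placeholder_swap = Composition.from_dict({"S": 1, "Se": -1})
        assert (mq - placeholder_swap).as_dict() == adduct.as_dict()

    def test_identity_with_empty_leaving_group(self):
        ligand = parse_composition("C(2)H(3)NO")
        empty = Composition.from_dict({})
        assert covalent_adduct_composition(ligand, empty).as_dict() == \
            ligand.as_dict()

    def test_impossible_subtraction_rejected(self):
        with pytest.raises(ValueError, match="leaving group"):
            covalent_adduct_composition(parse_composition("C(2)H(3)NO"),
                                        parse_composition("Br"))
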