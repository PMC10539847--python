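"""Mass-action solver: exactness, conservation, limits and symmetries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slowex import (
    BindingConstants,
    CompetitionAssay,
    EquilibriumState,
    SITE_DISABLED_KD,
    TitrationPoint,
    occupancies,
    predict_titration_curve,
    single_site_bound_fraction,
    solve_competition,
    solve_two_site,
)
from slowex.errors import DomainError

from oracles import competition_nested_bisection, quadratic_bound_fraction, two_site_bisection

GOLDEN = (3.0 - math.sqrt(5.0)) / 2.0  # Et = Lt = KD single-site bound fraction

conc = st.floats(min_value=1e-9, max_value=1e-2)


def assert_state_valid(state, constants, point, rtol=1e-9):
    et, lt = point.total_enzyme, point.total_ligand
    assert abs(state.total_enzyme - et) / et < rtol
    assert abs(state.free_ligand + state.bound_ligand - lt) <= rtol * max(lt, et)
    # detailed balance of both sites
    scale = et * max(state.free_ligand, 1e-300)
    assert abs(state.e1 * constants.kd_orthosteric - state.e0 * state.free_ligand) <= 1e-8 * scale + 1e-300
    assert abs(state.e2 * constants.kd_allosteric - state.e0 * state.free_ligand) <= 1e-8 * scale + 1e-300


class TestSolveTwoSite:
    def test_zero_ligand_is_all_apo(self):
        state = solve_two_site(BindingConstants(1e-8, 1e-5), TitrationPoint(79e-6, 0.0))
        assert state == EquilibriumState(79e-6, 0.0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize("lt_ratio", [0.3, 1.0, 3.0])
    def test_symmetric_sites_give_equal_single_bound_states(self, lt_ratio):
        k = 5e-6
        state = solve_two_site(BindingConstants(k, k), TitrationPoint(79e-6, lt_ratio * 79e-6))
        assert state.e1 == pytest.approx(state.e2, rel=1e-12)

    def test_disabled_site_reduces_to_quadratic_golden_value(self):
        state = solve_two_site(BindingConstants(1.0, 1e9), TitrationPoint(1.0, 1.0))
        assert state.e1 == pytest.approx(GOLDEN, rel=1e-8)

    @pytest.mark.parametrize(
        "kd,et,lt",
        [(1e-8, 79e-6, 40e-6), (1e-5, 79e-6, 237e-6), (43e-6, 4e-6, 25e-6), (1e-6, 5e-8, 2e-7)],
    )
    def test_disabled_site_matches_closed_form(self, kd, et, lt):
        state = solve_two_site(BindingConstants(kd, 1e9), TitrationPoint(et, lt))
        expected = quadratic_bound_fraction(kd, et, lt)
        assert (state.e1 + state.e3) / et == pytest.approx(expected, rel=1e-9)

    def test_reference_point_matches_bisection_oracle(self):
        constants = BindingConstants(10e-9, 10e-6)
        point = TitrationPoint(79e-6, 79e-6)
        state = solve_two_site(constants, point)
        oracle = two_site_bisection(10e-9, 10e-6, 79e-6, 79e-6)
        got = (state.e1 + state.e3) / 79e-6
        want = (oracle["e1"] + oracle["e3"]) / 79e-6
        assert got == pytest.approx(want, abs=1e-12)

    @given(kdo=conc, kda=conc, et=conc, lt=conc)
    def test_conservation_and_oracle_agreement(self, kdo, kda, et, lt):
        constants = BindingConstants(kdo, kda)
        point = TitrationPoint(et, lt)
        state = solve_two_site(constants, point)
        assert_state_valid(state, constants, point)
        oracle = two_site_bisection(kdo, kda, et, lt)
        for name in ("e0", "e1", "e2", "e3", "free_ligand"):
            assert getattr(state, name) == pytest.approx(
                oracle[name], rel=1e-8, abs=1e-15 * et
            )

    @given(kdo=conc, kda=conc, lt=conc)
    def test_swap_symmetry_is_exact(self, kdo, kda, lt):
        point = TitrationPoint(79e-6, lt)
        a = solve_two_site(BindingConstants(kdo, kda), point)
        b = solve_two_site(BindingConstants(kda, kdo), point)
        assert a.e1 == b.e2 and a.e2 == b.e1
        assert a.e0 == b.e0 and a.e3 == b.e3 and a.free_ligand == b.free_ligand

    def test_rejects_invalid_inputs(self):
        with pytest.raises(DomainError):
            BindingConstants(-1e-9, 1e-6)
        with pytest.raises(DomainError):
            BindingConstants(float("nan"), 1e-6)
        with pytest.raises(DomainError):
            TitrationPoint(0.0, 1e-6)
        with pytest.raises(DomainError):
            TitrationPoint(79e-6, -1e-9)


class TestOccupancies:
    def test_all_apo_and_saturated(self):
        assert occupancies(EquilibriumState(1e-6, 0, 0, 0, 0), 1e-6) == (0.0, 0.0)
        assert occupancies(EquilibriumState(0, 0, 0, 1e-6, 1e-6), 1e-6) == (1.0, 1.0)

    def test_solved_state_matches_oracle(self):
        state = solve_two_site(BindingConstants(10e-9, 10e-6), TitrationPoint(79e-6, 237e-6))
        occ_o, occ_a = occupancies(state, 79e-6)
        oracle = two_site_bisection(10e-9, 10e-6, 79e-6, 237e-6)
        assert occ_o == pytest.approx((oracle["e1"] + oracle["e3"]) / 79e-6, abs=1e-12)
        assert occ_a == pytest.approx((oracle["e2"] + oracle["e3"]) / 79e-6, abs=1e-12)

    def test_zero_enzyme_rejected(self):
        with pytest.raises(DomainError):
            occupancies(EquilibriumState(0, 0, 0, 0, 0), 0.0)


class TestPredictTitrationCurve:
    REFERENCE_RATIOS = np.array([0.0, 0.1, 0.3, 0.5, 0.7, 1.0, 3.0])

    def test_single_zero_point(self):
        curve = predict_titration_curve(BindingConstants(1e-8, 1e-5), 79e-6, [0.0])
        assert curve.occ_orthosteric.tolist() == [0.0]
        assert curve.occ_allosteric.tolist() == [0.0]

    @pytest.mark.parametrize("kdo,tol", [(1e-15, 5e-6), (1e-17, 1e-6)])
    def test_tight_binding_limit_saturates_at_equivalence(self, kdo, tol):
        # at Lt = Et the unbound fraction in the tight-binding limit is
        # sqrt(KD/Et), so occupancy -> 1 as KD -> 0
        curve = predict_titration_curve(
            BindingConstants(kdo, SITE_DISABLED_KD), 79e-6, [79e-6]
        )
        assert curve.occ_orthosteric[0] == pytest.approx(1.0, abs=tol)

    def test_reference_curve_matches_oracle_pointwise(self):
        series = self.REFERENCE_RATIOS * 79e-6
        curve = predict_titration_curve(BindingConstants(10e-9, 10e-6), 79e-6, series)
        for i, lt in enumerate(series):
            oracle = two_site_bisection(10e-9, 10e-6, 79e-6, lt)
            assert curve.occ_orthosteric[i] == pytest.approx(
                (oracle["e1"] + oracle["e3"]) / 79e-6, abs=1e-10
            )
            assert curve.occ_allosteric[i] == pytest.approx(
                (oracle["e2"] + oracle["e3"]) / 79e-6, abs=1e-10
            )

    def test_orthosteric_dominates_below_equivalence(self):
        # high-affinity site fills first: occ_orth > occ_allo at every
        # sub-stoichiometric point, and both series rise monotonically
        series = np.linspace(0.0, 79e-6, 12)
        curve = predict_titration_curve(BindingConstants(10e-9, 10e-6), 79e-6, series)
        assert np.all(np.diff(curve.occ_orthosteric) >= -1e-12)
        assert np.all(np.diff(curve.occ_allosteric) >= -1e-12)
        positive = series > 0
        assert np.all(curve.occ_orthosteric[positive] > curve.occ_allosteric[positive])

    def test_occupancy_decreases_with_own_kd(self):
        lt = [40e-6]
        weak = predict_titration_curve(BindingConstants(1e-6, 1e-5), 79e-6, lt)
        weaker = predict_titration_curve(BindingConstants(1e-5, 1e-5), 79e-6, lt)
        assert weaker.occ_orthosteric[0] < weak.occ_orthosteric[0]

    def test_rejects_unsorted_series(self):
        with pytest.raises(DomainError):
            predict_titration_curve(BindingConstants(1e-8, 1e-5), 79e-6, [1e-6, 0.0])

    def test_csv_export_roundtrip(self, tmp_path):
        import pandas as pd

        curve = predict_titration_curve(
            BindingConstants(10e-9, 10e-6), 79e-6, self.REFERENCE_RATIOS * 79e-6
        )
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["Lt_molar", "occ_orthosteric", "occ_allosteric"]
        np.testing.assert_allclose(df["occ_orthosteric"], curve.occ_orthosteric, rtol=1e-12)


class TestSingleSiteBoundFraction:
    def test_zero_ligand(self):
        assert single_site_bound_fraction(1e-6, 79e-6, 0.0) == 0.0

    def test_golden_value(self):
        assert single_site_bound_fraction(1.0, 1.0, 1.0) == pytest.approx(GOLDEN, rel=1e-12)

    def test_weak_binding_limit_vanishes(self):
        assert single_site_bound_fraction(1e9 * 79e-6, 79e-6, 79e-6) < 1e-8

    def test_rejects_negative_inputs(self):
        with pytest.raises(DomainError):
            single_site_bound_fraction(-1.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            single_site_bound_fraction(1.0, 1.0, -1.0)

    @given(kd=conc, et=conc, lt=conc)
    def test_matches_two_site_with_other_site_disabled(self, kd, et, lt):
        direct = single_site_bound_fraction(kd, et, lt)
        state = solve_two_site(BindingConstants(kd, 1e12), TitrationPoint(et, lt))
        assert (state.e1 + state.e3) / et == pytest.approx(direct, rel=1e-9, abs=1e-15)


class TestCompetition:
    REFERENCE = CompetitionAssay(
        total_enzyme=4e-6, total_reporter=25e-6, total_competitor=25e-6,
        kd_reporter=43e-6, kd_competitor=10e-6,
    )

    def test_no_competitor_reduces_to_single_site(self):
        assay = CompetitionAssay(4e-6, 25e-6, 0.0, 43e-6, 10e-6)
        result = solve_competition(assay)
        assert result.reporter_bound_fraction == pytest.approx(
            single_site_bound_fraction(43e-6, 4e-6, 25e-6), rel=1e-10
        )
        assert result.displacement_fraction == 0.0

    def test_identical_ligands_bind_equally(self):
        assay = CompetitionAssay(4e-6, 25e-6, 25e-6, 43e-6, 43e-6)
        result = solve_competition(assay)
        assert result.reporter_bound_fraction == pytest.approx(
            result.competitor_bound_fraction, rel=1e-10
        )

    def test_reference_scenario_matches_nested_bisection_oracle(self):
        result = solve_competition(self.REFERENCE)
        er, ec = competition_nested_bisection(4e-6, 25e-6, 25e-6, 43e-6, 10e-6)
        assert result.reporter_bound_fraction == pytest.approx(er / 4e-6, rel=1e-8)
        assert result.competitor_bound_fraction == pytest.approx(ec / 4e-6, rel=1e-8)
        er0, _ = competition_nested_bisection(4e-6, 25e-6, 0.0, 43e-6, 10e-6)
        assert result.displacement_fraction == pytest.approx(1.0 - er / er0, rel=1e-8)

    def test_displacement_strictly_decreasing_in_competitor_kd(self):
        # a weaker competitor displaces less reporter: non-displacement
        # implies weak binding of the competitor to the shared site
        kds = np.geomspace(1e-7, 1e-2, 12)
        disp = [
            solve_competition(
                CompetitionAssay(4e-6, 25e-6, 25e-6, 43e-6, kd)
            ).displacement_fraction
            for kd in kds
        ]
        assert all(a > b for a, b in zip(disp, disp[1:]))

    def test_zero_enzyme_is_all_free(self):
        result = solve_competition(CompetitionAssay(0.0, 25e-6, 25e-6, 43e-6, 10e-6))
        assert result == (0.0, 0.0, 0.0)
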