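"""Analytic relations and stochastic simulators of the two-state model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenofluct.switching_model import (
    AssayParams,
    CloneComposition,
    DegenerateModelError,
    InfeasibleParameterError,
    ModelError,
    SamplingError,
    SwitchingParams,
    UndefinedSteadyStateError,
    expected_survival_fraction,
    growth_rate_from_doubling_time,
    rates_from_fraction_and_memory,
    rates_from_fraction_and_relaxation,
    resistant_fraction_from_survival,
    simulate_clone_composition,
    simulate_clone_compositions,
    simulate_suspension_assay,
    steady_state_fraction,
)


class TestSteadyState:
    @pytest.mark.parametrize(
        "p_sr,p_rs,expected",
        [
            (0.3016, 0.0952, 0.3016 / (0.3016 + 0.0952)),
            (0.0, 0.3, 0.0),  # absorbing sensitive state
            (0.2, 0.0, 1.0),  # absorbing resistant state
            (0.5, 0.5, 0.5),
        ],
    )
    def test_defining_ratio(self, p_sr, p_rs, expected):
        assert steady_state_fraction(p_sr, p_rs) == pytest.approx(expected)

    def test_both_rates_zero_is_undefined(self):
        with pytest.raises(UndefinedSteadyStateError):
            steady_state_fraction(0.0, 0.0)


class TestGrowthRate:
    @pytest.mark.parametrize(
        "T_d,expected",
        [(100.0, math.log(2) / 100), (24.0, math.log(2) / 24), (38.0, math.log(2) / 38)],
    )
    def test_ln2_over_doubling_time(self, T_d, expected):
        assert growth_rate_from_doubling_time(T_d) == pytest.approx(expected)

    def test_nonpositive_doubling_time_rejected(self):
        with pytest.raises(ModelError):
            growth_rate_from_doubling_time(0.0)


class TestSurvivalRelation:
    def test_paper_inversion(self):
        # mean survival 0.9 over a 24 h assay at T_d = 100 h implies f ~ 0.76
        f = resistant_fraction_from_survival(0.9, 24, 100, 0)
        assert f == pytest.approx(0.7621, abs=1e-4)

    def test_forward_survival(self):
        assert expected_survival_fraction(0.76, 24, 100, 0) == pytest.approx(
            0.8976, abs=1e-4
        )

    def test_one_doubling_doubles_resistant_mass(self):
        # T = T_d: resistant cells exactly double; f=0.5 gives survival 1.0
        assert expected_survival_fraction(0.5, 36.0, 36.0, 0) == pytest.approx(1.0)

    def test_all_sensitive_survival_is_escape(self):
        assert expected_survival_fraction(0.0, 24, 100, 0.25) == pytest.approx(0.25)

    def test_no_growth_limit_forces_f_one(self):
        f = resistant_fraction_from_survival(1.0, 24, 1e12, 0)
        assert f == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_survival_raises_with_parameters_named(self):
        with pytest.raises(InfeasibleParameterError, match="outside"):
            resistant_fraction_from_survival(5.0, 24, 100, 0)

    @given(
        f=st.floats(0.0, 1.0),
        T=st.floats(1.0, 72.0),
        T_d=st.floats(10.0, 500.0),
        escape=st.floats(0.0, 0.5),
    )
    def test_round_trip(self, f, T, T_d, escape):
        s = expected_survival_fraction(f, T, T_d, escape)
        assert resistant_fraction_from_survival(s, T, T_d, escape) == pytest.approx(
            f, abs=1e-12
        )


class TestRatesFromFractionAndMemory:
    def test_round_trip_through_steady_state(self):
        params = rates_from_fraction_and_memory(0.76, 10.5)
        assert params.p_rs == pytest.approx(1 / 10.5)
        assert params.p_sr == pytest.approx(0.76 / 0.24 / 10.5)
        assert params.steady_state_f == pytest.approx(0.76)
        assert params.memory_generations == pytest.approx(10.5)

    def test_symmetric_switching(self):
        params = rates_from_fraction_and_memory(0.5, 7.0)
        assert params.p_sr == pytest.approx(params.p_rs) == pytest.approx(1 / 7.0)

    def test_short_memory_with_high_fraction_is_infeasible(self):
        with pytest.raises(InfeasibleParameterError):
            rates_from_fraction_and_memory(0.76, 1.0)

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_degenerate_fraction_rejected(self, f):
        with pytest.raises(DegenerateModelError):
            rates_from_fraction_and_memory(f, 10.0)

    def test_relaxation_parameterisation(self):
        params = rates_from_fraction_and_relaxation(0.76, 10.5)
        assert params.steady_state_f == pytest.approx(0.76)
        assert params.p_sr + params.p_rs == pytest.approx(1 / 10.5)


class TestCloneSimulation:
    def test_pure_doubling_without_switching(self):
        comp = simulate_clone_composition(
            SwitchingParams(0.0, 0.0), 3, founder="R", seed=0
        )
        assert (comp.n_sensitive, comp.n_resistant) == (0, 8)

    def test_zero_generations_returns_founder(self):
        comp = simulate_clone_composition(
            SwitchingParams(0.3, 0.1), 0, founder="S", seed=0
        )
        assert (comp.n_sensitive, comp.n_resistant) == (1, 0)
        assert comp.founder_state == "S"

    @pytest.mark.parametrize("generations", [1, 4, 9])
    def test_conservation_of_cell_number(self, generations):
        params = rates_from_fraction_and_memory(0.76, 10.5)
        _, n_s, n_r = simulate_clone_compositions(
            params, generations, 500, seed=11
        )
        assert np.all(n_s + n_r == 2**generations)

    @pytest.mark.parametrize("founder", ["S", "R", "steady_state"])
    def test_ergodicity_regardless_of_founder(self, founder):
        # 20 generations >> memory: mean resistant fraction matches steady state
        params = rates_from_fraction_and_memory(0.76, 10.5)
        _, n_s, n_r = simulate_clone_compositions(
            params, 20, 1000, founder=founder, seed=7
        )
        f = n_r / (n_s + n_r)
        mc_se = f.std(ddof=1) / math.sqrt(f.size)
        assert abs(f.mean() - 0.76) < 3 * mc_se + 1e-4

    def test_identical_seeds_identical_outputs(self):
        params = rates_from_fraction_and_memory(0.76, 10.5)
        a = simulate_clone_compositions(params, 10, 100, seed=42)
        b = simulate_clone_compositions(params, 10, 100, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestSuspensionAssay:
    def test_all_sensitive_clone_dies(self):
        comp = CloneComposition(100, 0, 5, "S")
        assay = AssayParams(plated_count=100, count_depth=None)
        out = simulate_suspension_assay(comp, assay, seed=0)
        assert out.survival_fraction == 0.0

    def test_all_resistant_clone_doubles_over_one_doubling_time(self):
        comp = CloneComposition(0, 128, 7, "R")
        assay = AssayParams(
            T_suspension=24.0, T_d_resistant=24.0, plated_count=128, count_depth=None
        )
        out = simulate_suspension_assay(comp, assay, seed=0)
        assert out.survival_fraction == pytest.approx(2.0)
        assert out.live_at_end == pytest.approx(256.0)

    def test_noise_free_assay_matches_expected_survival_exactly(self):
        comp = CloneComposition(24, 76, 10, "R")
        assay = AssayParams(plated_count=100, count_depth=None)
        out = simulate_suspension_assay(comp, assay, seed=3)
        assert out.survival_fraction == pytest.approx(
            expected_survival_fraction(0.76, 24, 100, 0), abs=1e-12
        )

    def test_overplating_raises(self):
        comp = CloneComposition(5, 5, 1, "R")
        with pytest.raises(SamplingError):
            simulate_suspension_assay(comp, AssayParams(plated_count=100), seed=0)

    def test_counting_noise_is_unbiased(self):
        comp = CloneComposition(240_000, 760_000, 20, "R")
        assay = AssayParams(plated_count=1000, count_depth=500)
        rng = np.random.default_rng(5)
        vals = np.array(
            [simulate_suspension_assay(comp, assay, seed=rng).survival_fraction
             for _ in range(400)]
        )
        expected = expected_survival_fraction(0.76, 24, 100, 0)
        assert vals.mean() == pytest.approx(expected, rel=0.02)
        assert vals.std(ddof=1) > 0
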