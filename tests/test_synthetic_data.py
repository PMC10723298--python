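"""Synthetic experiment generators: reproducibility, schema and calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from phenofluct.fluctuation_stats import load_clone_table, replicate_cv, write_clone_table
from phenofluct.growth_metrics import reversion_generations
from phenofluct.switching_model import (
    AssayParams,
    ModelError,
    SwitchingParams,
    expected_survival_fraction,
    rates_from_fraction_and_memory,
)
from phenofluct.synthetic_data import (
    ExperimentDesign,
    design_to_dict,
    generate_clone_experiment,
    generate_population_replicates,
    generate_reversion_experiment,
)

QUIET_ASSAY = AssayParams(count_depth=None)


class TestCloneExperiment:
    def test_single_clone_emits_one_record_per_passage(self):
        for model in ("two_state", "heterogeneous_gamma", "combined"):
            design = ExperimentDesign(n_clones=1, model=model, seed=0)
            table = generate_clone_experiment(design)
            assert len(table.records) == len(design.assay_passages)

    def test_seed_reproducibility(self):
        a = generate_clone_experiment(ExperimentDesign(seed=5))
        b = generate_clone_experiment(ExperimentDesign(seed=5))
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_schema_round_trip(self, tmp_path):
        table = generate_clone_experiment(ExperimentDesign(n_clones=10, seed=1))
        path = tmp_path / "clones.csv"
        write_clone_table(table, path)
        again = load_clone_table(path)
        pd.testing.assert_frame_equal(table.records, again.records)

    def test_two_state_fluctuations_are_noise_dominated(self):
        # model-intrinsic CV < 0.01; plating + counting noise bring the
        # interclonal CV to a few percent at most
        design = ExperimentDesign(model="two_state", seed=2)
        table = generate_clone_experiment(design)
        v = table.at_passage(1)["survival_fraction"].to_numpy()
        assert v.std(ddof=1) / v.mean() < 0.05

    def test_heterogeneous_mean_survival_calibrated(self):
        # mean-calibrated gamma draws keep the mean at the survival relation
        means = []
        for seed in range(50):
            design = ExperimentDesign(
                model="heterogeneous_gamma", assay=QUIET_ASSAY, seed=seed
            )
            means.append(
                generate_clone_experiment(design)
                .at_passage(1)["survival_fraction"]
                .mean()
            )
        assert 0.88 <= float(np.mean(means)) <= 0.92

    def test_combined_model_matches_observed_statistics(self):
        # acceptance envelope of the generator: mean ~0.9, CV in the
        # observed 0.25-0.3 band (widened for sampling error), every passage
        means = {p: [] for p in (1, 3, 6)}
        cvs = {p: [] for p in (1, 3, 6)}
        for seed in range(50):
            table = generate_clone_experiment(ExperimentDesign(seed=seed))
            for p in (1, 3, 6):
                v = table.at_passage(p)["survival_fraction"].to_numpy()
                means[p].append(v.mean())
                cvs[p].append(v.std(ddof=1) / v.mean())
        for p in (1, 3, 6):
            assert 0.85 <= float(np.mean(means[p])) <= 0.95
            assert 0.20 <= float(np.mean(cvs[p])) <= 0.35

    def test_persistent_gamma_restores_cross_passage_correlation(self):
        from phenofluct.fluctuation_stats import passage_correlation

        redrawn = generate_clone_experiment(ExperimentDesign(seed=11))
        persistent = generate_clone_experiment(
            ExperimentDesign(redraw_gamma_each_passage=False, seed=11)
        )
        r_redrawn = passage_correlation(redrawn, 1, 3).r
        r_persistent = passage_correlation(persistent, 1, 3).r
        assert r_persistent > 0.5
        assert abs(r_redrawn) < r_persistent

    def test_invalid_design_rejected(self):
        with pytest.raises(ModelError):
            ExperimentDesign(n_clones=0)
        with pytest.raises(ModelError):
            ExperimentDesign(assay_passages=(3, 1))
        with pytest.raises(ModelError):
            ExperimentDesign(model="three_state")

    def test_design_manifest_is_complete(self):
        design = ExperimentDesign(seed=3)
        manifest = design_to_dict(design)
        assert manifest["seed"] == 3
        assert manifest["switching"]["steady_state_f"] == pytest.approx(0.76)
        assert manifest["assay"]["count_depth"] == 500


class TestPopulationReplicates:
    def test_zero_noise_returns_copies(self):
        vals = generate_population_replicates(11, 0.9, 0.0, seed=0)
        assert np.allclose(vals, 0.9)

    def test_generator_estimator_consistency(self):
        # replicate_cv of the output recovers the generating CV on average
        cvs = [
            replicate_cv(generate_population_replicates(11, 0.9, 0.1, seed=s))
            for s in range(200)
        ]
        assert float(np.mean(cvs)) == pytest.approx(0.1, abs=0.01)

    def test_seed_reproducibility_and_truncation(self):
        a = generate_population_replicates(11, 0.9, 0.1, seed=4)
        b = generate_population_replicates(11, 0.9, 0.1, seed=4)
        np.testing.assert_array_equal(a, b)
        extreme = generate_population_replicates(1000, 0.1, 5.0, seed=5)
        assert extreme.min() >= 0.0


class TestReversionExperiment:
    def test_permanent_resistance_never_reverts(self):
        params = SwitchingParams(p_sr=0.3, p_rs=0.0)
        assay = AssayParams()
        curve = generate_reversion_experiment(params, n_passages=5, assay=assay)
        expected = expected_survival_fraction(1.0, assay.T_suspension,
                                              assay.T_d_resistant)
        assert np.allclose(curve.survival_fractions, expected)

    def test_zero_passages_gives_initial_point_only(self):
        params = rates_from_fraction_and_memory(0.76, 10.5)
        curve = generate_reversion_experiment(params, n_passages=0)
        assert len(curve.cumulative_generations) == 1
        assert curve.cumulative_generations[0] == 0.0

    def test_reversion_duration_finite_and_increasing_with_memory(self):
        crossings = []
        for memory in (5.0, 10.5, 20.0):
            params = rates_from_fraction_and_memory(0.76, memory)
            curve = generate_reversion_experiment(
                params, n_passages=40, generations_per_passage=1.0
            )
            g = reversion_generations(curve, tolerance=0.05)
            assert math.isfinite(g)
            crossings.append(g)
        assert crossings == sorted(crossings)
        assert crossings[0] < crossings[-1]

    def test_crossing_scales_linearly_with_memory_in_long_memory_regime(self):
        memories = np.array([10.5, 15.0, 20.0, 30.0])
        crossings = []
        for m in memories:
            params = rates_from_fraction_and_memory(0.76, m)
            curve = generate_reversion_experiment(
                params, n_passages=120, generations_per_passage=0.25
            )
            crossings.append(reversion_generations(curve, tolerance=0.05))
        crossings = np.array(crossings)
        r = np.corrcoef(memories, crossings)[0, 1]
        assert r > 0.99
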