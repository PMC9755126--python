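"""IIC, the balance-of-correlations target and the Monte Carlo optimizer."""

import math

import numpy as np
import pytest

from smilescw.dataset_io import CALIBRATION, TRAIN
from smilescw.monte_carlo import (
    OptimizerConfig,
    build_model,
    grid_search_TN,
    iic,
    optimize,
    run_probes,
    target_function,
)
from smilescw.validation import pearson_r


class TestIIC:
    def test_balanced_residuals_equal_pearson(self):
        obs = np.array([1.0, 2, 3, 4])
        pred = np.array([1.5, 1.5, 3.5, 3.5])
        # -MAE = +MAE = 0.5, so IIC collapses to the Pearson correlation
        expected_r = 4.0 / (2.0 * math.sqrt(5.0))
        assert iic(obs, pred) == pytest.approx(expected_r, abs=1e-12)
        assert iic(obs, pred) == pytest.approx(pearson_r(obs, pred), abs=1e-12)

    def test_perfect_predictions_give_iic_one(self):
        x = np.array([1.0, 2, 3, 4])
        assert iic(x, x) == pytest.approx(1.0)

    def test_one_sided_residuals_give_zero(self):
        obs = np.array([1.0, 2, 3, 4])
        assert iic(obs, obs + 0.5) == 0.0  # all deltas negative
        assert iic(obs, obs - 0.5) == 0.0  # all deltas positive (other class empty)

    def test_iic_bounded_by_correlation(self, rng):
        for _ in range(50):
            obs = rng.normal(size=12)
            pred = obs * rng.uniform(0.5, 2) + rng.normal(scale=0.5, size=12)
            assert abs(iic(obs, pred)) <= abs(pearson_r(obs, pred)) + 1e-12

    def test_negative_correlation_keeps_sign(self):
        obs = np.array([1.0, 2, 3, 4, 5])
        pred = np.array([5.2, 3.9, 3.0, 2.1, 0.8])
        assert iic(obs, pred) < 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iic([1, 2, 3], [1, 2])


class TestTargetFunction:
    def test_tf_arithmetic(self):
        cfg = OptimizerConfig(dr_weight=0.1, iic_weight=0.2)
        state = target_function(0.8, 0.6, 0.5, cfg)
        assert state.TF == pytest.approx(0.8 + 0.6 - 0.2 * 0.1)
        assert state.TFm == pytest.approx(state.TF + 0.5 * 0.2)

    def test_equal_correlations_remove_penalty(self):
        cfg = OptimizerConfig(dr_weight=0.7)
        for r in (0.3, 0.9):
            assert target_function(r, r, 0.0, cfg).TF == pytest.approx(2 * r)


class TestOptimizer:
    def test_trajectory_non_decreasing(self, small_panel, fast_config):
        labelled, profiles, _ = small_panel
        _, traj = optimize(labelled, profiles, fast_config)
        assert all(b >= a for a, b in zip(traj, traj[1:]))
        assert traj[-1] >= traj[0]

    def test_seed_determinism(self, small_panel, fast_config):
        labelled, profiles, _ = small_panel
        t1, traj1 = optimize(labelled, profiles, fast_config)
        t2, traj2 = optimize(labelled, profiles, fast_config)
        assert t1.weights == t2.weights  # byte-identical floats
        assert traj1 == traj2

    def test_different_seeds_differ(self, small_panel):
        labelled, profiles, _ = small_panel
        t1, _ = optimize(labelled, profiles, OptimizerConfig(n_epochs=3, seed=1))
        t2, _ = optimize(labelled, profiles, OptimizerConfig(n_epochs=3, seed=2))
        assert t1.weights != t2.weights

    def test_rare_keys_stay_frozen(self, small_panel):
        labelled, profiles, _ = small_panel
        cfg = OptimizerConfig(T=3, n_epochs=2, seed=0)
        table, _ = optimize(labelled, profiles, cfg)
        assert table.rare_keys
        assert all(table.weights[k] == 0.0 for k in table.rare_keys)

    def test_planted_signal_recovered_noise_free(self):
        """15 epochs on a clean n=300 panel reach near-perfect training fit."""
        from smilescw.dataset_io import apply_split, make_split
        from smilescw.smiles_attributes import profile_dataset
        from smilescw.synthetic_data import GeneratorConfig, generate_dataset
        from smilescw.validation import r2

        ds, _ = generate_dataset(GeneratorConfig(n_molecules=300, noise_sd=0.0, seed=100))
        lab = apply_split(ds, make_split(ds, seed=0))
        profiles = profile_dataset(lab)
        cfg = OptimizerConfig(seed=0)
        table, _ = optimize(lab, profiles, cfg)
        model = build_model(lab, profiles, table, cfg)
        train = [c for c in lab.compounds if c.set_label == TRAIN]
        obs = np.array([c.endpoint for c in train])
        pred = np.array([model.predict_one(profiles[c.id]) for c in train])
        assert r2(obs, pred) >= 0.95


class TestProbes:
    def test_probe_count_and_seed_offsets(self, small_panel):
        labelled, profiles, _ = small_panel
        cfg = OptimizerConfig(n_epochs=3, seed=40, n_probes=3)
        models = run_probes(labelled, profiles, cfg)
        assert len(models) == 3
        assert [m.probe_seed for m in models] == [40, 41, 42]
        # probe 0 equals a bare optimize with the same seed
        t0, _ = optimize(labelled, profiles, OptimizerConfig(n_epochs=3, seed=40))
        assert models[0].cw_table.weights == t0.weights
        # probes generally differ
        assert models[0].cw_table.weights != models[1].cw_table.weights


class TestGridSearch:
    def test_single_candidate(self, small_panel):
        labelled, profiles, _ = small_panel
        cfg = OptimizerConfig(n_epochs=2, seed=1)
        assert grid_search_TN(labelled, profiles, [1], [15], cfg) == (1, 15)

    def test_tie_breaks_toward_smaller_T_then_N(self, small_panel, monkeypatch):
        labelled, profiles, _ = small_panel
        import smilescw.monte_carlo as mc

        # force identical calibration R2 for every candidate
        monkeypatch.setattr(mc, "optimize", lambda d, p, c: (mc.CorrelationWeightTable(weights={"Cmax.0": 1.0, "Cmax.1": 2.0, "Cmax.2": 3.0, "Cmax.3": 4.0}, T=c.T), [0.0]))
        t, n = grid_search_TN(labelled, profiles, [2, 1], [20, 10], OptimizerConfig(seed=0))
        assert (t, n) == (1, 10)
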