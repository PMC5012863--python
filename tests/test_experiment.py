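import dataclasses

import numpy as np
import pandas as pd
import pytest

from virtualtms import (
    PerturbationSpec,
    SimulationConfig,
    calibrate_lambda,
    generate_reference_fc,
    node_strength,
    peak_delta,
    per_region_stats,
    run_trial_pair,
    run_trials,
    sweep_delta_omega,
)
from virtualtms.experiment import (
    ControlSiteResult,
    PerturbationError,
    SweepResult,
    control_site_experiment,
)

#: coupling placing the 16-region toy network in partial synchrony
TOY_COUPLING = 0.5


@pytest.fixture
def toy_cfg():
    return SimulationConfig(coupling=TOY_COUPLING)


@pytest.fixture
def short_cfg():
    return SimulationConfig(
        coupling=TOY_COUPLING, dt=0.1, duration=240.0, transient=60.0,
        sampling_interval=2.0,
    )


class TestTrialPairs:
    def test_null_perturbation_is_bitwise_identical(self, toy16, short_cfg):
        conn, omega = toy16
        pair = run_trial_pair(
            conn, omega, short_cfg, PerturbationSpec("r008", 0.0), trial_seed=5
        )
        np.testing.assert_array_equal(
            pair.pre_fc.to_numpy(), pair.post_fc.to_numpy()
        )

    def test_same_seed_reproduces_trial(self, toy16, short_cfg):
        conn, omega = toy16
        pert = PerturbationSpec("r008", 0.002)
        a = run_trial_pair(conn, omega, short_cfg, pert, trial_seed=9)
        b = run_trial_pair(conn, omega, short_cfg, pert, trial_seed=9)
        np.testing.assert_array_equal(a.pre_fc.to_numpy(), b.pre_fc.to_numpy())
        np.testing.assert_array_equal(a.post_fc.to_numpy(), b.post_fc.to_numpy())

    def test_batch_order_independence(self, toy16, short_cfg):
        """A trial's result does not depend on which batch it ran in."""
        conn, omega = toy16
        pert = PerturbationSpec("r008", 0.002)
        batch = run_trials(conn, omega, short_cfg, pert, 4, base_seed=20)
        single = run_trial_pair(conn, omega, short_cfg, pert, trial_seed=22)
        assert batch[2].seed == 22
        np.testing.assert_allclose(
            batch[2].post_fc.to_numpy(), single.post_fc.to_numpy(), atol=1e-9
        )

    def test_vectors_exclude_target(self, toy16, short_cfg):
        conn, omega = toy16
        pair = run_trial_pair(
            conn, omega, short_cfg, PerturbationSpec("r008", 0.001), trial_seed=0
        )
        assert len(pair.pre_fc) == conn.n_regions - 1
        assert "r008" not in pair.pre_fc.index

    def test_excessive_reduction_rejected(self, toy16, short_cfg):
        conn, omega = toy16
        with pytest.raises(PerturbationError):
            run_trial_pair(
                conn, omega, short_cfg, PerturbationSpec("r008", 0.5), trial_seed=0
            )

    def test_sensory_slowing_increases_fc_at_bootstrap_confidence(
        self, toy16, toy_cfg
    ):
        """Slowing the fast peripheral node toward the network mean raises
        its FC with the rest of the network (50 paired trials)."""
        conn, omega = toy16
        gap = omega["r008"] - omega.mean()
        trials = run_trials(
            conn, omega, toy_cfg,
            PerturbationSpec("r008", 0.75 * float(gap)), 50, base_seed=3,
        )
        d = np.array([(t.post_fc - t.pre_fc).mean() for t in trials])
        rng = np.random.default_rng(0)
        boot = np.array(
            [rng.choice(d, d.size, replace=True).mean() for _ in range(2000)]
        )
        assert np.percentile(boot, 2.5) > 0


class TestSweep:
    def test_zero_grid_gives_exact_null(self, toy16, short_cfg):
        conn, omega = toy16
        sweep = sweep_delta_omega(
            conn, omega, short_cfg, "r008", [0.0], n_trials=4, base_seed=1
        )
        assert np.all(sweep.mean_change == 0.0)
        assert np.all(sweep.per_region.to_numpy() == 0.0)
        assert np.all(sweep.trial_means == 0.0)

    def test_deterministic_under_base_seed(self, toy16, short_cfg):
        conn, omega = toy16
        a = sweep_delta_omega(
            conn, omega, short_cfg, "r008", [0.001, 0.002], 4, base_seed=2
        )
        b = sweep_delta_omega(
            conn, omega, short_cfg, "r008", [0.001, 0.002], 4, base_seed=2
        )
        np.testing.assert_array_equal(a.mean_change, b.mean_change)

    def test_non_increasing_grid_rejected(self, toy16, short_cfg):
        conn, omega = toy16
        with pytest.raises(ValueError, match="increasing"):
            sweep_delta_omega(
                conn, omega, short_cfg, "r008", [0.002, 0.001], 4, base_seed=0
            )

    def test_out_of_range_delta_rejected(self, toy16, short_cfg):
        conn, omega = toy16
        with pytest.raises(PerturbationError):
            sweep_delta_omega(
                conn, omega, short_cfg, "r008", [0.2], 4, base_seed=0
            )

    def test_shapes(self, toy16, short_cfg):
        conn, omega = toy16
        sweep = sweep_delta_omega(
            conn, omega, short_cfg, "r008", [0.001, 0.003], 5, base_seed=0
        )
        assert sweep.trial_means.shape == (2, 5)
        assert sweep.per_region.shape == (2, conn.n_regions - 1)
        np.testing.assert_allclose(
            sweep.mean_change, sweep.trial_means.mean(axis=1), atol=1e-12
        )


class TestPeakDelta:
    def _mk(self, deltas, mean_change):
        n = len(deltas)
        return SweepResult(
            target="x",
            deltas=np.asarray(deltas, float),
            mean_change=np.asarray(mean_change, float),
            sem=np.zeros(n),
            per_region=pd.DataFrame(np.zeros((n, 2)), index=deltas),
            trial_means=np.zeros((n, 2)),
            n_trials=2,
            scale="z",
        )

    def test_monotone_decreasing_returns_first(self):
        assert peak_delta(self._mk([0.001, 0.002, 0.003], [3, 2, 1])) == 0.001

    def test_tie_returns_smallest(self):
        assert peak_delta(self._mk([0.001, 0.002], [2.0, 2.0])) == 0.001

    def test_single_point(self):
        assert peak_delta(self._mk([0.004], [1.0])) == 0.004


class TestPerRegionStats:
    def test_null_perturbation_yields_no_significance(self, toy16, short_cfg):
        conn, omega = toy16
        trials = run_trials(
            conn, omega, short_cfg, PerturbationSpec("r008", 0.0), 6, base_seed=0
        )
        res = per_region_stats(trials)
        assert not res.table["significant"].any()
        assert (res.table["p_value"] == 1.0).all()

    def test_pvalues_match_direct_calls(self, toy16, short_cfg):
        from virtualtms import paired_rank_test

        conn, omega = toy16
        trials = run_trials(
            conn, omega, short_cfg, PerturbationSpec("r008", 0.003), 8, base_seed=4
        )
        res = per_region_stats(trials)
        for region in res.table.index[:5]:
            pre = np.array([t.pre_fc[region] for t in trials])
            post = np.array([t.post_fc[region] for t in trials])
            expected = paired_rank_test(pre, post).p_value
            assert res.table.loc[region, "p_value"] == pytest.approx(expected)

    def test_threshold_is_alpha_over_regions(self, toy16, short_cfg):
        conn, omega = toy16
        trials = run_trials(
            conn, omega, short_cfg, PerturbationSpec("r008", 0.001), 6, base_seed=0
        )
        res = per_region_stats(trials, alpha=0.05)
        assert res.threshold == pytest.approx(0.05 / (conn.n_regions - 1))

    def test_too_few_trials_rejected(self, toy16, short_cfg):
        conn, omega = toy16
        trials = run_trials(
            conn, omega, short_cfg, PerturbationSpec("r008", 0.001), 3, base_seed=0
        )
        with pytest.raises(ValueError):
            per_region_stats(trials)


class TestControlSites:
    def test_designated_control_rejected(self, toy16, short_cfg):
        conn, omega = toy16
        with pytest.raises(ValueError, match="designated"):
            control_site_experiment(
                conn, omega, short_cfg, ["r000"], sensory_id="r008",
                hub_id="r000", n_trials=6,
            )

    def test_null_delta_changes_nothing(self, toy16, short_cfg):
        conn, omega = toy16
        res = control_site_experiment(
            conn, omega, short_cfg, ["r004"], sensory_id="r008", hub_id="r000",
            delta_omega=0.0, n_trials=6, base_seed=1,
        )
        assert res.sweeps["r004"].mean_change[0] == 0.0
        assert res.pair_change["r004"] == 0.0
        assert res.pair_test["r004"].p_value == 1.0

    def test_deterministic(self, toy16, short_cfg):
        conn, omega = toy16
        kwargs = dict(
            sensory_id="r008", hub_id="r000", delta_omega=0.001,
            n_trials=6, base_seed=2,
        )
        a = control_site_experiment(conn, omega, short_cfg, ["r004"], **kwargs)
        b = control_site_experiment(conn, omega, short_cfg, ["r004"], **kwargs)
        assert a.pair_change == b.pair_change

    def test_control_leaves_sensory_hub_pair_unmodulated(self, toy16, toy_cfg):
        """Slowing a weak, hypothesis-irrelevant node must not modulate the
        sensory-hub pair: the pair change stays far below the direct-target
        effect and clears no Bonferroni-corrected significance bar."""
        conn, omega = toy16
        strengths = node_strength(conn).drop(["r000", "r008"])
        control = strengths.idxmin()
        res = control_site_experiment(
            conn, omega, toy_cfg, [control], sensory_id="r008", hub_id="r000",
            delta_omega=0.001, n_trials=20, base_seed=9,
        )
        gap = omega["r008"] - omega.mean()
        direct = run_trials(
            conn, omega, toy_cfg,
            PerturbationSpec("r008", 0.75 * float(gap)), 20, base_seed=9,
        )
        direct_effect = np.mean(
            [(t.post_fc - t.pre_fc).mean() for t in direct]
        )
        corrected_threshold = 0.05 / (conn.n_regions - 1)
        assert res.pair_test[control].p_value > corrected_threshold
        assert abs(res.pair_change[control]) < 0.1 * abs(direct_effect)


class TestCalibration:
    def test_single_value_grid(self, toy16, short_cfg):
        conn, omega = toy16
        ref = generate_reference_fc(
            conn, omega, TOY_COUPLING, short_cfg, ["r008"], n_trials=4, seed=0
        )
        res = calibrate_lambda(
            conn, omega, short_cfg, ref, [0.3], n_trials=4, base_seed=1
        )
        assert res.selected_lambda == 0.3
        assert res.fit_r.shape == (1,)

    def test_fit_r_in_range(self, toy16, short_cfg):
        conn, omega = toy16
        ref = generate_reference_fc(
            conn, omega, TOY_COUPLING, short_cfg, ["r008"], n_trials=4, seed=0
        )
        res = calibrate_lambda(
            conn, omega, short_cfg, ref, [0.1, 0.5, 2.0], n_trials=4, base_seed=1
        )
        assert np.all(res.fit_r >= -1.0) and np.all(res.fit_r <= 1.0)
        assert res.selected_lambda == res.lambda_grid[np.argmax(res.fit_r)]

    def test_degenerate_reference_rejected(self, toy16, short_cfg):
        conn, omega = toy16
        flat = {"r008": pd.Series(np.ones(15))}
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_lambda(
                conn, omega, short_cfg, flat, [0.1], n_trials=4, base_seed=0
            )

    def test_invalid_grid_rejected(self, toy16, short_cfg):
        conn, omega = toy16
        ref = generate_reference_fc(
            conn, omega, TOY_COUPLING, short_cfg, ["r008"], n_trials=4, seed=0
        )
        with pytest.raises(ValueError):
            calibrate_lambda(conn, omega, short_cfg, ref, [], n_trials=4, base_seed=0)
        with pytest.raises(ValueError):
            calibrate_lambda(
                conn, omega, short_cfg, ref, [-0.1], n_trials=4, base_seed=0
            )
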