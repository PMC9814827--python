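"""Sweep pipeline: sampling, filtering, scoring, selection, experiments."""

import numpy as np
import pandas as pd
import pytest

import seedshell as ss
from seedshell.sweep import (
    SweepConfig,
    marginal_mode,
    run_sweep,
    sample_parameters,
    sensitivity_scan,
    pressure_swap_experiment,
    constant_pressure_scan,
    _integrate_sets,
)


class TestSampling:
    def test_deterministic_from_seed(self):
        cfg = SweepConfig(n_sets=500, seed=9)
        assert sample_parameters(cfg).equals(sample_parameters(cfg))

    def test_different_seed_differs(self):
        a = sample_parameters(SweepConfig(n_sets=500, seed=9))
        b = sample_parameters(SweepConfig(n_sets=500, seed=10))
        assert not a.equals(b)

    def test_empty(self):
        assert len(sample_parameters(SweepConfig(n_sets=0))) == 0

    def test_log_uniform_median(self):
        """Median of log-uniform rho on [0.5, 10] is sqrt(5) (closed form)."""
        cfg = SweepConfig(n_sets=100_000, seed=4)
        rho = sample_parameters(cfg)["rho"]
        expected = np.log(np.sqrt(0.5 * 10.0))
        assert np.median(np.log(rho)) == pytest.approx(expected, rel=0.01)

    def test_uniform_initial_stress_bounds(self):
        x0 = sample_parameters(SweepConfig(n_sets=2000, seed=1))["x0"]
        assert x0.min() >= 1.01 and x0.max() <= 1.5


class TestRunSweep:
    def test_reproducible(self, wt_dataset):
        cfg = SweepConfig(n_sets=2000, seed=6)
        a = run_sweep(cfg, 1.0, wt_dataset, genotype="Col-0")
        b = run_sweep(cfg, 1.0, wt_dataset, genotype="Col-0")
        assert a.table.equals(b.table)
        assert a.top.index.equals(b.top.index)

    def test_no_stiffening_leaves_no_survivors(self, wt_dataset):
        """With the stiffening amplitude effectively zero every growing
        trajectory blows up, so nothing passes the convergence filter."""
        cfg = SweepConfig(n_sets=500, seed=1, alpha_range=(1e-8, 2e-8))
        result = run_sweep(cfg, 1.0, wt_dataset, genotype="Col-0")
        assert result.n_in_band == 0
        assert result.insufficient_survivors
        assert (result.table["outcome"] == "diverged").all()

    def test_top_sets_converged_and_in_band(self, wt_sweep):
        top = wt_sweep.top
        assert len(top) == 100
        assert (top["outcome"] == "converged").all()
        assert top["final_rel_radius"].between(3.0, 4.0).all()
        scores = top["score"].to_numpy()
        assert np.all(np.diff(scores) >= 0)

    def test_self_fit_scores_zero_and_ranks_first(self, wt_sweep):
        """Rescoring against a survivor's own simulated curve puts that set
        first with score exactly 0."""
        target_idx = wt_sweep.survivor_index[0]
        pos = 0
        curve = wt_sweep.survivor_curves[pos]
        rescored = wt_sweep.rescore(curve)
        assert rescored.best().name == target_idx
        assert rescored.best()["score"] == 0.0

    def test_score_detects_constant_offset(self, wt_sweep):
        """Adding 0.1 to every day of a perfect-fit target yields a score
        of exactly 0.1 (RMSE of a constant offset)."""
        curve = wt_sweep.survivor_curves[0]
        rescored = wt_sweep.rescore(curve + 0.1)
        idx = wt_sweep.survivor_index[0]
        assert rescored.table.loc[idx, "score"] == pytest.approx(0.1, rel=1e-12)


class TestMarginalMode:
    def _result_with_top(self, values):
        import seedshell.sweep as sw

        top = pd.DataFrame({"rho": values})
        return sw.SweepResult(
            config=SweepConfig(n_sets=0),
            table=top,
            top=top,
            days=np.arange(11),
            target=np.zeros(11),
            survivor_index=np.arange(len(values)),
            survivor_curves=np.zeros((len(values), 11)),
            insufficient_survivors=False,
        )

    def test_degenerate_top(self):
        m = marginal_mode(self._result_with_top([2.0] * 50), "rho")
        assert abs(m.mode_bin_center - 2.0) <= m.bin_width / 2
        assert m.median == 2.0

    def test_majority_bin(self):
        m = marginal_mode(self._result_with_top([0.9] * 40 + [2.0] * 60), "rho")
        assert abs(m.mode_bin_center - 2.0) <= m.bin_width / 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            marginal_mode(self._result_with_top([]), "rho")
        with pytest.raises(ValueError):
            marginal_mode(self._result_with_top([1.0]), "not_a_param")


class TestExperiments:
    def test_sensitivity_zero_delta_is_baseline(self, wt_sweep):
        top = wt_sweep.top.head(5)
        cfg = SweepConfig(n_sets=0)
        scan = sensitivity_scan(
            top, pressures={"const": ss.ConstantPressure(1.0)}, config=cfg,
            param_names=("rho",), deltas=[0.0],
        )
        _, _, baseline, _ = _integrate_sets(top, 1.0, cfg)
        np.testing.assert_array_equal(
            scan["final_rel_radius"].to_numpy(), baseline
        )

    def test_swap_identical_drops_identical_results(self, iku2_sweep):
        top = iku2_sweep.top.head(5)
        drop = ss.DEFAULT_IKU2_DROP
        swap = pressure_swap_experiment(top, drops={"iku2": drop, "75-25": drop})
        np.testing.assert_array_equal(swap.final_rel["iku2"], swap.final_rel["75-25"])
        np.testing.assert_array_equal(swap.r_mean["iku2"], swap.r_mean["75-25"])

    def test_constant_scan_below_threshold_never_grows(self, wt_sweep):
        top = wt_sweep.top.head(10)
        scan = constant_pressure_scan(top, factors=[0.6, 1.0])
        low = scan[scan["factor"] == 0.6].merge(
            top[["x0"]], left_on="set_index", right_index=True
        )
        below = low[low["x0"] * 0.6 <= 1.0]
        assert len(below) > 0
        assert (below["outcome"] == "no_growth").all()
        assert np.allclose(below["final_rel_radius"], 1.0)

    def test_empty_top_sets_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_scan(pd.DataFrame())
        with pytest.raises(ValueError):
            constant_pressure_scan(pd.DataFrame())
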