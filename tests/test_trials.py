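"""Trial engine: stopping rule, determinism, batches, summaries."""

import numpy as np
import pytest

from doublewell import (
    ConfigurationError,
    InvalidArgumentError,
    ProcessParams,
    SystemState,
    TrialConfig,
    TwoProcessConfig,
    decide,
    preset,
    run_batch,
    run_trial_1d,
    run_trial_2d,
    summarize,
)
from doublewell.trials import results_to_frame, trajectories_to_frame

from .conftest import oracle_trial


class TestDecide:
    @pytest.mark.parametrize(
        "acc_f, acc_s, expected",
        [
            (-30.2, 4.1, ("egocentric", "fast")),
            (12.0, -12.0, None),
            (31.0, -33.0, ("egocentric", "slow")),  # larger magnitude wins
            (5.0, 30.0, ("other_centric", "slow")),
            (-31.0, 31.0, ("egocentric", "fast")),  # exact tie goes to fast
        ],
    )
    def test_rule(self, acc_f, acc_s, expected):
        assert decide(acc_f, acc_s, 30.0) == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            decide(0.0, 0.0, 0.0)


class TestDeterministicTrial:
    """sigma = 0 trials are exactly reproducible arithmetic."""

    def test_figure3_regime_pinned_step_count(self, fig3_config):
        # brute-force re-iteration of the noise-free map pins this at
        # 35 steps with final fast accumulator -30.668276
        from dataclasses import replace

        config = replace(fig3_config, dynamics=replace(fig3_config.dynamics, sigma=0.0))
        result = run_trial_2d(config, np.random.default_rng(0))
        assert result.steps == 35
        assert result.outcome == "egocentric"
        assert result.winner == "fast"
        assert result.accum_fast[-1] == pytest.approx(-30.668276, abs=1e-6)
        # dual route: the in-test oracle must agree step for step
        oracle = oracle_trial(0.2, 0.2, 0.0, 0.1, 0.0, 0.0, 0.0, iter(lambda: (0.0, 0.0), None))
        assert oracle[:3] == ("egocentric", "fast", 35)
        assert result.accum_fast[-1] == pytest.approx(oracle[3], abs=1e-12)

    def test_exact_saddle_without_noise_never_decides(self):
        cfg = TwoProcessConfig(
            fast=ProcessParams(0.0, 0.2), slow=ProcessParams(0.0, 0.2), sigma=0.0
        )
        config = TrialConfig(dynamics=cfg, max_steps=300)
        result = run_trial_2d(config, np.random.default_rng(0))
        assert result.outcome == "none"
        assert result.winner == "none"
        assert result.steps == 300
        assert np.all(result.states == 0.0)


class TestStochasticTrials:
    def test_figure3_regime_is_fast_egocentric(self, fig3_config):
        for seed in range(20):
            r = run_trial_2d(fig3_config, np.random.default_rng(seed))
            assert r.outcome == "egocentric"
            assert r.winner == "fast"

    def test_trial_matches_oracle_with_shared_draws(self, fig5_config):
        d = fig5_config.dynamics
        for seed in (0, 1, 2):
            draws = np.random.default_rng(seed).standard_normal((2000, 2))
            result = run_trial_2d(fig5_config, _ReplayGenerator(draws))
            oracle = oracle_trial(
                d.fast.k, d.fast.u, d.slow.k, d.slow.u, d.alpha, d.beta, d.sigma,
                iter(map(tuple, draws)),
            )
            assert (result.outcome, result.winner, result.steps) == oracle[:3]
            assert result.accum_fast[-1] == pytest.approx(oracle[3], abs=1e-9)
            assert result.accum_slow[-1] == pytest.approx(oracle[4], abs=1e-9)

    def test_first_crossing_property(self, fig5_config):
        results, _ = run_batch(fig5_config, 50, seed=3)
        for r in results:
            if r.decided:
                before = np.maximum(np.abs(r.accum_fast[:-1]), np.abs(r.accum_slow[:-1]))
                assert np.all(before < fig5_config.threshold)
                assert (
                    max(abs(r.accum_fast[-1]), abs(r.accum_slow[-1]))
                    >= fig5_config.threshold
                )

    def test_trajectories_stay_bounded(self, fig5_config):
        results, _ = run_batch(fig5_config, 30, seed=4)
        for r in results:
            assert np.all(np.abs(r.states) < 2.0)


class _ReplayGenerator:
    """Feeds a fixed array of draws through the Generator interface."""

    def __init__(self, draws):
        self._draws = np.asarray(draws, dtype=float).reshape(-1)
        self._pos = 0

    def standard_normal(self, size=None):
        if size is None:
            size = 1
        n = int(np.prod(size))
        out = self._draws[self._pos : self._pos + n]
        if out.size < n:
            out = np.concatenate([out, np.zeros(n - out.size)])
        self._pos += n
        return out.reshape(size)


class TestRunTrial1D:
    def test_strong_tilt_is_unanimously_egocentric(self):
        for seed in range(50):
            r = run_trial_1d(0.5, 0.01, rng=np.random.default_rng(seed))
            assert r.outcome == "egocentric"

    def test_untilted_noisy_trials_split_both_ways(self):
        outcomes = {
            run_trial_1d(0.0, 0.1, rng=np.random.default_rng(seed)).outcome
            for seed in range(60)
        }
        assert outcomes == {"egocentric", "other_centric"}

    def test_exact_saddle_without_noise_never_decides(self):
        r = run_trial_1d(0.0, 0.0, max_steps=200, rng=np.random.default_rng(0))
        assert r.outcome == "none"
        assert r.steps == 200

    def test_first_crossing(self):
        r = run_trial_1d(0.1, 0.05, rng=np.random.default_rng(7))
        assert np.all(np.abs(r.accum[:-1]) < 30.0)
        assert abs(r.accum[-1]) >= 30.0


class TestBatch:
    def test_bitwise_reproducibility(self, fig5_config):
        res_a, sum_a = run_batch(fig5_config, 20, seed=11)
        res_b, sum_b = run_batch(fig5_config, 20, seed=11)
        for a, b in zip(res_a, res_b):
            np.testing.assert_array_equal(a.accum_fast, b.accum_fast)
            np.testing.assert_array_equal(a.accum_slow, b.accum_slow)
            np.testing.assert_array_equal(a.states, b.states)
        assert sum_a == sum_b

    def test_single_trial_batch_counts(self, fig2_config):
        _, summary = run_batch(fig2_config, 1, seed=0)
        assert sum(summary.counts.values()) == 1
        assert summary.n_trials == 1

    def test_counts_sum_to_n_trials(self, fig5_config):
        _, summary = run_batch(fig5_config, 40, seed=5)
        assert sum(summary.counts.values()) == 40

    def test_mirror_tilt_symmetry_swaps_outcome_proportions(self, fig5_config):
        from dataclasses import replace

        n = 500
        _, fwd = run_batch(fig5_config, n, seed=0)
        d = fig5_config.dynamics
        mirrored = replace(
            fig5_config,
            dynamics=replace(
                d,
                fast=replace(d.fast, k=-d.fast.k),
                slow=replace(d.slow, k=-d.slow.k),
            ),
        )
        _, rev = run_batch(mirrored, n, seed=0)
        band = 3.0 * np.sqrt(2 * 0.25 / n)
        assert abs(fwd.prop_other - (1.0 - rev.prop_other)) <= band

    def test_invalid_config_rejected(self, fig2_config):
        with pytest.raises(ConfigurationError):
            TrialConfig(dynamics=fig2_config.dynamics, threshold=-1.0)
        with pytest.raises(ConfigurationError):
            TrialConfig(dynamics=fig2_config.dynamics, max_steps=0)
        with pytest.raises(InvalidArgumentError):
            run_batch(fig2_config, 0, seed=0)


class TestSummarize:
    @staticmethod
    def _toy(outcome, winner, steps=10):
        from doublewell import TrialResult

        return TrialResult(
            states=np.zeros((steps + 1, 2)),
            accum_fast=np.zeros(steps + 1),
            accum_slow=np.zeros(steps + 1),
            outcome=outcome,
            winner=winner,
            steps=steps,
        )

    def test_all_egocentric(self):
        summary = summarize([self._toy("egocentric", "fast")] * 3)
        assert summary.prop_other == 0.0
        assert summary.n_nondecision == 0

    def test_even_mixture(self):
        trials = [self._toy("other_centric", "slow")] * 2 + [self._toy("egocentric", "fast")] * 2
        assert summarize(trials).prop_other == 0.5

    def test_nondecisions_excluded_from_proportion(self):
        trials = [self._toy("other_centric", "fast"), self._toy("none", "none", steps=50)]
        summary = summarize(trials)
        assert summary.prop_other == 1.0
        assert summary.n_nondecision == 1
        assert summary.mean_steps == 10.0

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            summarize([])

    def test_matches_independent_recount(self, fig5_config):
        results, summary = run_batch(fig5_config, 100, seed=9)
        # independent tally
        decided = [r for r in results if r.outcome != "none"]
        n_other = sum(1 for r in decided if r.outcome == "other_centric")
        assert summary.prop_other == pytest.approx(n_other / len(decided))
        assert summary.mean_steps == pytest.approx(
            sum(r.steps for r in decided) / len(decided)
        )
        assert summary.n_nondecision == len(results) - len(decided)
        for key, count in summary.counts.items():
            assert count == sum(1 for r in results if (r.outcome, r.winner) == key)


class TestTabularExport:
    def test_results_frame_shape(self, fig2_config):
        results, _ = run_batch(fig2_config, 5, seed=1)
        frame = results_to_frame(results)
        assert len(frame) == 5
        assert set(frame.columns) >= {"outcome", "winner", "steps"}

    def test_trajectory_frame_lengths(self, fig2_config):
        results, _ = run_batch(fig2_config, 3, seed=1)
        frame = trajectories_to_frame(results)
        assert len(frame) == sum(len(r.accum_fast) for r in results)
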