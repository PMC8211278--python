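"""Unit and property tests of the response-threshold simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antdol.threshold_model import (
    INACTIVE,
    ColonyState,
    SimConfig,
    TypeParams,
    response_probability,
    run_batch,
    run_simulation,
    sample_thresholds,
    step,
    update_stimuli,
)


def _pure(mu=10.0, sigma=0.1, alpha=2.0, n=16, **kw):
    return SimConfig(composition=((TypeParams("X", mu=mu, sigma=sigma, alpha=alpha), n),), **kw)


class TestSampleThresholds:
    def test_zero_sigma_is_degenerate_at_the_mean(self, rng):
        tp = TypeParams("X", mu=(10.0, 25.0), sigma=0.0)
        theta = sample_thresholds(tp, 50, rng)
        assert np.all(theta[:, 0] == 10.0) and np.all(theta[:, 1] == 25.0)

    def test_large_sample_moments_match_the_normal(self, rng):
        tp = TypeParams("X", mu=(10.0, 10.0), sigma=(0.1, 0.1))
        theta = sample_thresholds(tp, 100_000, rng)
        # Normal(10, 1) per column: LLN bounds
        assert np.allclose(theta.mean(axis=0), 10.0, atol=0.1)
        assert np.allclose(theta.std(axis=0, ddof=1), 1.0, atol=0.05)
        assert np.all(theta > 0)

    def test_columns_are_independent(self, rng):
        tp = TypeParams("X", mu=(10.0, 10.0), sigma=(0.3, 0.3))
        theta = sample_thresholds(tp, 50_000, rng)
        corr = np.corrcoef(theta[:, 0], theta[:, 1])[0, 1]
        assert abs(corr) < 0.02

    def test_positivity_enforced_under_heavy_resampling(self, rng):
        # sigma = 2: ~31% of raw draws are non-positive and must be resampled
        tp = TypeParams("X", mu=1.0, sigma=2.0)
        theta = sample_thresholds(tp, 5000, rng, m=1)
        assert np.all(theta > 0)

    def test_invalid_parameters_raise(self, rng):
        with pytest.raises(ValueError):
            sample_thresholds(TypeParams("X", mu=np.nan), 5, rng)
        with pytest.raises(ValueError):
            sample_thresholds(TypeParams("X", mu=-1.0), 5, rng)
        with pytest.raises(ValueError):
            sample_thresholds(TypeParams("X", mu=10.0), 0, rng)


class TestResponseProbability:
    @given(st.floats(0.5, 50.0), st.floats(0.1, 40.0))
    @settings(deadline=None, max_examples=50)
    def test_half_at_threshold_for_any_eta(self, theta, eta):
        assert response_probability(theta, theta, eta) == pytest.approx(0.5)

    def test_zero_stimulus_gives_zero(self):
        assert response_probability(0.0, 10.0, 7.0) == 0.0

    def test_direct_evaluation(self):
        # s=20, theta=10, eta=2 -> 400/500
        assert response_probability(20.0, 10.0, 2.0) == pytest.approx(0.8)

    def test_monotone_in_stimulus_and_threshold(self):
        s = np.linspace(0.0, 30.0, 121)
        p = response_probability(s, 10.0, 7.0)
        assert np.all(np.diff(p) >= 0)
        theta = np.linspace(0.5, 30.0, 121)
        p = response_probability(12.0, theta, 7.0)
        assert np.all(np.diff(p) <= 0)

    def test_large_eta_is_numerically_stable(self):
        assert response_probability(20.0, 10.0, 1000.0) == pytest.approx(1.0)
        assert response_probability(5.0, 10.0, 1000.0) == pytest.approx(0.0)

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            response_probability(1.0, 0.0, 7.0)
        with pytest.raises(ValueError):
            response_probability(1.0, -2.0, 7.0)


class TestUpdateStimuli:
    def test_no_active_agents_grow_by_demand(self):
        cfg = _pure(n=16, delta=(0.6, 1.1), T=10)
        s = update_stimuli(np.array([2.0, 3.0]), cfg, np.zeros((1, 2)))
        assert np.allclose(s, [2.6, 4.1])

    def test_two_type_work_term(self):
        # n=16, delta=1.3, alpha_X=4.5 (2 active), alpha_Y=2 (3 active):
        # s' = s + 1.3 - (2*4.5 + 3*2)/16 = s + 0.3625
        x = TypeParams("X", mu=11.0, alpha=4.5)
        y = TypeParams("Y", mu=10.0, alpha=2.0)
        cfg = SimConfig(composition=((x, 8), (y, 8)), delta=1.3, T=10)
        counts = np.array([[2.0, 0.0], [3.0, 0.0]])
        s = update_stimuli(np.array([5.0, 0.0]), cfg, counts)
        assert s[0] == pytest.approx(5.0 + 0.3625)

    def test_floor_at_zero(self):
        cfg = _pure(n=10, delta=0.0, T=10)
        s = update_stimuli(np.array([0.1, 0.0]), cfg, np.array([[1.0, 0.0]]))
        assert s[0] == 0.0 and s[1] == 0.0

    def test_negative_or_excess_counts_raise(self):
        cfg = _pure(n=4, T=10)
        with pytest.raises(ValueError):
            update_stimuli(np.zeros(2), cfg, np.array([[-1.0, 0.0]]))
        with pytest.raises(ValueError):
            update_stimuli(np.zeros(2), cfg, np.array([[3.0, 2.0]]))


class TestStepSemantics:
    def _state(self, cfg, task, s):
        theta = np.full((cfg.n, cfg.m), 10.0)
        return ColonyState(theta, np.asarray(task, dtype=int), np.asarray(s, dtype=float))

    def test_forced_quit_blocks_same_step_reentry(self, rng):
        # tau=1 with huge stimulus: all quit and none re-enters this step
        cfg = _pure(n=6, tau=1.0, T=10)
        state = self._state(cfg, [0, 0, 1, 1, 0, 1], [100.0, 100.0])
        new = step(state, cfg, rng)
        assert np.all(new.task_state == INACTIVE)

    def test_step_function_limit_blocks_activation(self, rng):
        # eta large, stimulus below every threshold: nobody activates
        cfg = _pure(n=6, eta=500.0, T=10)
        state = self._state(cfg, [INACTIVE] * 6, [5.0, 5.0])
        new = step(state, cfg, rng)
        assert np.all(new.task_state == INACTIVE)

    def test_single_agent_activation_probability(self, rng):
        # s = theta for both tasks (P = 0.5 each): P(active) = 1 - 0.25 = 0.75
        cfg = _pure(n=1, tau=0.0, T=10)
        trials = 4000
        active = 0
        for _ in range(trials):
            state = self._state(cfg, [INACTIVE], [10.0, 10.0])
            active += step(state, cfg, rng).task_state[0] != INACTIVE
        assert active / trials == pytest.approx(0.75, abs=0.025)

    def test_batch_engine_matches_activation_probability(self):
        # same 0.75 law via the vectorized engine (closed-form m=2 path)
        cfg = _pure(n=1, mu=10.0, sigma=0.0, tau=0.0, T=1, initial_stimulus=10.0, delta=0.0, seed=5)
        batch = run_batch(cfg, 4000)
        frac_active = (batch.task_history[:, 0, 0] != INACTIVE).mean()
        assert frac_active == pytest.approx(0.75, abs=0.025)


class TestRunSimulation:
    def test_seeded_determinism_is_bit_exact(self):
        cfg = _pure(T=500, seed=42)
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert np.array_equal(a.task_history, b.task_history)
        assert np.array_equal(a.stimulus_history, b.stimulus_history)
        assert np.array_equal(a.thresholds, b.thresholds)

    def test_replicate_stream_independent_of_batch_size(self):
        cfg = _pure(T=300, seed=7)
        small = run_batch(cfg, 3).replicate(2)
        large = run_batch(cfg, 12).replicate(2)
        assert np.array_equal(small.task_history, large.task_history)
        assert np.array_equal(small.stimulus_history, large.stimulus_history)

    def test_state_conservation_and_stimulus_floor(self, pure_x_small, mixed_small):
        for batch in (pure_x_small, mixed_small):
            hist = batch.task_history
            n = batch.config.n
            counts = (hist == INACTIVE).sum(axis=2) + (hist >= 0).sum(axis=2)
            assert np.all(counts == n)
            assert np.all(batch.stimulus_history >= 0.0)

    def test_history_shapes_and_type_labels(self, mixed_small):
        cfg = mixed_small.config
        assert mixed_small.task_history.shape == (10, cfg.T, cfg.n)
        assert mixed_small.stimulus_history.shape == (10, cfg.T, cfg.m)
        assert list(mixed_small.type_labels) == ["X"] * 8 + ["Y"] * 8

    def test_three_task_engine_path(self):
        # m=3 exercises the general sequential-order path
        tp = TypeParams("X", mu=10.0, sigma=0.1, alpha=2.0)
        cfg = SimConfig(composition=((tp, 12),), m=3, delta=0.4, T=1500, seed=3)
        batch = run_batch(cfg, 5)
        assert np.all(batch.stimulus_history >= 0.0)
        freq = np.stack([(batch.task_history == j).mean(axis=(1, 2)) for j in range(3)])
        # flux balance: per-task frequency ~ delta / alpha = 0.2
        assert np.allclose(freq.mean(axis=1), 0.2, atol=0.03)


class TestStationaryRegimes:
    @pytest.mark.parametrize("eta", [2.0, 7.0, 20.0])
    @pytest.mark.parametrize("tau", [0.1, 0.2, 0.3])
    def test_flux_balance_across_eta_and_tau(self, eta, tau):
        # stationary per-task performance frequency = delta / alpha
        cfg = _pure(eta=eta, tau=tau, delta=0.6, T=2000, seed=100)
        batch = run_batch(cfg, 5)
        half = cfg.T // 2
        freq = np.stack(
            [(batch.task_history[:, half:] == j).mean(axis=(1, 2)) for j in range(2)]
        )
        assert np.allclose(freq.mean(axis=1), 0.3, atol=0.03)

    def test_capacity_law_stable_vs_unstable(self):
        # pure colony stabilizes iff m * delta <= alpha
        stable = run_batch(_pure(alpha=2.0, delta=0.6, T=1000, seed=1), 5)
        unstable = run_batch(_pure(alpha=2.0, delta=1.3, T=1000, seed=1), 5)
        s_stable = stable.stimulus_history
        s_unstable = unstable.stimulus_history
        assert s_unstable[:, -1].mean() > 3 * s_unstable[:, 499].mean() / 2
        assert s_stable[:, -1].mean() < s_stable[:, 499].mean() * 1.5
        assert s_unstable[:, -1].mean() > 10 * s_stable[:, -1].max()

    def test_raising_mu_does_not_increase_activity(self):
        # paired over seeds: higher thresholds => no more task performance
        freqs = {}
        for mu in (10.0, 14.0):
            vals = []
            for seed in range(6):
                batch = run_batch(_pure(mu=mu, T=1500, seed=seed), 4)
                vals.append((batch.task_history >= 0).mean())
            freqs[mu] = np.array(vals)
        assert np.all(freqs[14.0] <= freqs[10.0] + 1e-9)


class TestConfigValidation:
    def test_invalid_configs_raise(self):
        tp = TypeParams("X", mu=10.0)
        with pytest.raises(ValueError):
            SimConfig(composition=((tp, 0),))  # n = 0
        with pytest.raises(ValueError):
            SimConfig(composition=((tp, 4),), tau=1.5)
        with pytest.raises(ValueError):
            SimConfig(composition=((tp, 4),), T=0)
        with pytest.raises(ValueError):
            SimConfig(composition=((tp, 4),), delta=-0.1)
        with pytest.raises(ValueError):
            SimConfig(composition=((tp, 4),), eta=0.0)
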