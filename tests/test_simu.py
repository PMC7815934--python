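"""Integrate-and-fire simulator and Spearman-window microcircuit builder."""

import itertools
import math

import numpy as np
import pytest

from wgevia import (
    NeuronParams,
    SimulationConfig,
    build_microcircuits,
    generate_simu_dataset,
    simulate_condition,
    spearman_corr,
)
from wgevia.simu import ActivityTrace


def quiet_config(**kw) -> SimulationConfig:
    defaults = dict(n_a=5, n_b=5, duration=100, stimulus_rate=0.0, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestIntegrator:
    def test_noiseless_unstimulated_network_stays_at_rest(self):
        params = NeuronParams(sigma=0.0)
        trace = simulate_condition(quiet_config(), params)
        assert np.all(trace.potentials == params.rho_rest)
        assert not trace.spikes.any()

    def test_noiseless_decay_matches_closed_form(self):
        # With rho(0) = rho0 and no input, Euler integration of the leak
        # gives rho(t) = rho0 * (1 - dt/tau)^t, which must track the exact
        # exponential rho0 * exp(-t/tau) to within Euler error.
        params = NeuronParams(sigma=0.0, tau=20.0, dt=1.0, spike_threshold=10.0)
        rho0 = 1.0
        rho = rho0
        for _ in range(20):  # integrate for t = tau
            rho += params.dt * (params.rho_rest - rho) / params.tau
        assert rho == pytest.approx(rho0 * (1 - 1 / 20) ** 20)
        assert abs(rho - rho0 * math.exp(-1)) < 0.02

        # The simulator applies the same update rule: under a deterministic
        # subthreshold kick every step, the trace must follow the recursion
        # rho_{t+1} = rho_t (1 - dt/tau) + amplitude exactly.
        cfg = quiet_config(stimulus_rate=1.0, stimulus_amplitude=0.5, duration=30)
        trace = simulate_condition(cfg, params)
        expected, seq = 0.0, []
        for _ in range(30):
            expected = expected * (1 - 1 / 20) + 0.5
            seq.append(expected)
        assert np.allclose(trace.potentials[0], seq)

    def test_deterministic_given_seed(self):
        cfg = quiet_config(stimulus_rate=0.1, seed=5)
        t1 = simulate_condition(cfg)
        t2 = simulate_condition(cfg)
        assert np.array_equal(t1.potentials, t2.potentials)
        assert np.array_equal(t1.spikes, t2.spikes)

    def test_refractory_period_enforces_spike_spacing(self):
        cfg = quiet_config(stimulus_rate=1.0, stimulus_amplitude=2.0, duration=50, seed=1)
        params = NeuronParams(sigma=0.0, refractory=2)
        trace = simulate_condition(cfg, params)
        for row in trace.spikes[: cfg.n_a]:
            times = np.flatnonzero(row)
            assert np.all(np.diff(times) > params.refractory)

    def test_condition_two_is_more_coherent_across_groups(self):
        # Denser A->B parentage (condition 2) must raise the mean A-B
        # correlation relative to condition 1, averaged over seeds.
        def mean_ab_corr(condition, seed):
            cfg = SimulationConfig(
                n_a=20, n_b=20, condition=condition, duration=200, seed=seed
            )
            d = build_microcircuits(simulate_condition(cfg), window=40)
            vals = []
            for m in d.members:
                vals.extend(
                    w for (i, j), w in m.weights.items() if i <= 20 < j
                )
            return np.mean(vals)

        c1 = np.mean([mean_ab_corr(1, s) for s in range(5)])
        c2 = np.mean([mean_ab_corr(2, s) for s in range(5)])
        assert c2 > c1


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.arange(1.0, 9.0)
        assert spearman_corr(x, x**2) == pytest.approx(1.0)
        assert spearman_corr(x, -x) == pytest.approx(-1.0)

    def test_known_small_example(self):
        # d^2 sum = 2 -> 1 - 6*2/(4*15) = 0.8
        assert spearman_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_series_is_undefined(self):
        assert math.isnan(spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_matches_rank_formula_on_all_permutations(self):
        # Independent oracle: 1 - 6 sum(d^2) / (n (n^2 - 1)) on untied ranks.
        x = [1.0, 2.0, 3.0, 4.0]
        for perm in itertools.permutations([1, 2, 3, 4]):
            d2 = sum((xi - yi) ** 2 for xi, yi in zip([1, 2, 3, 4], perm))
            expected = 1 - 6 * d2 / (4 * (16 - 1))
            assert spearman_corr(x, list(map(float, perm))) == pytest.approx(expected)

    def test_rejects_short_or_mismatched_input(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            spearman_corr([1.0, 2.0, 3.0], [1.0, 2.0])


class TestMicrocircuitBuilder:
    def test_one_graph_per_window(self):
        cfg = quiet_config(stimulus_rate=0.2, duration=80, seed=3)
        trace = simulate_condition(cfg)
        d = build_microcircuits(trace, window=40)
        assert len(d) == 2
        n = cfg.n_neurons
        assert all(m.graph.edge_count == n * (n - 1) // 2 for m in d.members)

    def test_weights_are_valid_correlations(self):
        cfg = quiet_config(stimulus_rate=0.2, duration=120, seed=4)
        d = build_microcircuits(simulate_condition(cfg), window=40)
        for m in d.members:
            for w in m.weights.values():
                assert -1.0 <= w <= 1.0

    def test_identical_segments_give_identical_microcircuits(self):
        seg = np.random.default_rng(0).random((4, 40))
        trace = ActivityTrace(
            potentials=np.hstack([seg, seg]), spikes=np.zeros((4, 80), dtype=bool)
        )
        d = build_microcircuits(trace, window=40)
        assert d.members[0].weights == d.members[1].weights

    def test_window_longer_than_trace_rejected(self):
        trace = simulate_condition(quiet_config(duration=30))
        with pytest.raises(ValueError):
            build_microcircuits(trace, window=40)

    def test_independent_noise_pairs_have_small_weights(self):
        # Null check: uncorrelated white-noise neurons should rarely exceed
        # |w| = 0.3 at window 40.
        rng = np.random.default_rng(11)
        trace = ActivityTrace(
            potentials=rng.standard_normal((10, 400)),
            spikes=np.zeros((10, 400), dtype=bool),
        )
        d = build_microcircuits(trace, window=40)
        weights = np.array([w for m in d.members for w in m.weights.values()])
        assert np.mean(np.abs(weights) < 0.3) >= 0.95


class TestDatasetGenerator:
    def test_counts_labels_and_determinism(self):
        cfg = SimulationConfig(n_a=6, n_b=6, window=20)
        d1 = generate_simu_dataset(3, 4, cfg, seed=9)
        assert len(d1) == 7
        assert d1.labels == [0, 0, 0, 1, 1, 1, 1]
        d2 = generate_simu_dataset(3, 4, cfg, seed=9)
        assert all(
            a.weights == b.weights for a, b in zip(d1.members, d2.members)
        )

    def test_rejects_empty_conditions(self):
        with pytest.raises(ValueError):
            generate_simu_dataset(0, 1)
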