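"""Simulator and initializer tests, each checked against an independent oracle."""

import numpy as np
import pytest

from pspm.models import (
    LIFParams,
    WeightMatrix,
    build_pif_network,
    draw_sign_mask,
    generate_lif_inputs,
    generate_pif_inputs,
    init_weights,
    normalize_spectral_radius,
    simulate_lif,
    simulate_pif,
)


def lif_loop_oracle(w_volts, currents, params):
    """Straightforward per-neuron, per-step LIF integration (no vectorization)."""
    t_steps, n = currents.shape
    alpha = params.dt / params.tau_m
    w_mv = w_volts * 1e3
    spikes = np.zeros((t_steps, n), dtype=np.uint8)
    v = [0.0] * n
    s_prev = [0.0] * n
    for t in range(t_steps):
        v_new = []
        for i in range(n):
            syn = sum(w_mv[i][j] * s_prev[j] for j in range(n))
            vi = v[i] + alpha * (-v[i] + params.r_m * currents[t, i] * 1e9 + syn)
            if vi >= params.v_th:
                spikes[t, i] = 1
                vi = 0.0
            v_new.append(vi)
        v = v_new
        s_prev = [float(x) for x in spikes[t]]
    return spikes


class TestSimulateLIF:
    def test_zero_weights_zero_input_is_fixed_point(self):
        n = 3
        w = WeightMatrix(np.zeros((n, n)), np.zeros(n, bool))
        spikes, volts = simulate_lif(w, np.zeros((20, n)), LIFParams(n=n))
        assert not spikes.any()
        assert np.all(volts == 0.0)

    def test_single_neuron_periodic_spiking_matches_scalar_recurrence(self):
        # R_m * I = 40 mV > threshold: hand-iterate v <- v + 0.1 (40 - v).
        params = LIFParams(n=1)
        current = 4e-10
        t_steps = 60
        v, expected_spike_steps = 0.0, []
        for t in range(t_steps):
            v = v + 0.1 * (40.0 - v)
            if v >= 30.0:
                expected_spike_steps.append(t)
                v = 0.0
        w = WeightMatrix(np.zeros((1, 1)), np.zeros(1, bool))
        spikes, _ = simulate_lif(w, np.full((t_steps, 1), current), params)
        assert expected_spike_steps  # the oracle must actually spike
        assert list(np.flatnonzero(spikes[:, 0])) == expected_spike_steps
        # periodic after the first spike
        gaps = np.diff(expected_spike_steps)
        assert len(set(gaps)) == 1

    def test_excitatory_chain_fires_one_step_after_upstream(self):
        # Neuron 0 is forced by a single current pulse; the 0->1 weight alone
        # clears the threshold gap, so neuron 1 fires exactly one step later.
        n = 3
        w = np.zeros((n, n))
        w[1, 0] = 0.5  # volts: dt/tau * 500 mV = 50 mV > v_th
        wm = WeightMatrix(w, np.zeros(n, bool))
        currents = np.zeros((6, n))
        currents[1, 0] = 4e-9  # R_m I = 400 mV for one step
        spikes, _ = simulate_lif(wm, currents, LIFParams(n=n))
        assert list(np.flatnonzero(spikes[:, 0])) == [1]
        assert list(np.flatnonzero(spikes[:, 1])) == [2]
        assert not spikes[:, 2].any()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_naive_loop_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n, t_steps = 5, 50
        mask = draw_sign_mask(n, 0.2, gen)
        mags = gen.uniform(0, 5e-3, (n, n))
        w = np.where(mask[None, :], -mags, mags)
        np.fill_diagonal(w, 0.0)
        wm = WeightMatrix(w, mask)
        currents = gen.normal(2.5e-10, 1e-10, (t_steps, n))
        params = LIFParams(n=n)
        spikes, _ = simulate_lif(wm, currents, params)
        assert np.array_equal(spikes, lif_loop_oracle(w, currents, params))

    def test_deterministic_and_does_not_mutate_weights(self, rng):
        n = 4
        mask = draw_sign_mask(n, 0.25, rng)
        wm = init_weights("uniform", "reference", n, rng=rng, inhibitory=mask)
        before = wm.w.copy()
        currents = generate_lif_inputs(40, n, rng=rng)
        s1, v1 = simulate_lif(wm, currents, LIFParams(n=n))
        s2, v2 = simulate_lif(wm, currents, LIFParams(n=n))
        assert np.array_equal(s1, s2) and np.array_equal(v1, v2)
        assert np.array_equal(wm.w, before)

    def test_recorded_voltages_stay_below_threshold(self, rng):
        n = 2
        wm = WeightMatrix(np.zeros((n, n)), np.zeros(n, bool))
        currents = rng.normal(4e-10, 2e-10, (200, n))
        _, volts = simulate_lif(wm, currents, LIFParams(n=n))
        assert np.all(volts < LIFParams(n=n).v_th)

    def test_dimension_mismatch_raises(self):
        wm = WeightMatrix(np.zeros((3, 3)), np.zeros(3, bool))
        with pytest.raises(ValueError):
            simulate_lif(wm, np.zeros((10, 4)), LIFParams(n=3))

    def test_nonfinite_inputs_raise(self):
        wm = WeightMatrix(np.zeros((2, 2)), np.zeros(2, bool))
        bad = np.zeros((5, 2))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError):
            simulate_lif(wm, bad, LIFParams(n=2))

    def test_zero_weight_rate_is_small_and_synapse_dominated(self):
        # External drive alone produces sparse firing; synaptic currents,
        # once enabled, dominate the output rate.
        n, t_steps = 100, 3000
        mask = draw_sign_mask(n, 0.2, 7)
        w0 = WeightMatrix(np.zeros((n, n)), mask)
        currents = generate_lif_inputs(t_steps, n, rng=8)
        s0, _ = simulate_lif(w0, currents, LIFParams(n=n))
        rate0 = s0.mean()
        assert 0.0 < rate0 < 0.01  # well under 3.3 Hz at a 3 ms step
        wu = init_weights("uniform", "reference", n, rng=9, inhibitory=mask)
        su, _ = simulate_lif(wu, currents, LIFParams(n=n))
        assert su.mean() > 3 * rate0


class TestSimulatePIF:
    def test_saturating_input_fires_every_neuron_every_step(self):
        n = 4
        w = WeightMatrix(np.zeros((n, n)), np.zeros(n, bool))
        spikes = simulate_pif(w, np.full((10, n), 1.5), rng=0)
        assert not spikes[0].any()  # quiescent initial state
        assert spikes[1:].all()

    def test_zero_input_zero_weights_is_silent(self):
        w = WeightMatrix(np.zeros((3, 3)), np.zeros(3, bool))
        assert not simulate_pif(w, np.zeros((50, 3)), rng=1).any()

    def test_isolated_neuron_matches_bernoulli_rate(self):
        t_steps, p = 100_000, 0.3
        w = WeightMatrix(np.zeros((1, 1)), np.zeros(1, bool))
        spikes = simulate_pif(w, np.full((t_steps, 1), p), rng=2)
        rate = spikes[1:].mean()
        se = np.sqrt(p * (1 - p) / (t_steps - 1))
        assert abs(rate - p) < 3 * se

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            simulate_pif(np.array([[0.0, -0.1], [0.0, 0.0]]), np.zeros((5, 2)))

    def test_reproducible_under_fixed_seed(self):
        w = build_pif_network(20, 0.3, (0, 0.1), rng=3)
        inputs = generate_pif_inputs(200, 20, rng=4)
        assert np.array_equal(simulate_pif(w, inputs, rng=5), simulate_pif(w, inputs, rng=5))


class TestBuildPIFNetwork:
    def test_spectral_radius_is_one(self):
        w = build_pif_network(100, 0.1, (0, 0.02), rng=0)
        lam = np.max(np.abs(np.linalg.eigvals(w.w)))
        assert abs(lam - 1.0) < 1e-9

    def test_density_near_connection_probability(self):
        n, p = 400, 0.1
        w = build_pif_network(n, p, (0, 0.02), rng=1)
        density = np.count_nonzero(w.w) / (n * n - n)
        se = np.sqrt(p * (1 - p) / (n * n - n))
        assert abs(density - p) < 3 * se

    def test_fixed_two_neuron_matrix_rescales_to_unit_eigenvalue(self):
        w = normalize_spectral_radius(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert np.allclose(w, [[0.0, 1.0], [1.0, 0.0]])

    def test_normalization_is_idempotent(self):
        w = build_pif_network(50, 0.2, (0, 0.05), rng=2)
        assert np.allclose(normalize_spectral_radius(w.w), w.w)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            normalize_spectral_radius(np.zeros((3, 3)))


class TestInitWeights:
    def test_naive_half_max_bounds(self):
        w = init_weights("naive-half-max", "naive", 50, rng=0)
        assert np.abs(w.w).max() <= 2.5e-3
        w_ref = init_weights("naive-half-max", "reference", 50, rng=0)
        assert np.abs(w_ref.w).max() > 2.5e-3  # full-range reference

    def test_sparse_naive_zeroes_exactly_half(self):
        n = 30
        w = init_weights("sparse", "naive", n, rng=1)
        off_diag = ~np.eye(n, dtype=bool)
        assert np.count_nonzero(w.w[off_diag] == 0.0) == (n * n) // 2

    def test_gaussian_magnitudes_follow_truncated_normal(self):
        from scipy.stats import norm

        w = init_weights("gaussian", "naive", 60, rng=2)
        assert np.all(np.abs(w.w) >= 0)
        mags = np.abs(w.w[~np.eye(60, dtype=bool)])
        # redrawing below 0 gives a left-truncated normal; closed-form mean
        mu, sigma = 0.4e-3, 0.4e-3
        expected = mu + sigma * norm.pdf(-mu / sigma) / norm.cdf(mu / sigma)
        assert abs(mags.mean() - expected) < 4 * sigma / np.sqrt(mags.size)

    def test_sign_structure_and_zero_diagonal(self):
        mask = draw_sign_mask(40, 0.2, 3)
        w = init_weights("uniform", "reference", 40, rng=4, inhibitory=mask)
        assert np.all(w.w[:, mask] <= 0)
        assert np.all(w.w[:, ~mask] >= 0)
        assert np.all(np.diag(w.w) == 0)
        assert mask.sum() == 8

    def test_seeding_contract(self):
        a = init_weights("uniform", "naive", 20, rng=5)
        b = init_weights("uniform", "naive", 20, rng=5)
        c = init_weights("uniform", "naive", 20, rng=6)
        assert np.array_equal(a.w, b.w)
        assert not np.array_equal(a.w, c.w)

    def test_unknown_config_rejected(self):
        with pytest.raises(ValueError):
            init_weights("lognormal", "naive", 10, rng=0)


class TestInputGenerators:
    def test_lif_input_moments(self):
        x = generate_lif_inputs(1000, 1000, rng=0)
        se = 1e-10 / np.sqrt(x.size)
        assert abs(x.mean() - 2.5e-10) < 4 * se

    def test_lif_sigma_zero_is_constant(self):
        x = generate_lif_inputs(10, 4, sigma=0.0, rng=1)
        assert np.all(x == 2.5e-10)

    def test_pif_input_mean_and_zero_scale(self):
        x = generate_pif_inputs(2000, 500, rng=2)
        se = 1e-3 / np.sqrt(x.size)  # Poisson(1) has unit variance
        assert abs(x.mean() - 1e-3) < 4 * se
        assert not generate_pif_inputs(10, 4, scale=0.0, rng=3).any()

    def test_driven_pif_network_rate_exceeds_floor(self):
        w = build_pif_network(200, 0.1, (0, 0.02), rng=4)
        inputs = generate_pif_inputs(3000, 200, rng=5)
        spikes = simulate_pif(w, inputs, rng=6)
        assert spikes.mean() > 0.003


class TestWeightMatrixInvariants:
    def test_sign_violations_rejected(self):
        w = np.array([[0.0, 0.5], [-0.1, 0.0]])
        with pytest.raises(ValueError):
            WeightMatrix(w, np.array([False, False]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            WeightMatrix(np.eye(3), np.zeros(3, bool))
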