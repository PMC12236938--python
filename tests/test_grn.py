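"""Unit tests for the GRN/SDE synthetic-data generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from profet.grn import (DEFAULT_RANGES, GRNModel, default_emt_topology, drift,
                        sample_parameter_ensemble, shifted_hill,
                        simulate_euler_maruyama, subsample_snapshots)


class TestShiftedHill:
    def test_no_regulator_gives_unity(self):
        assert shifted_hill(0.0, lam=0.3, theta=2.0, n=4) == pytest.approx(1.0)

    def test_half_occupancy_at_threshold(self):
        for lam in (0.2, 1.0, 5.0):
            assert shifted_hill(2.0, lam=lam, theta=2.0, n=3) == pytest.approx((1 + lam) / 2)

    def test_neutral_fold_change_is_identity(self):
        x = np.linspace(0, 10, 25)
        assert shifted_hill(x, lam=1.0, theta=1.5, n=2) == pytest.approx(np.ones_like(x))

    @pytest.mark.parametrize("lam", [0.1, 0.9, 3.0, 10.0])
    def test_bounded_between_one_and_fold_change(self, lam, rng):
        x = rng.uniform(0, 50, size=200)
        h = shifted_hill(x, lam=lam, theta=1.0, n=3)
        assert np.all(h >= min(1.0, lam) - 1e-12)
        assert np.all(h <= max(1.0, lam) + 1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(0, 1e6), lam=st.floats(0.01, 50.0),
           theta=st.floats(1e-3, 1e3), n=st.integers(1, 8))
    def test_bounds_hold_for_arbitrary_parameters(self, x, lam, theta, n):
        h = float(shifted_hill(x, lam, theta, n))
        assert min(1.0, lam) - 1e-9 <= h <= max(1.0, lam) + 1e-9

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            shifted_hill(1.0, lam=0.5, theta=0.0, n=2)
        with pytest.raises(ValueError):
            shifted_hill(1.0, lam=0.5, theta=1.0, n=0)


class TestDrift:
    def test_unregulated_fixed_point(self, unregulated_model):
        x = unregulated_model.g / unregulated_model.k
        assert drift(x, unregulated_model) == pytest.approx(np.zeros(3), abs=1e-12)

    def test_unregulated_origin_gives_production(self, unregulated_model):
        assert drift(np.zeros(3), unregulated_model) == pytest.approx(unregulated_model.g)

    def test_saturated_inhibitor_limit(self, two_gene_model):
        m = two_gene_model
        x = np.array([1.0, 1e6 * m.theta[0, 1]])
        limit = m.g[0] * m.lam[0, 1] - m.k[0] * x[0]
        assert drift(x, m)[0] == pytest.approx(limit, rel=1e-3)

    def test_dimension_mismatch(self, two_gene_model):
        with pytest.raises(ValueError):
            drift(np.zeros(3), two_gene_model)


class TestEulerMaruyama:
    def test_zero_duration_returns_start(self, two_gene_model):
        x0 = np.array([1.0, 2.0])
        out = simulate_euler_maruyama(two_gene_model, x0, dt=0.01, t_end=0.0, seed=0)
        assert out.values.shape == (1, 1, 2)
        assert out.values[0, 0] == pytest.approx(x0)

    def test_deterministic_limit_matches_finer_euler(self, two_gene_model):
        """With D=0 the scheme is plain Euler; global error shrinks ~linearly in dt."""
        x0 = np.array([0.5, 3.0])
        coarse = simulate_euler_maruyama(two_gene_model, x0, dt=0.05, t_end=2.0, seed=0)
        fine = simulate_euler_maruyama(two_gene_model, x0, dt=0.005, t_end=2.0, seed=0)
        err = np.abs(coarse.values[0, -1] - fine.values[0, -1]).max()
        assert err < 0.05  # O(dt) global error on an O(1) solution

    def test_seed_reproducibility(self, two_gene_model):
        m = GRNModel(**{**two_gene_model.__dict__, "D": 0.5})
        a = simulate_euler_maruyama(m, np.ones(2), dt=0.01, t_end=1.0, seed=42)
        b = simulate_euler_maruyama(m, np.ones(2), dt=0.01, t_end=1.0, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_dt(self, two_gene_model):
        with pytest.raises(ValueError):
            simulate_euler_maruyama(two_gene_model, np.ones(2), dt=0.0, t_end=1.0, seed=0)

    def test_unregulated_converges_to_steady_state(self, unregulated_model):
        m = unregulated_model
        t_end = 20.0 / m.k.min()
        out = simulate_euler_maruyama(m, np.array([10.0, 0.0, 5.0]), dt=0.01,
                                      t_end=t_end, seed=0)
        assert out.values[0, -1] == pytest.approx(m.g / m.k, abs=1e-6)

    def test_noisy_ensemble_mean_tracks_deterministic(self, two_gene_model):
        """Replicate mean at small t stays within 3 standard errors of the ODE."""
        m = GRNModel(**{**two_gene_model.__dict__, "D": 0.3})
        x0 = np.tile([1.0, 1.0], (600, 1))
        sim = simulate_euler_maruyama(m, x0, dt=0.01, t_end=0.5, seed=3)
        det = simulate_euler_maruyama(two_gene_model, np.array([1.0, 1.0]),
                                      dt=0.01, t_end=0.5, seed=0)
        mean = sim.values[:, -1, :].mean(axis=0)
        se = sim.values[:, -1, :].std(axis=0, ddof=1) / np.sqrt(600)
        assert np.all(np.abs(mean - det.values[0, -1]) < 3 * se + 1e-9)


class TestParameterEnsemble:
    def test_degenerate_ranges_fully_determine_model(self):
        J = np.array([[0, 1], [-1, 0]])
        ranges = {"g": (5.0, 5.0), "k": (0.5, 0.5), "lam_act": (2.0, 2.0),
                  "lam_inh": (0.3, 0.3), "theta": (1.0, 1.0), "n": (2, 2)}
        (m,) = sample_parameter_ensemble(J, 1, ranges=ranges, seed=0)
        assert m.g == pytest.approx([5.0, 5.0])
        assert m.lam[0, 1] == 2.0 and m.lam[1, 0] == 0.3
        assert m.theta[0, 1] == pytest.approx(5.0 / 0.5)  # 1.0 x regulator steady state
        assert m.n[0, 1] == 2

    def test_fold_change_ranges_respect_edge_signs(self):
        J, _ = default_emt_topology()
        models = sample_parameter_ensemble(J, 5, seed=1)
        for m in models:
            assert (m.lam[J == 1] > 1).all()
            assert ((m.lam[J == -1] > 0) & (m.lam[J == -1] < 1)).all()

    def test_production_rate_marginal_is_uniform(self):
        J = np.zeros((4, 4), dtype=int)
        models = sample_parameter_ensemble(J, 100, seed=7)
        g = np.array([m.g for m in models]).ravel()
        lo, hi = DEFAULT_RANGES["g"]
        stat = stats.kstest(g, stats.uniform(lo, hi - lo).cdf).statistic
        # critical value at alpha = 0.01 for n = 400
        assert stat < 1.628 / np.sqrt(g.size)

    def test_inverted_range_raises(self):
        with pytest.raises(ValueError):
            sample_parameter_ensemble(np.zeros((2, 2), dtype=int), 1,
                                      ranges={"g": (10.0, 1.0)}, seed=0)


class TestSubsampling:
    def test_full_grid_round_trips(self, two_gene_model):
        sim = simulate_euler_maruyama(two_gene_model, np.ones((4, 2)), dt=0.1,
                                      t_end=1.0, seed=0)
        series = subsample_snapshots(sim, sim.times)
        for i in range(sim.times.size):
            np.testing.assert_array_equal(series.matrices[i], sim.values[:, i, :])

    def test_nearest_grid_ties_resolve_earlier(self, two_gene_model):
        sim = simulate_euler_maruyama(two_gene_model, np.ones((2, 2)), dt=0.1,
                                      t_end=1.0, seed=0)
        series = subsample_snapshots(sim, [0.05])  # equidistant from 0.0 and 0.1
        np.testing.assert_array_equal(series.matrices[0], sim.values[:, 0, :])

    def test_time_outside_range_raises(self, two_gene_model):
        sim = simulate_euler_maruyama(two_gene_model, np.ones(2), dt=0.1, t_end=1.0, seed=0)
        with pytest.raises(ValueError):
            subsample_snapshots(sim, [1.5])


class TestTopologyFile:
    def test_packaged_emt_network_shape(self):
        J, genes = default_emt_topology()
        assert J.shape == (26, 26)
        assert len(genes) == 26
        assert np.isin(J, (-1, 0, 1)).all()
        assert (J != 0).any(axis=1).sum() > 20  # most genes are regulated


def test_model_invariant_validation():
    J = np.array([[0, 1], [0, 0]])
    bad_lam = np.ones((2, 2)) * 0.5  # activation edge needs lam > 1
    with pytest.raises(ValueError):
        GRNModel(J=J, g=np.ones(2), k=np.ones(2), lam=bad_lam,
                 theta=np.ones((2, 2)), n=np.ones((2, 2)))
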