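"""Unit tests for the Lipschitz-regularized gradient-flow particle transport."""

import numpy as np
import pytest
from scipy import optimize

from profet.gpa import (GPAConfig, LipschitzPotential, ParticleSet,
                        VelocitySampleSet, euler_step, fit_potential, fstar,
                        kinetic_energy, run_gpa, variational_objective)

FAST = GPAConfig(inner_iters=40, max_iters=60, seed=0)


def constant_potential(dim: int, c: float, L: float = 1.0) -> LipschitzPotential:
    phi = LipschitzPotential(dim, L=L, seed=0)
    phi.net.W = [np.zeros_like(W) for W in phi.net.W]
    phi.net.b = [np.zeros_like(b) for b in phi.net.b]
    phi.net.b[-1][:] = c / L
    return phi


class _LinearPhi:
    """Duck-typed potential phi(x) = a . x used for exact-gradient checks."""

    def __init__(self, a):
        self.a = np.asarray(a, dtype=float)

    def gradient(self, X):
        return np.tile(self.a, (np.atleast_2d(X).shape[0], 1))


class TestFStar:
    def test_known_values(self):
        assert fstar(1.0) == pytest.approx(1.0)
        assert fstar(0.0) == pytest.approx(np.exp(-1.0))

    def test_convexity_on_random_pairs(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert np.all(fstar(0.5 * (a + b)) <= 0.5 * (fstar(a) + fstar(b)) + 1e-12)


class TestVariationalObjective:
    def test_zero_potential(self, rng):
        phi = constant_potential(1, 0.0)
        src, tgt = rng.normal(size=(10, 1)), rng.normal(size=(12, 1))
        assert variational_objective(phi, src, tgt) == pytest.approx(-np.exp(-1.0))

    def test_constant_potential_maximum_at_one(self, rng):
        src, tgt = rng.normal(size=(10, 1)), rng.normal(size=(10, 1))
        vals = {c: variational_objective(constant_potential(1, c, L=2.0), src, tgt)
                for c in (-1.0, 0.0, 0.5, 1.0, 1.5)}
        for c, v in vals.items():
            assert v == pytest.approx(c - np.exp(c - 1.0))
        assert max(vals, key=vals.get) == 1.0
        assert vals[1.0] == pytest.approx(0.0)

    def test_empty_sets_rejected(self):
        phi = constant_potential(1, 0.0)
        with pytest.raises(ValueError):
            variational_objective(phi, np.empty((0, 1)), np.ones((2, 1)))


def _oracle_1d_divergence(src, tgt, L=1.0, grid_size=120):
    """Concave maximization over discretized 1-Lipschitz potentials.

    phi is piecewise linear on a shared grid with slope constraints; the
    objective is concave in the node values, so a local optimum is global.
    """
    pts = np.concatenate([src.ravel(), tgt.ravel()])
    grid = np.linspace(pts.min() - 0.5, pts.max() + 0.5, grid_size)
    dx = grid[1] - grid[0]

    def interp(vals, x):
        return np.interp(x, grid, vals)

    def neg_obj(vals):
        return -(interp(vals, src.ravel()).mean()
                 - np.exp(interp(vals, tgt.ravel()) - 1.0).mean())

    cons = optimize.LinearConstraint(
        np.diff(np.eye(grid_size), axis=0), -L * dx, L * dx)
    res = optimize.minimize(neg_obj, np.zeros(grid_size), constraints=[cons],
                            method="SLSQP", options={"maxiter": 300})
    return -res.fun


class TestFitPotential:
    def test_identical_samples_give_small_divergence(self, rng):
        X = rng.normal(size=(60, 1))
        phi = fit_potential(X, X, FAST)
        assert variational_objective(phi, X, X) <= 0.05

    def test_matches_discretized_oracle_on_separated_gaussians(self, rng):
        src = rng.normal(0.0, 1.0, size=(80, 1))
        tgt = rng.normal(4.0, 1.0, size=(80, 1))
        cfg = GPAConfig(inner_iters=400, seed=0)
        phi = fit_potential(src, tgt, cfg)
        fitted = variational_objective(phi, src, tgt)
        oracle = _oracle_1d_divergence(src, tgt)
        assert fitted > 0
        assert fitted == pytest.approx(oracle, rel=0.2)

    def test_seed_reproducibility(self, rng):
        src, tgt = rng.normal(size=(20, 1)), rng.normal(loc=2.0, size=(20, 1))
        phi1 = fit_potential(src, tgt, FAST)
        phi2 = fit_potential(src, tgt, FAST)
        for W1, W2 in zip(phi1.net.W, phi2.net.W):
            np.testing.assert_array_equal(W1, W2)


class TestEulerStep:
    def test_linear_potential_moves_uniformly(self, rng):
        a = np.array([0.3, -0.7])
        particles = ParticleSet(positions=rng.normal(size=(15, 2)))
        moved = euler_step(particles, _LinearPhi(a), dt=0.1)
        np.testing.assert_allclose(moved.positions, particles.positions - 0.1 * a)
        assert moved.iteration == 1

    def test_zero_gradient_is_stationary(self, rng):
        particles = ParticleSet(positions=rng.normal(size=(5, 2)))
        moved = euler_step(particles, _LinearPhi([0.0, 0.0]), dt=0.5)
        np.testing.assert_array_equal(moved.positions, particles.positions)

    def test_autodiff_matches_finite_differences(self, rng):
        phi = LipschitzPotential(3, L=1.0, seed=4)
        X = rng.normal(size=(6, 3))
        grad = phi.gradient(X)
        h = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            fd = (phi(X + e) - phi(X - e)) / (2 * h)
            np.testing.assert_allclose(grad[:, j], fd, atol=1e-4)


class TestKineticEnergy:
    def test_constant_potential_is_zero(self, rng):
        particles = ParticleSet(positions=rng.normal(size=(10, 2)))
        assert kinetic_energy(particles, constant_potential(2, 1.5)) == pytest.approx(0.0)

    def test_linear_potential_gives_squared_slope(self, rng):
        a = np.array([0.6, -0.8])
        particles = ParticleSet(positions=rng.normal(size=(10, 2)))
        grad = _LinearPhi(a).gradient(particles.positions)
        assert (grad ** 2).sum(axis=1).mean() == pytest.approx(1.0)

    def test_decays_over_gaussian_transport(self, rng):
        src = rng.normal(0, 1, (80, 1))
        tgt = rng.normal(2.5, 1, (80, 1))
        res = run_gpa(src, tgt, GPAConfig(inner_iters=40, max_iters=50, seed=1))
        assert res.kinetic[-1] < res.kinetic[0]


class TestRunGPA:
    def test_identical_snapshots_stop_immediately(self, rng):
        X = rng.normal(size=(50, 2))
        res = run_gpa(X, X, FAST)
        assert res.n_iters <= 1
        assert len(res.velocities) <= 50

    def test_velocity_record_bookkeeping(self, rng):
        src = rng.normal(0, 1, (40, 1))
        tgt = rng.normal(3, 1, (40, 1))
        res = run_gpa(src, tgt, GPAConfig(inner_iters=30, max_iters=25, seed=2))
        assert len(res.velocities) == 40 * res.n_iters
        # local time labels are n * dt
        np.testing.assert_allclose(np.unique(res.velocities.t),
                                   np.arange(res.n_iters) * 0.1)

    def test_transports_gaussian_mean(self, rng):
        src = rng.normal(0, 1, (80, 1))
        tgt = rng.normal(3, 1, (80, 1))
        res = run_gpa(src, tgt, GPAConfig(inner_iters=40, max_iters=80, seed=3))
        assert abs(res.particles.positions.mean() - 3.0) < 0.7

    def test_speed_bound_certified(self, rng):
        src = rng.normal(0, 1, (40, 2))
        tgt = rng.normal(2, 1, (40, 2))
        res = run_gpa(src, tgt, GPAConfig(inner_iters=30, max_iters=30, seed=4))
        speeds = np.linalg.norm(res.velocities.v, axis=1)
        assert speeds.max() <= 1.0 + 1e-3

    def test_full_run_is_reproducible(self, rng):
        src = rng.normal(0, 1, (30, 1))
        tgt = rng.normal(2, 1, (30, 1))
        r1 = run_gpa(src, tgt, GPAConfig(inner_iters=25, max_iters=15, seed=5))
        r2 = run_gpa(src, tgt, GPAConfig(inner_iters=25, max_iters=15, seed=5))
        np.testing.assert_array_equal(r1.particles.positions, r2.particles.positions)
        np.testing.assert_array_equal(r1.velocities.v, r2.velocities.v)

    def test_divergence_below_threshold_when_stopped(self, rng):
        src = rng.normal(0, 1, (60, 1))
        tgt = rng.normal(1.5, 1, (60, 1))
        res = run_gpa(src, tgt, GPAConfig(inner_iters=40, max_iters=100, seed=6))
        if res.stopped:
            assert res.objectives[-1] < 0.05


def test_velocity_sample_set_roundtrip(rng):
    s = VelocitySampleSet(x=rng.normal(size=(7, 2)), t=np.arange(7.0),
                          v=rng.normal(size=(7, 2)))
    df = s.to_dataframe()
    assert list(df.columns) == ["x1", "x2", "t", "v1", "v2", "subinterval"]
    assert len(df) == 7
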