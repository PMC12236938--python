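"""Unit tests for time alignment, field training and trajectory integration."""

import numpy as np
import pytest

from profet.force_matching import (FMConfig, TimeAlignment, align_times,
                                   force_matching_loss, integrate_trajectories,
                                   train_velocity_field)
from profet.gpa import VelocitySampleSet


class _ExactField:
    """Duck-typed velocity field with a closed-form rule."""

    def __init__(self, fn, dim=1, time_domain=(0.0, 1.0)):
        self.fn = fn
        self.dim = dim
        self.time_domain = time_domain

    def __call__(self, X, s):
        X = np.atleast_2d(X)
        return self.fn(X, s)


def _records(x, t, v, sub=0):
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    v = np.asarray(v, dtype=float).reshape(-1, 1)
    return VelocitySampleSet(x=x, t=np.asarray(t, dtype=float), v=v,
                             subinterval=np.full(len(x), sub))


class TestTimeAlignment:
    def test_single_subinterval_affine_endpoints(self):
        rec = _records([0.0, 0.0, 0.0], [0.0, 2.5, 5.0], [1.0, 1.0, 1.0])
        aligned, al = align_times([rec], [0.0, 4.0], horizons=[5.0])
        np.testing.assert_allclose(aligned.t, [0.0, 2.0, 4.0])

    def test_two_subintervals_map_to_disjoint_intervals(self):
        r0 = _records([0.0], [1.0], [1.0], sub=0)
        r1 = _records([0.0], [1.0], [1.0], sub=1)
        aligned, al = align_times([r0, r1], [0.0, 2.0, 4.0], horizons=[2.0, 8.0])
        assert aligned.t[0] == pytest.approx(1.0)   # halfway through [0, 2]
        assert aligned.t[1] == pytest.approx(2.25)  # 1/8 through [2, 4]

    def test_velocity_rescaled_by_time_compression(self):
        # local horizon 3 squeezed into a unit observation interval: speeds x3
        rec = _records([0.0], [0.0], [1.0])
        aligned, al = align_times([rec], [0.0, 1.0], horizons=[3.0])
        assert aligned.v[0, 0] == pytest.approx(3.0)
        assert al.velocity_scale(0) == pytest.approx(3.0)

    def test_inverse_mapping_recovers_local_times(self):
        al = TimeAlignment(observation_times=[0.0, 2.0, 5.0], horizons=[3.0, 7.0])
        local = np.linspace(0, 7, 11)
        back = al.to_local(1, al.to_global(1, local))
        np.testing.assert_allclose(back, local, atol=1e-10)

    def test_unknown_subinterval_rejected(self):
        rec = _records([0.0], [0.0], [1.0], sub=3)
        with pytest.raises(KeyError):
            align_times([rec], [0.0, 1.0])

    def test_longest_horizon_mode_shares_the_rate(self):
        al = TimeAlignment(observation_times=[0.0, 1.0, 2.0], horizons=[2.0, 4.0],
                           mode="longest-horizon")
        # both subintervals use H_max = 4: local 4 maps to the interval end
        assert al.to_global(0, 4.0) == pytest.approx(1.0)
        assert al.to_global(1, 4.0) == pytest.approx(2.0)


class TestRelaxationAlignment:
    def _two_phase_records(self):
        """10 fast iterations then 10 slow ones (speeds 1.0 and 0.1)."""
        speeds = np.concatenate([np.full(10, 1.0), np.full(10, 0.1)])
        x = np.cumsum(np.concatenate([[0.0], speeds[:-1]])) * 0.1
        return VelocitySampleSet(x=x.reshape(-1, 1),
                                 t=np.arange(20) * 0.1,
                                 v=speeds.reshape(-1, 1),
                                 subinterval=np.zeros(20, dtype=int))

    def test_global_times_monotone_and_inside_interval(self):
        rec = self._two_phase_records()
        aligned, _ = align_times([rec], [0.0, 2.0], mode="relaxation")
        assert (np.diff(aligned.t) > 0).all()
        assert aligned.t[0] == pytest.approx(0.0)
        assert aligned.t[-1] < 2.0

    def test_displacement_preserved_under_reparameterization(self):
        """v_global * ds equals v_local * dt per record: the integrated path
        is unchanged, only its schedule."""
        rec = self._two_phase_records()
        aligned, _ = align_times([rec], [0.0, 2.0], mode="relaxation")
        # reconstruct per-record global steps from consecutive unique times
        s_grid = np.unique(aligned.t)
        ds = np.diff(np.append(s_grid, 2.0))
        local_disp = (rec.v[:, 0] * 0.1).sum()
        global_disp = (aligned.v[:, 0] * ds).sum()
        assert global_disp == pytest.approx(local_disp, rel=1e-6)

    def test_peak_speed_insensitive_to_crawl_tail(self):
        """A long slow tail inflates the affine map's peak aligned speed
        (horizon grows, so the fast phase is squeezed into ever less global
        time) but leaves the relaxation schedule's peak speed bounded."""
        def records(n_slow):
            speeds = np.concatenate([np.full(10, 1.0), np.full(n_slow, 0.05)])
            x = np.cumsum(np.concatenate([[0.0], speeds[:-1]])) * 0.1
            return VelocitySampleSet(x=x.reshape(-1, 1),
                                     t=np.arange(speeds.size) * 0.1,
                                     v=speeds.reshape(-1, 1),
                                     subinterval=np.zeros(speeds.size, dtype=int))

        peaks = {}
        for mode in ("per-interval", "relaxation"):
            aligned_short, _ = align_times([records(10)], [0.0, 2.0], mode=mode)
            aligned_long, _ = align_times([records(200)], [0.0, 2.0], mode=mode)
            peaks[mode] = (np.abs(aligned_short.v).max(), np.abs(aligned_long.v).max())
        assert peaks["per-interval"][1] > 3 * peaks["per-interval"][0]
        assert peaks["relaxation"][1] < 2 * peaks["relaxation"][0]

    def test_invalid_warp(self):
        rec = self._two_phase_records()
        with pytest.raises(ValueError):
            align_times([rec], [0.0, 2.0], mode="relaxation", warp=0.5)


class TestForceMatchingLoss:
    def test_exact_field_gives_zero(self, rng):
        x = rng.normal(size=(20, 1))
        samples = VelocitySampleSet(x=x, t=np.zeros(20), v=-x)
        field = _ExactField(lambda X, s: -X)
        assert force_matching_loss(field, samples) == pytest.approx(0.0)

    def test_constant_offset_gives_squared_norm(self, rng):
        x = rng.normal(size=(15, 2))
        v = rng.normal(size=(15, 2))
        c = np.array([0.3, -0.4])
        field = _ExactField(lambda X, s: v[:X.shape[0]] + c, dim=2)
        samples = VelocitySampleSet(x=x, t=np.zeros(15), v=v)
        assert force_matching_loss(field, samples) == pytest.approx((c ** 2).sum())

    def test_three_sample_hand_arithmetic(self):
        samples = _records([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        field = _ExactField(lambda X, s: np.zeros_like(X))
        assert force_matching_loss(field, samples) == pytest.approx((1 + 4 + 9) / 3)

    def test_empty_batch_rejected(self):
        empty = VelocitySampleSet(x=np.empty((0, 1)), t=np.empty(0), v=np.empty((0, 1)))
        field = _ExactField(lambda X, s: X)
        with pytest.raises(ValueError):
            force_matching_loss(field, empty)


class TestTraining:
    def test_recovers_constant_field(self, rng):
        n = 600
        x = rng.uniform(-1, 1, (n, 2))
        t = rng.uniform(0, 1, n)
        v = np.tile([1.0, 0.0], (n, 1))
        field = train_velocity_field(VelocitySampleSet(x=x, t=t, v=v),
                                     FMConfig(epochs=150, seed=0))
        grid = np.stack(np.meshgrid(np.linspace(-1, 1, 5), np.linspace(-1, 1, 5)),
                        axis=-1).reshape(-1, 2)
        pred = field(grid, 0.5)
        assert np.abs(pred - [1.0, 0.0]).max() < 0.05

    def test_recovers_linear_decay_field(self, rng):
        n = 1500
        x = rng.uniform(-2, 2, (n, 1))
        t = rng.uniform(0, 1, n)
        field = train_velocity_field(VelocitySampleSet(x=x, t=t, v=-x),
                                     FMConfig(epochs=250, seed=1))
        grid = np.linspace(-2, 2, 21).reshape(-1, 1)
        rel = np.abs(field(grid, 0.5) + grid).max() / 2.0
        assert rel < 0.10

    def test_seed_reproducibility(self, rng):
        x = rng.normal(size=(100, 1))
        samples = VelocitySampleSet(x=x, t=np.zeros(100), v=-x)
        f1 = train_velocity_field(samples, FMConfig(epochs=20, seed=7))
        f2 = train_velocity_field(samples, FMConfig(epochs=20, seed=7))
        for W1, W2 in zip(f1.net.W, f2.net.W):
            np.testing.assert_array_equal(W1, W2)


class TestIntegration:
    def test_zero_field_is_stationary(self, rng):
        field = _ExactField(lambda X, s: np.zeros_like(X), dim=2)
        starts = rng.normal(size=(8, 2))
        traj = integrate_trajectories(field, starts, 0.0, 1.0, 50)
        np.testing.assert_array_equal(traj.states[:, -1, :], starts)

    def test_constant_field_is_exact(self):
        field = _ExactField(lambda X, s: np.full_like(X, 0.7))
        traj = integrate_trajectories(field, [[0.0]], 0.0, 2.0, 10)
        assert traj.states[0, -1, 0] == pytest.approx(1.4)

    def test_exponential_decay_closed_form(self):
        field = _ExactField(lambda X, s: -X)
        traj = integrate_trajectories(field, [[1.0]], 0.0, 1.0, 1000)
        assert traj.states[0, -1, 0] == pytest.approx(np.exp(-1.0), abs=2e-3)

    def test_first_order_step_size_convergence(self):
        field = _ExactField(lambda X, s: -X)
        e = []
        for n in (100, 200):
            traj = integrate_trajectories(field, [[1.0]], 0.0, 1.0, n)
            e.append(abs(traj.states[0, -1, 0] - np.exp(-1.0)))
        assert e[1] < e[0]
        assert e[1] == pytest.approx(e[0] / 2, rel=0.2)  # order-1 halving

    def test_invalid_steps(self):
        field = _ExactField(lambda X, s: -X)
        with pytest.raises(ValueError):
            integrate_trajectories(field, [[1.0]], 0.0, 1.0, 0)

    def test_extrapolation_warns(self):
        field = _ExactField(lambda X, s: -X, time_domain=(0.0, 0.5))
        with pytest.warns(RuntimeWarning):
            integrate_trajectories(field, [[1.0]], 0.0, 1.0, 10)
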