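"""Force-matching: lift per-subinterval particle velocities to a global field.

The GPA stage produces Lagrangian velocity samples on each snapshot pair's
own local clock.  Here those clocks are aligned onto the experimental time
axis, a time-dependent neural velocity field ``v(x, s)`` is fit by
least-squares regression onto the aligned samples, and continuous
trajectories are recovered by forward-Euler integration of the field from
arbitrary start states.

Because the local GPA clock of subinterval i (horizon ``H_i = n_T^i dt_i``)
is compressed affinely onto the observation interval ``[t_i, t_{i+1}]``,
velocities are rescaled by the chain-rule factor ``H_i / (t_{i+1} - t_i)``
so that integrating the global field in experimental time traverses the
same path the particles did.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import MLP, Adam
from .gpa import VelocitySampleSet

__all__ = [
    "FMConfig",
    "TimeAlignment",
    "VelocityField",
    "TrajectoryEnsemble",
    "align_times",
    "force_matching_loss",
    "train_velocity_field",
    "integrate_trajectories",
]


@dataclass
class FMConfig:
    """Velocity-field training hyperparameters (mini-batch Adam on MSE)."""

    batch: int = 256
    lr: float = 1e-3
    epochs: int = 2000
    seed: int = 0
    hidden: tuple[int, ...] = (64, 64, 64, 64)
    sn_cap: float = 3.0  # per-layer spectral-norm cap; keeps the field Lipschitz
    val_fraction: float = 0.1


@dataclass
class TimeAlignment:
    """Affine maps from per-subinterval local GPA time to global time.

    ``mode="per-interval"`` maps subinterval i's local clock ``[0, H_i]``
    onto its own observation interval ``[t_i, t_{i+1}]``.  The alternative
    ``mode="longest-horizon"`` uses a shared rate set by the longest local
    horizon, so shorter subintervals fill only part of their interval.
    (The nonlinear ``"relaxation"`` schedule is handled directly by
    :func:`align_times`; this dataclass covers the affine modes.)
    """

    observation_times: np.ndarray
    horizons: np.ndarray
    mode: str = "per-interval"

    def __post_init__(self):
        self.observation_times = np.asarray(self.observation_times, dtype=float)
        self.horizons = np.asarray(self.horizons, dtype=float)
        if self.observation_times.size != self.horizons.size + 1:
            raise ValueError("need one horizon per adjacent snapshot pair")
        if (np.diff(self.observation_times) <= 0).any():
            raise ValueError("observation times must be strictly increasing")
        if self.mode not in ("per-interval", "longest-horizon"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")

    def _rate(self, i: int) -> float:
        """d(global s) / d(local t) on subinterval i."""
        span = self.observation_times[i + 1] - self.observation_times[i]
        h = self.horizons.max() if self.mode == "longest-horizon" else self.horizons[i]
        if h <= 0:
            raise ValueError(f"subinterval {i} has zero local horizon")
        return span / h

    def to_global(self, i: int, local_t) -> np.ndarray:
        if not 0 <= i < self.horizons.size:
            raise KeyError(f"unknown subinterval id {i}")
        return self.observation_times[i] + self._rate(i) * np.asarray(local_t, dtype=float)

    def to_local(self, i: int, global_s) -> np.ndarray:
        if not 0 <= i < self.horizons.size:
            raise KeyError(f"unknown subinterval id {i}")
        return (np.asarray(global_s, dtype=float) - self.observation_times[i]) / self._rate(i)

    def velocity_scale(self, i: int) -> float:
        """Chain-rule factor applied to local velocities: dx/ds = dx/dt / rate."""
        return 1.0 / self._rate(i)


def align_times(records: list[VelocitySampleSet] | VelocitySampleSet,
                observation_times, horizons=None,
                mode: str = "per-interval",
                warp: float = 3.0) -> tuple[VelocitySampleSet, TimeAlignment]:
    """Reparameterize per-subinterval velocity samples onto experimental time.

    ``horizons`` defaults to each subinterval's last recorded local time plus
    one step (``n_T^i * dt_i``) inferred from the records.  Velocities are
    rescaled by the chain rule so that integrating in global time traverses
    the same paths the particles did.

    Modes: ``"per-interval"`` and ``"longest-horizon"`` are affine in local
    time.  ``"relaxation"`` distributes each subinterval's ensemble transport
    progress P over its observation interval along the concave profile
    ``P = 1 - (1-u)^warp`` (u the normalized global time): transport is
    front-loaded, mimicking exponential relaxation toward the target, and
    aligned speeds stay within a narrow range instead of concentrating the
    whole fast phase of the gradient flow into a sliver of global time —
    which an L-Lipschitz field cannot represent.
    """
    if isinstance(records, VelocitySampleSet):
        records = [records]
    merged = VelocitySampleSet.concatenate(records)
    observation_times = np.asarray(observation_times, dtype=float)
    n_sub = observation_times.size - 1
    ids = np.unique(merged.subinterval)
    if ids.size and (ids.min() < 0 or ids.max() >= n_sub):
        raise KeyError(f"record with unknown subinterval id (have intervals 0..{n_sub - 1})")
    if horizons is None:
        horizons = np.zeros(n_sub)
        for i in range(n_sub):
            mask = merged.subinterval == i
            if mask.any():
                ts = np.unique(merged.t[mask])
                step = ts[1] - ts[0] if ts.size > 1 else ts[0] or 1.0
                horizons[i] = ts[-1] + step
            else:
                horizons[i] = 1.0  # placeholder; no records to map
    if mode == "relaxation":
        if warp < 1.0:
            raise ValueError("warp exponent must be >= 1")
        s = np.empty_like(merged.t)
        v = merged.v.copy()
        for i in range(n_sub):
            mask = merged.subinterval == i
            if not mask.any():
                continue
            t0g, t1g = observation_times[i], observation_times[i + 1]
            span = t1g - t0g
            ts = np.unique(merged.t[mask])
            dt_loc = ts[1] - ts[0] if ts.size > 1 else horizons[i]
            iters = np.searchsorted(ts, merged.t[mask])
            speeds = np.linalg.norm(merged.v[mask], axis=1)
            mean_speed = np.array([speeds[iters == n].mean() for n in range(ts.size)])
            cum = np.concatenate([[0.0], np.cumsum(mean_speed * dt_loc)])
            if cum[-1] <= 0:  # no transport: fall back to affine
                u = np.linspace(0.0, 1.0, ts.size + 1)
            else:
                progress = cum / cum[-1]
                u = 1.0 - (1.0 - progress) ** (1.0 / warp)
            s_grid = t0g + span * u
            ds = np.maximum(np.diff(s_grid), 1e-12)
            s[mask] = s_grid[iters]
            v[mask] *= (dt_loc / ds)[iters][:, None]
        alignment = TimeAlignment(observation_times=observation_times,
                                  horizons=np.asarray(horizons, dtype=float),
                                  mode="per-interval")
        aligned = VelocitySampleSet(x=merged.x, t=s, v=v, subinterval=merged.subinterval)
        return aligned, alignment
    alignment = TimeAlignment(observation_times=observation_times,
                              horizons=np.asarray(horizons, dtype=float), mode=mode)
    s = np.empty_like(merged.t)
    v = merged.v.copy()
    for i in range(n_sub):
        mask = merged.subinterval == i
        if not mask.any():
            continue
        s[mask] = alignment.to_global(i, merged.t[mask])
        v[mask] *= alignment.velocity_scale(i)
    aligned = VelocitySampleSet(x=merged.x, t=s, v=v, subinterval=merged.subinterval)
    return aligned, alignment


class VelocityField:
    """Neural velocity field v(x, s): tanh MLP over (position, time).

    Spectral caps on every layer keep the field Lipschitz in (x, s), which
    stabilizes integration and yields temporally smooth interpolation.
    """

    def __init__(self, dim: int, time_domain: tuple[float, float],
                 hidden=(64, 64, 64, 64), sn_cap: float = 3.0, seed: int = 0,
                 out_scale: float = 1.0):
        rng = np.random.default_rng(seed)
        self.net = MLP([dim + 1, *hidden, dim], "tanh", rng, spectral_cap=sn_cap)
        self.dim = dim
        self.time_domain = (float(time_domain[0]), float(time_domain[1]))
        # velocity unit used during training; network outputs are O(1) in it
        self.out_scale = float(out_scale)

    def __call__(self, X: np.ndarray, s) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = np.broadcast_to(np.asarray(s, dtype=float), (X.shape[0],))
        return self.out_scale * self.net.forward(np.column_stack([X, s]))


def force_matching_loss(field: VelocityField, samples: VelocitySampleSet) -> float:
    """Mean squared deviation between the field and the recorded velocities."""
    if len(samples) == 0:
        raise ValueError("empty sample set")
    pred = field(samples.x, samples.t)
    return float(((pred - samples.v) ** 2).sum(axis=1).mean())


def train_velocity_field(samples: VelocitySampleSet, config: FMConfig | None = None,
                         seed: int | None = None,
                         time_domain: tuple[float, float] | None = None) -> VelocityField:
    """Fit the velocity field by mini-batch Adam on the force-matching loss.

    A seeded 10% split is held out as an overfit guard: a validation loss
    above twice the training loss triggers a warning only.  The fitted field
    carries ``final_train_loss`` and ``final_val_loss`` attributes.
    """
    cfg = config or FMConfig()
    if seed is not None:
        cfg = FMConfig(**{**cfg.__dict__, "seed": seed})
    if len(samples) == 0:
        raise ValueError("empty sample set")
    d = samples.x.shape[1]
    if time_domain is None:
        time_domain = (float(min(samples.t.min(), 0.0)), float(samples.t.max()))
    field = VelocityField(d, time_domain, hidden=cfg.hidden,
                          sn_cap=cfg.sn_cap, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    n = len(samples)
    perm = rng.permutation(n)
    n_val = int(cfg.val_fraction * n) if n >= 20 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    inputs = np.column_stack([samples.x, samples.t])
    targets = samples.v
    opt = Adam(field.net, lr=cfg.lr)
    batch = min(cfg.batch, train_idx.size)
    train_loss = np.nan
    for epoch in range(cfg.epochs):
        # cosine decay to ~1% of the base rate stabilizes the late fit
        opt.lr = cfg.lr * (0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs)))
        order = rng.permutation(train_idx)
        for start in range(0, order.size, batch):
            idx = order[start:start + batch]
            pred, tape = field.net.forward(inputs[idx], cache=True)
            resid = pred - targets[idx]
            loss = float((resid ** 2).sum(axis=1).mean())
            if not np.isfinite(loss):
                raise RuntimeError("force-matching loss became non-finite; reduce lr")
            dW, db, _ = field.net.backward(tape, 2.0 * resid / idx.size)
            opt.step(dW, db)
            train_loss = loss
    field.net.project()
    field.final_train_loss = float(
        ((field.net.forward(inputs[train_idx]) - targets[train_idx]) ** 2).sum(axis=1).mean())
    if n_val:
        field.final_val_loss = float(
            ((field.net.forward(inputs[val_idx]) - targets[val_idx]) ** 2).sum(axis=1).mean())
        if field.final_val_loss > 2.0 * max(field.final_train_loss, 1e-12):
            warnings.warn(
                f"held-out force-matching loss {field.final_val_loss:.3g} exceeds twice "
                f"the training loss {field.final_train_loss:.3g}", RuntimeWarning)
    else:
        field.final_val_loss = float("nan")
    return field


def save_field(field: VelocityField, path) -> None:
    """Serialize a trained velocity field to a single .npz archive."""
    arrays = {f"W{l}": W for l, W in enumerate(field.net.W)}
    arrays.update({f"b{l}": b for l, b in enumerate(field.net.b)})
    np.savez(path, n_layers=len(field.net.W), dim=field.dim,
             hidden=np.asarray(field.net.sizes[1:-1]),
             sn_cap=field.net.spectral_cap if field.net.spectral_cap is not None else -1.0,
             time_domain=np.asarray(field.time_domain),
             out_scale=field.out_scale, **arrays)


def load_field(path) -> VelocityField:
    with np.load(path) as z:
        sn_cap = float(z["sn_cap"])
        field = VelocityField(int(z["dim"]), tuple(z["time_domain"]),
                              hidden=tuple(int(h) for h in z["hidden"]),
                              sn_cap=sn_cap if sn_cap > 0 else None,
                              out_scale=float(z["out_scale"]))
        n = int(z["n_layers"])
        field.net.W = [z[f"W{l}"] for l in range(n)]
        field.net.b = [z[f"b{l}"] for l in range(n)]
    return field


@dataclass
class TrajectoryEnsemble:
    """Integrated trajectories: times grid plus cell x time x dim states."""

    times: np.ndarray
    states: np.ndarray
    provenance: list[str] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 3 or self.states.shape[1] != self.times.size:
            raise ValueError("states must be (cells, n_times, dim)")
        if not np.isfinite(self.states).all():
            raise ValueError("non-finite trajectory states")

    def at_time(self, s: float) -> np.ndarray:
        """States at the grid point nearest to s."""
        return self.states[:, int(np.argmin(np.abs(self.times - s))), :]

    def to_dataframe(self, cell_ids=None) -> pd.DataFrame:
        n_cells, n_times, d = self.states.shape
        if cell_ids is None:
            cell_ids = [f"cell{i}" for i in range(n_cells)]
        rows = {
            "cell_id": np.repeat(cell_ids, n_times),
            "s": np.tile(self.times, n_cells),
        }
        flat = self.states.reshape(n_cells * n_times, d)
        for j in range(d):
            rows[f"x{j + 1}"] = flat[:, j]
        return pd.DataFrame(rows)


def integrate_trajectories(field: VelocityField, starts: np.ndarray,
                           s_start: float, s_end: float,
                           n_steps: int) -> TrajectoryEnsemble:
    """Forward-Euler integration of the field from the given start states."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    lo, hi = field.time_domain
    if s_start < lo - 1e-9 or s_end > hi + 1e-9:
        warnings.warn(f"integration window [{s_start}, {s_end}] extrapolates beyond "
                      f"the field's time domain [{lo}, {hi}]", RuntimeWarning)
    X = np.atleast_2d(np.asarray(starts, dtype=float)).copy()
    h = (s_end - s_start) / n_steps
    times = s_start + h * np.arange(n_steps + 1)
    out = np.empty((X.shape[0], n_steps + 1, X.shape[1]))
    out[:, 0] = X
    for m in range(n_steps):
        X = X + h * field(X, times[m])
        if not np.isfinite(X).all():
            bad = int(np.argwhere(~np.isfinite(X).all(axis=1))[0, 0])
            raise RuntimeError(f"non-finite state at step {m + 1}, trajectory {bad}")
        out[:, m + 1] = X
    return TrajectoryEnsemble(times=times, states=out)
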