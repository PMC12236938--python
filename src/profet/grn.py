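"""Stochastic gene-regulatory-network simulator for synthetic EMT time courses.

The generative model is a coupled system of SDEs over a signed connection
matrix ``J`` (``J[i, j] = +1`` if gene *j* activates gene *i*, ``-1`` if it
inhibits it, ``0`` otherwise):

    dx_i/dt = g_i * prod_{j : J_ij != 0} HS(x_j; lam_ij, theta_ij, n_ij)
              - k_i * x_i + D * x_i * eta_i(t)

where ``HS`` is the shifted Hill function and ``eta_i`` is unit white
noise.  Integration uses the Euler–Maruyama scheme with states clipped at
zero after every step (noise is multiplicative, so the origin is absorbing
in the exact dynamics and clipping preserves that).

Snapshots subsampled from the simulated replicate ensemble at a few time
points emulate temporally sparse scRNA-seq measurements and are the
package's standard synthetic benchmark input.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRNModel",
    "SimulatedTrajectorySet",
    "shifted_hill",
    "drift",
    "simulate_euler_maruyama",
    "sample_parameter_ensemble",
    "subsample_snapshots",
    "load_topology",
    "default_emt_topology",
    "DEFAULT_RANGES",
]

#: Default sampling bounds for the random parameter ensemble.  Thresholds are
#: expressed as fractions of the regulator's unregulated steady state g_j/k_j.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "g": (1.0, 100.0),
    "k": (0.1, 1.0),
    "lam_act": (1.0, 10.0),
    "lam_inh": (0.1, 1.0),
    "theta": (0.02, 1.98),
    "n": (1, 6),
}


@dataclass
class GRNModel:
    """A parameterized gene regulatory network.

    ``lam``, ``theta`` and ``n`` are dense genes x genes arrays whose entries
    are meaningful only where ``J`` is nonzero.
    """

    J: np.ndarray
    g: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    n: np.ndarray
    D: float = 1.0
    gene_names: list[str] | None = None

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=int)
        for name in ("g", "k", "lam", "theta", "n"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.J.shape[0]

    def validate(self) -> None:
        J = self.J
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("J must be a square matrix")
        if not np.isin(J, (-1, 0, 1)).all():
            raise ValueError("J entries must be in {-1, 0, +1}")
        m = J.shape[0]
        if self.g.shape != (m,) or self.k.shape != (m,):
            raise ValueError("g and k must be per-gene vectors")
        if (self.g <= 0).any() or (self.k <= 0).any():
            raise ValueError("production and degradation rates must be > 0")
        act, inh = J == 1, J == -1
        if (self.lam[act] <= 1).any():
            raise ValueError("lambda must be > 1 on activating edges")
        if ((self.lam[inh] <= 0) | (self.lam[inh] >= 1)).any():
            raise ValueError("lambda must be in (0, 1) on inhibiting edges")
        edges = act | inh
        if (self.theta[edges] <= 0).any():
            raise ValueError("theta must be > 0 on every edge")
        if (self.n[edges] < 1).any():
            raise ValueError("Hill coefficients must be >= 1")
        if self.D < 0:
            raise ValueError("noise magnitude D must be >= 0")


@dataclass
class SimulatedTrajectorySet:
    """Replicate x time x gene array of simulated expression values."""

    times: np.ndarray
    values: np.ndarray  # (replicates, n_times, n_genes)
    seed: int
    gene_names: list[str] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.times.size:
            raise ValueError("values must be (replicates, n_times, n_genes)")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")


def shifted_hill(x, lam, theta, n):
    """Shifted Hill regulation factor ``lam + (1 - lam) / (1 + (x/theta)^n)``.

    Equals 1 when the regulator is absent (x = 0) and saturates at the fold
    change ``lam`` for ``x >> theta``; the output always lies between
    ``min(1, lam)`` and ``max(1, lam)``.
    """
    x = np.asarray(x, dtype=float)
    theta_a = np.asarray(theta, dtype=float)
    n_a = np.asarray(n)
    if (theta_a <= 0).any():
        raise ValueError("theta must be > 0")
    if (np.asarray(n_a) < 1).any():
        raise ValueError("Hill coefficient n must be >= 1")
    ratio = (x / theta_a) ** n_a
    return lam + (1.0 - np.asarray(lam, dtype=float)) / (1.0 + ratio)


def drift(x: np.ndarray, model: GRNModel) -> np.ndarray:
    """Deterministic part of the SDE; supports a single state or a batch.

    The regulation product runs over a gene's regulators only; an empty
    regulator set contributes a factor of 1.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    m = model.n_genes
    if X.shape[-1] != m:
        raise ValueError(f"state has {X.shape[-1]} genes, model has {m}")
    mask = model.J != 0
    # H[r, i, j] = HS(x_r[j]; params[i, j]) where j regulates i, else 1
    H = np.ones((X.shape[0], m, m))
    if mask.any():
        reg = np.broadcast_to(X[:, None, :], (X.shape[0], m, m))[:, mask]
        H[:, mask] = shifted_hill(reg, model.lam[mask], model.theta[mask], model.n[mask])
    production = model.g * H.prod(axis=2)
    out = production - model.k * X
    return out[0] if single else out


def simulate_euler_maruyama(model: GRNModel, x0: np.ndarray, dt: float,
                            t_end: float, seed: int) -> SimulatedTrajectorySet:
    """Integrate the GRN SDE with the Euler–Maruyama scheme.

    ``x0`` may be a single state vector or a (replicates, genes) array; each
    replicate receives independent noise.  States are clipped at zero after
    every step.  A fixed seed gives bit-identical output.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    x0 = np.asarray(x0, dtype=float)
    if (x0 < 0).any():
        raise ValueError("initial states must be non-negative")
    X = (x0[None, :] if x0.ndim == 1 else x0).copy()
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    rng = np.random.default_rng(seed)
    out = np.empty((X.shape[0], n_steps + 1, model.n_genes))
    out[:, 0] = X
    sq = np.sqrt(dt)
    for step in range(n_steps):
        xi = rng.standard_normal(X.shape)
        X = X + dt * drift(X, model) + model.D * X * sq * xi
        np.clip(X, 0.0, None, out=X)
        out[:, step + 1] = X
    return SimulatedTrajectorySet(times=times, values=out, seed=seed,
                                  gene_names=model.gene_names)


def sample_parameter_ensemble(J: np.ndarray, n_sets: int,
                              ranges: dict[str, tuple[float, float]] | None = None,
                              seed: int = 0, D: float = 1.0,
                              gene_names: list[str] | None = None) -> list[GRNModel]:
    """Draw random kinetic parameter sets for a fixed topology.

    ``g`` and ``k`` are uniform on their ranges; fold changes are drawn from
    the activation range on ``J=+1`` edges and the inhibition range on
    ``J=-1`` edges; thresholds are uniform fractions (``ranges["theta"]``) of
    the regulator's unregulated steady state ``g_j / k_j``; Hill coefficients
    are integer-uniform on ``ranges["n"]`` inclusive.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    J = np.asarray(J, dtype=int)
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for key, (lo, hi) in r.items():
        if lo > hi:
            raise ValueError(f"inverted range for {key!r}: ({lo}, {hi})")
    m = J.shape[0]
    rng = np.random.default_rng(seed)
    models = []
    act, inh = J == 1, J == -1
    for _ in range(n_sets):
        g = rng.uniform(*r["g"], size=m)
        k = rng.uniform(*r["k"], size=m)
        lam = np.ones((m, m))
        lam[act] = rng.uniform(*r["lam_act"], size=int(act.sum()))
        lam[inh] = rng.uniform(*r["lam_inh"], size=int(inh.sum()))
        steady = g / k  # regulator j scale, broadcast across targets i
        frac = rng.uniform(*r["theta"], size=(m, m))
        theta = np.ones((m, m))
        edges = act | inh
        theta[edges] = (frac * steady[None, :])[edges]
        lo_n, hi_n = r["n"]
        n = np.ones((m, m))
        n[edges] = rng.integers(int(lo_n), int(hi_n) + 1, size=int(edges.sum()))
        models.append(GRNModel(J=J, g=g, k=k, lam=lam, theta=theta, n=n, D=D,
                               gene_names=gene_names))
    return models


def subsample_snapshots(trajectories: SimulatedTrajectorySet, sample_times):
    """Extract one cells x genes matrix per requested time point.

    Each replicate contributes one cell; values are taken at the nearest
    simulation grid point, with exact ties resolved toward the earlier index.
    """
    from .preprocess import SnapshotSeries

    times = trajectories.times
    sample_times = np.asarray(sample_times, dtype=float)
    if (sample_times < times[0]).any() or (sample_times > times[-1]).any():
        raise ValueError("requested time outside the simulated range")
    idx = [int(np.argmin(np.abs(times - t))) for t in sample_times]
    genes = trajectories.gene_names or [f"g{i}" for i in range(trajectories.values.shape[2])]
    matrices = [trajectories.values[:, i, :].copy() for i in idx]
    return SnapshotSeries(times=sample_times, matrices=matrices, gene_names=list(genes))


def load_topology(path) -> tuple[np.ndarray, list[str]]:
    """Read a signed connection matrix from a whitespace-delimited text file.

    Expected layout: comment lines starting with ``#``, then a header row of
    gene names, then one row per target gene of ``name v1 ... vm``.
    Returns ``(J, gene_names)`` with ``J[i, j]`` the effect of gene j on gene i.
    """
    with open(path) as fh:
        rows = [ln.split() for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")]
    header = rows[0]
    m = len(header)
    J = np.zeros((m, m), dtype=int)
    names_seen = []
    for row in rows[1:]:
        names_seen.append(row[0])
        if len(row) != m + 1:
            raise ValueError(f"row for {row[0]!r} has {len(row) - 1} entries, expected {m}")
        J[len(names_seen) - 1] = [int(v) for v in row[1:]]
    if names_seen != header:
        raise ValueError("row gene names do not match the header")
    if not np.isin(J, (-1, 0, 1)).all():
        raise ValueError("connection matrix entries must be in {-1, 0, +1}")
    return J, header


def default_emt_topology() -> tuple[np.ndarray, list[str]]:
    """The packaged 26-gene EMT-style network topology."""
    ref = importlib.resources.files("profet").joinpath("data/emt_grn_topology.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_topology(path)
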