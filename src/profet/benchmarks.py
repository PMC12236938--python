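"""Self-contained benchmark runs exercising the whole method at desk scale.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantities in a flat dict.  They
are used both by the test suite and by ``scripts/acceptance.py``, so the
numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import functools
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from threadpoolctl import threadpool_limits

from .config import (DownstreamConfig, EvalConfig, PreprocessConfig, RunConfig,
                     derive_seed)
from .downstream import permutation_test, stratify_by_displacement
from .force_matching import (FMConfig, TrajectoryEnsemble, align_times,
                             integrate_trajectories, train_velocity_field)
from .gpa import GPAConfig, VelocitySampleSet, run_gpa
from .metrics import mmd_rbf, sinkhorn_divergence
from .pipeline import run_pipeline, simulate_emt_series

EPSILON_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def _single_threaded(fn):
    """Pin BLAS to one thread: bit-reproducible results regardless of host CPUs."""

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        with threadpool_limits(limits=1):
            return fn(*args, **kwargs)

    return wrapper


@_single_threaded
def closed_form_metric_checks(seed: int = 0) -> dict:
    """Closed-form identities of the distributional metrics.

    Sinkhorn divergence of two unit atoms at distance r is r^2 for every
    epsilon; squared MMD of two atoms at distance r with gamma=1 is
    2 - 2 exp(-r^2); and the vectorized MMD must match a brute-force double
    loop.
    """
    rng = np.random.default_rng(seed)
    r = 3.0
    x, y = np.array([[0.0]]), np.array([[r]])
    sink_err = max(abs(sinkhorn_divergence(x, y, eps) - r ** 2) for eps in EPSILON_GRID)
    mmd_err = abs(mmd_rbf([[0.0]], [[1.0]], 1.0) - (2 - 2 * np.exp(-1.0)))
    brute_err = 0.0
    for _ in range(10):
        X = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 2))
        k = lambda a, b: np.exp(-((a - b) ** 2).sum())
        brute = (sum(k(p, q) for p in X for q in X) / 400
                 + sum(k(p, q) for p in Y for q in Y) / 400
                 - 2 * sum(k(p, q) for p in X for q in Y) / 400)
        brute_err = max(brute_err, abs(mmd_rbf(X, Y, 1.0) - brute))
    return {"sinkhorn_atoms_max_abs_error": sink_err,
            "mmd_atoms_abs_error": mmd_err,
            "mmd_bruteforce_max_abs_diff": brute_err}


@_single_threaded
def gpa_gaussian_benchmark(seed: int = 0) -> dict:
    """1-D N(0,1) -> N(5,1) transport with N = M = 200 particles.

    Reports the transported mean (target 5), the largest emitted speed
    (certified <= L = 1), and the divergence estimate at the stop.
    """
    rng = np.random.default_rng(derive_seed(seed, "gpa-gauss-data"))
    src = rng.normal(0.0, 1.0, (200, 1))
    tgt = rng.normal(5.0, 1.0, (200, 1))
    cfg = GPAConfig(max_iters=150, seed=derive_seed(seed, "gpa-gauss"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_gpa(src, tgt, cfg)
        sink_before = sinkhorn_divergence(src, tgt, 1.0)
        sink_after = sinkhorn_divergence(res.particles.positions, tgt, 1.0)
    return {"gpa_final_mean": float(res.particles.positions.mean()),
            "gpa_max_speed": float(np.linalg.norm(res.velocities.v, axis=1).max()),
            "gpa_stop_divergence": float(res.objectives[-1]),
            "gpa_stopped": float(res.stopped),
            "gpa_sinkhorn_improvement": float(1.0 - sink_after / sink_before)}


@_single_threaded
def field_recovery_benchmark(seed: int = 0) -> dict:
    """Force-matching on samples from the linear decay field v = -x.

    Reports the worst relative field error on a grid over [-2, 2] and the
    endpoint of Euler integration from x0 = 1 over [0, 1] (exact: e^{-1}).
    """
    rng = np.random.default_rng(derive_seed(seed, "fm-data"))
    n = 2000
    x = rng.uniform(-2, 2, (n, 1))
    t = rng.uniform(0, 1, n)
    samples = VelocitySampleSet(x=x, t=t, v=-x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        field = train_velocity_field(samples, FMConfig(epochs=300,
                                                       seed=derive_seed(seed, "fm")),
                                     time_domain=(0.0, 1.0))
        grid = np.linspace(-2, 2, 21).reshape(-1, 1)
        rel_err = float(np.abs(field(grid, 0.5) + grid).max() / 2.0)
        traj = integrate_trajectories(field, [[1.0]], 0.0, 1.0, 1000)
    return {"fm_field_max_rel_error": rel_err,
            "fm_integration_endpoint": float(traj.states[0, -1, 0]),
            "fm_endpoint_abs_error": float(abs(traj.states[0, -1, 0] - np.exp(-1.0)))}


@_single_threaded
def turning_point_benchmark(seed: int = 0) -> dict:
    """Three-snapshot 1-D toy N(0,1) -> N(3,1) -> N(0,1).

    The reconstruction must visit the middle state (mean near 3 at the
    middle time) — behavior a straight source-to-final interpolation cannot
    produce (its middle-time mean stays near 0).
    """
    rng = np.random.default_rng(derive_seed(seed, "turn-data"))
    snaps = [rng.normal(m, 1.0, (200, 1)) for m in (0.0, 3.0, 0.0)]
    times = [0.0, 1.0, 2.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = [run_gpa(snaps[i], snaps[i + 1],
                           GPAConfig(max_iters=150, seed=derive_seed(seed, f"turn-gpa{i}")),
                           subinterval_id=i)
                   for i in range(2)]
        aligned, _ = align_times([r.velocities for r in results], times,
                                 [max(r.horizon, r.particles.dt) for r in results])
        field = train_velocity_field(aligned, FMConfig(epochs=400,
                                                       seed=derive_seed(seed, "turn-fm")),
                                     time_domain=(0.0, 2.0))
        traj = integrate_trajectories(field, snaps[0], 0.0, 2.0, 400)
        # distribution-match gain over the first leg (source and final snapshot
        # coincide in this toy, so the middle snapshot is the informative target)
        mid_sink = sinkhorn_divergence(traj.at_time(1.0), snaps[1], 1.0)
        start_sink = sinkhorn_divergence(snaps[0], snaps[1], 1.0)
    linear_middle = 0.5 * (snaps[0].mean() + snaps[2].mean())
    return {"turning_point_middle_mean": float(traj.at_time(1.0).mean()),
            "linear_interpolation_middle_mean": float(linear_middle),
            "turning_point_final_mean": float(traj.states[:, -1, 0].mean()),
            "middle_sinkhorn_rel_improvement": float(1 - mid_sink / start_sink)}


@_single_threaded
def emt_benchmark(seed: int = 0, n_replicates: int = 100,
                  out_dir: str | Path | None = None) -> dict:
    """Scaled synthetic-EMT end-to-end run through the full pipeline.

    Simulates the packaged 26-gene network at five time points, trains on
    times {0, 2, 4} with {1, 3} held out, and compares the reconstruction
    against the OT-coupling and random-coupling interpolation baselines by
    Sinkhorn divergence across the epsilon grid.  Reports the smallest
    margin (random minus reconstruction) over both held-out times and all
    epsilons: a positive value means the reconstruction wins everywhere.
    """
    series = simulate_emt_series(n_replicates=n_replicates,
                                 sample_times=(0, 1, 2, 3, 4),
                                 seed=derive_seed(seed, "emt-sim"))
    tmp = Path(out_dir) if out_dir else Path(tempfile.mkdtemp(prefix="profet-emt-"))
    cfg = RunConfig(
        out_dir=str(tmp), seed=derive_seed(seed, "emt-run"),
        preprocess=PreprocessConfig(log1p=True, latent_dim=2),
        gpa=GPAConfig(dt=0.25, max_iters=450, stop_threshold=0.01, inner_lr=3e-3),
        fm=FMConfig(epochs=1200),
        evaluation=EvalConfig(held_out_times=[1.0, 3.0], epsilons=list(EPSILON_GRID),
                              sinkhorn_max_iter=1000),
        downstream=DownstreamConfig(n_perm=49, perm_metrics=["tv"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_dir = run_pipeline(cfg, series=series)
    ev = pd.read_csv(run_dir / "evaluation.tsv", sep="\t")
    sink = ev[ev.metric == "sinkhorn"].pivot_table(index=["time", "param"],
                                                   columns="method", values="value")
    margins = sink["random-coupling"] - sink["profet"]
    out = {"emt_min_margin_vs_random": float(margins.min()),
           "emt_profet_mean_sinkhorn": float(sink["profet"].mean()),
           "emt_random_mean_sinkhorn": float(sink["random-coupling"].mean()),
           "emt_ot_mean_sinkhorn": float(sink["ot-coupling"].mean())}
    for (t, eps), row in sink.iterrows():
        out[f"emt_sinkhorn_t{t:g}_eps{eps:g}_profet"] = float(row["profet"])
        out[f"emt_sinkhorn_t{t:g}_eps{eps:g}_random"] = float(row["random-coupling"])
    return out


@_single_threaded
def permutation_calibration(seed: int = 0, n_reps: int = 500,
                            n_perm: int = 99, n: int = 20) -> dict:
    """Type-I error of the permutation test at alpha = 0.05 under the null.

    Both samples are drawn from N(0,1); the rejection rate over ``n_reps``
    replicates should sit near the nominal level for each metric.  The
    Sinkhorn arm runs its solver at a fixed modest iteration budget: the
    permutation *ranking* stabilizes long before the transport marginals
    do, and observed and permuted statistics always share the same budget.
    """
    rng = np.random.default_rng(derive_seed(seed, "perm-null"))
    out = {}
    for metric in ("tv", "kl", "sinkhorn"):
        kwargs = {"max_iter": 100, "tol": 1e-3} if metric == "sinkhorn" else {}
        rejections = 0
        for i in range(n_reps):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = permutation_test(a, b, metric=metric, n_perm=n_perm,
                                   seed=derive_seed(seed, f"perm-{metric}-{i}"),
                                   **kwargs)
            rejections += res.p_value <= 0.05
        out[f"perm_type1_rate_{metric}"] = rejections / n_reps
    return out


@_single_threaded
def stratification_benchmark(seed: int = 0) -> dict:
    """KDE stratification of a trimodal displacement mixture.

    600 trajectories with displacement modes 1, 5, 9 (sd 0.3); the two KDE
    cutoffs must fall between adjacent modes and group labels must agree
    with the true mixture components.
    """
    rng = np.random.default_rng(derive_seed(seed, "strat"))
    component = np.repeat([0, 1, 2], 200)
    disp = rng.normal(np.array([1.0, 5.0, 9.0])[component], 0.3)
    states = np.zeros((600, 2, 1))
    states[:, 1, 0] = disp
    traj = TrajectoryEnsemble(times=np.array([0.0, 1.0]), states=states)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels, summary = stratify_by_displacement(traj, 0.0, 1.0)
    accuracy = float((labels.labels == component).mean())
    cut = labels.cutoffs
    return {"stratify_n_cutoffs": float(cut.size),
            "stratify_cutoff_low": float(cut[0]) if cut.size > 0 else float("nan"),
            "stratify_cutoff_high": float(cut[1]) if cut.size > 1 else float("nan"),
            "stratify_label_accuracy": accuracy,
            "stratify_cv": summary["cv"]}
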