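"""Statistical interpretation of reconstructed trajectories.

Covers four analyses: permutation tests comparing predicted against
held-out expression distributions; k-means fate/origin classification of
trajectory endpoints (k chosen by silhouette); KDE-based stratification of
cells by phenotypic displacement; and trajectory-aware differential
expression (normalized divergence profiles plus per-gene log2 fold change
with Welch t-tests and BH-FDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from . import metrics as _metrics
from .force_matching import TrajectoryEnsemble

__all__ = [
    "PermutationTestResult",
    "SubtrajectoryLabels",
    "permutation_test",
    "classify_fates",
    "stratify_by_displacement",
    "normalized_divergence",
    "deg_analysis",
]


@dataclass
class PermutationTestResult:
    gene: str
    metric: str
    observed: float
    p_value: float
    n_perm: int
    seed: int


@dataclass
class SubtrajectoryLabels:
    """Per-trajectory group labels under one classification scheme."""

    labels: np.ndarray
    scheme: str  # "fate" | "origin" | "shift"
    cutoffs: np.ndarray | None = None
    centroids: np.ndarray | None = None


_METRIC_FNS = {
    "tv": lambda a, b, kw: _metrics.tv_distance(a, b, **kw),
    "kl": lambda a, b, kw: _metrics.kl_estimate(a, b, **kw),
    "sinkhorn": lambda a, b, kw: _metrics.sinkhorn_divergence(
        np.asarray(a, dtype=float).reshape(-1, 1),
        np.asarray(b, dtype=float).reshape(-1, 1), **kw),
}


def permutation_test(predicted, observed, metric: str = "tv", n_perm: int = 1000,
                     seed: int = 0, gene: str = "", **metric_kwargs) -> PermutationTestResult:
    """One-sided label-permutation test of distributional equality.

    Pools the two samples, reshuffles labels ``n_perm`` times into groups of
    the original sizes, and reports the add-one-corrected p-value
    ``(#{perm >= observed} + 1) / (n_perm + 1)``, which is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    key = metric.lower()
    if key not in _METRIC_FNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_FNS)}")
    a = np.asarray(predicted, dtype=float).ravel()
    b = np.asarray(observed, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    if key == "sinkhorn":
        # evaluate observed + all relabellings with the batched 1-D solver
        eps = metric_kwargs.pop("epsilon", 1.0)
        perms = np.vstack([np.arange(pooled.size)]
                          + [rng.permutation(pooled.size) for _ in range(n_perm)])
        za = pooled[perms[:, :a.size]]
        zb = pooled[perms[:, a.size:]]
        stats_all = _metrics.batch_sinkhorn_divergence_1d(za, zb, eps, **metric_kwargs)
        observed_stat = stats_all[0]
        exceed = int((stats_all[1:] >= observed_stat).sum())
    else:
        fn = _METRIC_FNS[key]
        observed_stat = fn(a, b, metric_kwargs)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if fn(perm[:a.size], perm[a.size:], metric_kwargs) >= observed_stat:
                exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult(gene=gene, metric=key, observed=float(observed_stat),
                                 p_value=p, n_perm=n_perm, seed=seed)


def _nearest_centroid(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; exact ties resolve to the lowest index."""
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def classify_fates(reference_states: np.ndarray, predicted_states: np.ndarray,
                   k_candidates=range(2, 9), seed: int = 0,
                   scheme: str = "fate") -> SubtrajectoryLabels:
    """Cluster a reference time point and assign predicted states to clusters.

    k-means is fit on the reference states for each candidate k, the k with
    the highest mean silhouette is kept, and every predicted state receives
    the label of its nearest centroid.  Using the last time point as
    reference labels terminal fates; the first labels ancestral origins.
    """
    reference_states = np.atleast_2d(np.asarray(reference_states, dtype=float))
    predicted_states = np.atleast_2d(np.asarray(predicted_states, dtype=float))
    k_candidates = sorted(k_candidates)
    if not k_candidates or k_candidates[0] < 2:
        raise ValueError("k candidates must be >= 2")
    if reference_states.shape[0] <= max(k_candidates):
        raise ValueError("fewer reference points than the largest candidate k")
    best = None
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(reference_states)
        score = silhouette_score(reference_states, km.labels_)
        if best is None or score > best[0]:
            best = (score, km)
    centroids = best[1].cluster_centers_
    labels = _nearest_centroid(predicted_states, centroids)
    return SubtrajectoryLabels(labels=labels, scheme=scheme, centroids=centroids)


def _displacement_summary(d: np.ndarray, grid: np.ndarray | None,
                          density: np.ndarray | None) -> dict:
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    q1, q3 = np.percentile(d, [25, 75])
    cv = sd / mean if mean != 0 else 0.0
    if grid is not None:
        hist, _ = np.histogram(d, bins=np.linspace(grid[0], grid[-1], 65))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0
    return {"mean": mean, "sd": sd, "iqr": float(q3 - q1), "cv": float(cv),
            "entropy": entropy}


def stratify_by_displacement(trajectories: TrajectoryEnsemble, t_pre: float,
                             t_post: float,
                             grid_size: int = 512) -> tuple[SubtrajectoryLabels, dict]:
    """Stratify cells by the Euclidean displacement between two time points.

    Displacements are smoothed with a Gaussian KDE (Scott bandwidth); local
    minima of the density (peaks of its negation, with a small prominence
    floor to suppress numerical ripples) define the cutoffs, and the two
    smallest-x minima split cells into low/medium/high groups.  With one
    minimum two groups are formed, with none a single group (warning).
    """
    if t_pre >= t_post:
        raise ValueError("t_pre must be < t_post")
    pre = trajectories.at_time(t_pre)
    post = trajectories.at_time(t_post)
    d = np.linalg.norm(post - pre, axis=1)
    if np.allclose(d, d[0]):
        summary = _displacement_summary(d, None, None)
        labels = SubtrajectoryLabels(labels=np.zeros(d.size, dtype=int), scheme="shift",
                                     cutoffs=np.empty(0))
        labels.displacements = d
        return labels, summary
    kde = stats.gaussian_kde(d, bw_method="scott")
    grid = np.linspace(d.min(), d.max(), grid_size)
    density = kde(grid)
    minima_idx, _ = signal.find_peaks(-density, prominence=1e-4 * density.max())
    cutoffs = grid[minima_idx][:2]  # the two smallest-x local minima
    if cutoffs.size == 0:
        warnings.warn("no local minima in the displacement density; single group",
                      RuntimeWarning)
    groups = np.digitize(d, cutoffs)
    labels = SubtrajectoryLabels(labels=groups, scheme="shift", cutoffs=cutoffs)
    labels.displacements = d
    return labels, _displacement_summary(d, grid, density)


@dataclass
class DivergenceProfile:
    """Normalized between-group expression difference over time, in [-1, 1]."""

    gene: str
    times: np.ndarray
    profile: np.ndarray
    diverged: bool
    divergence_time: float | None
    converged: bool
    convergence_time: float | None
    degenerate: bool = False


def normalized_divergence(times, group1_mean, group2_mean,
                          gene: str = "", threshold: float = 0.5) -> DivergenceProfile:
    """Between-group mean-expression difference, normalized by its peak.

    ``profile(t) = (m1(t) - m2(t)) / max_t |m1 - m2|``; positive values mean
    higher expression in group 1.  A gene is flagged divergent at the first
    time |profile| reaches the threshold, and convergent at the first time
    |profile| has dropped by more than the threshold from its running peak.
    """
    times = np.asarray(times, dtype=float)
    delta = np.asarray(group1_mean, dtype=float) - np.asarray(group2_mean, dtype=float)
    peak = np.abs(delta).max()
    if peak == 0:
        return DivergenceProfile(gene=gene, times=times, profile=np.zeros_like(delta),
                                 diverged=False, divergence_time=None, converged=False,
                                 convergence_time=None, degenerate=True)
    profile = delta / peak
    absp = np.abs(profile)
    div_idx = np.nonzero(absp >= threshold)[0]
    diverged = div_idx.size > 0
    divergence_time = float(times[div_idx[0]]) if diverged else None
    running_max = np.maximum.accumulate(absp)
    conv_idx = np.nonzero(running_max - absp > threshold)[0]
    converged = conv_idx.size > 0
    convergence_time = float(times[conv_idx[0]]) if converged else None
    return DivergenceProfile(gene=gene, times=times, profile=profile, diverged=diverged,
                             divergence_time=divergence_time, converged=converged,
                             convergence_time=convergence_time)


def deg_analysis(group_a: np.ndarray, group_b: np.ndarray,
                 gene_names=None, pseudocount: float = 1e-9) -> pd.DataFrame:
    """Per-gene differential expression between two cell groups.

    Reports ``log2((mean_a + c) / (mean_b + c))`` with pseudocount c, the
    Welch two-sample t-test p-value, and BH-adjusted FDR.  Genes with zero
    variance in both groups get p = 1 by convention.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least 2 cells")
    if A.shape[1] != B.shape[1]:
        raise ValueError("gene dimension mismatch")
    m = A.shape[1]
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(m)]
    log2fc = np.log2((A.mean(axis=0) + pseudocount) / (B.mean(axis=0) + pseudocount))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": list(gene_names), "log2fc": log2fc, "p": p,
                         "fdr": fdr, "n_a": A.shape[0], "n_b": B.shape[0]})
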