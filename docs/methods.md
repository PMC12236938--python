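# Methods

This note documents the models and numerical choices behind `profet`, in the
order the pipeline applies them: synthetic data generation, preprocessing,
particle transport, force-matching, evaluation metrics, and downstream
statistics. It also records which design decisions were genuinely open and
why they were resolved the way they were.

## Problem setting

Time-course scRNA-seq gives independent cross-sections: a cells × genes
matrix at each of a few time points, with no cell-to-cell correspondence
across time. The package reconstructs a continuous description of the
population's motion through expression space from those snapshots alone, in
two stages:

1. **Generative particle transport (GPA).** For each adjacent snapshot pair,
   particles initialized at the earlier snapshot's cells are moved downhill
   on a learned potential until their distribution matches the later
   snapshot. The potential is the dual maximizer of the Lipschitz-regularized
   KL divergence, so the induced velocity `v = -∇φ` is bounded by the
   Lipschitz constant `L`. Every particle's position and velocity is recorded
   at every step.
2. **Force-matching.** The recorded per-pair (Lagrangian) velocity samples
   are placed on the experimental time axis and a single time-dependent
   (Eulerian) velocity field `v(x, s)` is fit to them by least squares.
   Integrating this field from any start state yields a continuous
   trajectory over the full time course, including between and (with a
   warning) beyond observed time points.

All modelling happens in a PCA latent space; trajectories are mapped back
through the exact inverse of the linear embedding to read off per-gene,
per-cell dynamics.

## Synthetic EMT generator

The benchmark generator simulates a 26-gene regulatory network with shifted
Hill kinetics and multiplicative noise:

    dx_i = [ g_i · Π_j HS(x_j; λ_ij, Θ_ij, n_ij) − k_i x_i ] dt + D x_i dW_i

`HS(x; λ, Θ, n) = λ + (1−λ)/(1 + (x/Θ)^n)` equals 1 with no regulator and
saturates at the fold change λ (λ>1 activation, 0<λ<1 inhibition). The
packaged topology (`data/emt_grn_topology.tsv`) is a synthetic EMT-style
circuit assembled from canonical motifs (TGFB→SNAIL→ZEB cascade, the
SNAIL/miR-34 and ZEB/miR-200 double-negative loops, epithelial gatekeepers,
marker genes); it is an editable stand-in, not a published adjacency.

Defaults and their rationale:

- **Integration**: Euler–Maruyama, `dt = 0.01` time units, states clipped at
  0 after each step (multiplicative noise makes the origin absorbing in the
  exact dynamics; clipping preserves that).
- **Noise**: `D = 1` — strong multiplicative noise, deliberately so; the
  benchmark is meant to look like noisy single-cell data.
- **Kinetic ensemble**: biological variability is emulated by sampling
  parameter sets per topology: `g ∈ [1, 100]`, `k ∈ [0.1, 1]` (uniform),
  λ uniform on `[1, 10]` (activation) or `[0.1, 1]` (inhibition), thresholds
  uniform in `[0.02, 1.98] × g_j/k_j` (the regulator's unregulated steady
  state), integer Hill coefficients 1–6. 25 parameter sets by default, with
  replicates split evenly across them.
- **Initial conditions**: uniform per gene in `[0, g_i/k_i]`, seeded.
- **Snapshots**: values at the nearest simulation grid point (ties to the
  earlier index), one cell per replicate.

What this emulates — and does not: the generator produces temporally sparse,
noisy, heterogeneous snapshots of a population relaxing through a regulatory
transition. It has no mRNA counting noise, no dropout, no library-size
variation, no cell division or death. Passing the synthetic benchmarks shows
the reconstruction machinery works on distribution-level dynamics of this
kind; it does not certify behavior under count noise or proliferation.
Because kinetic parameters vary 10–100× across the ensemble, within-time
spread is large relative to between-time motion in the later, near-steady
part of the time course — a deliberately hard regime for trajectory
inference.

## Preprocessing

`log(1+x)` normalization, then optional selection of the top-k genes by
sample variance (ddof=1) pooled over all time points, then covariance PCA
(centers, does not scale genes) fit on all training time points pooled.
Loading-column signs are fixed by making each column's largest-magnitude
entry positive, for cross-run reproducibility. The synthetic benchmark is
also log1p-transformed before embedding — simulated expression spans three
decades, and the transform matches how real count data would enter the
pipeline. Default latent dimension is 2 (visualization-scale); the machinery
is tested at moderate dimensions and nothing in it is specific to d=2.

## GPA numerics

- **Dual potential**: MLP with 3 hidden layers × 128 units, every weight
  matrix constrained to spectral norm ≤ 1, output scaled by `L` (default 1).
  The hidden activation is MaxMin (GroupSort-2) rather than ReLU: under a
  hard spectral constraint, rectifier networks cannot preserve gradient
  norm, which biases the variational divergence estimate low and makes the
  stopping rule fire early; MaxMin is 1-Lipschitz and norm-preserving, and
  measurably tightens both the divergence estimate and the shape of the
  transported cloud. ReLU remains available (`gpa.activation="relu"`).
- **Lipschitz enforcement**: exact post-step projection — after each Adam
  update every weight matrix is divided by its top singular value when above
  the cap (cheap persistent power iteration inside the loop, one exact SVD
  projection before a potential is used). The certified bound
  `‖∇φ‖ ≤ L` therefore holds deterministically for every emitted velocity,
  not just in expectation.
- **Objective**: `mean φ(Y) − mean exp(φ(X)−1)` (the f-divergence dual with
  `f(x) = x log x`); the `exp` argument is clamped at 50 to keep early
  optimization finite.
- **Inner loop**: warm-started Adam, 50 iterations at lr 1e-3 per outer
  step; the first (cold-started) fit runs 5× longer. A decreasing objective
  over the last 10% of inner iterations triggers a warning; NaN raises.
- **Outer loop**: forward Euler with step `dt` (default 0.1), stopping when
  the fitted divergence estimate drops below 0.05 or the iteration budget
  runs out. A no-progress warning fires if the objective has not decreased
  across the last quarter of an exhausted budget. A CFL-style guard warns
  when `dt·L` exceeds half the data diameter.
- **Step size per dataset**: with `L = 1` the particles move at most `dt`
  per iteration, so the iteration budget must cover the inter-snapshot
  distance in latent units; `dt` is the knob to adjust per dataset (the
  synthetic EMT benchmark uses `dt = 0.25` with a 300-iteration budget).

The stopping threshold has a useful closed-form intuition: for two broad
clouds of within-cloud scale σ whose means differ by Δ, the L=1 regularized
divergence is ≈ Δ²/2σ², so transport halts when Δ ≈ 0.3σ. Residual offsets
of that order are inherent to the threshold, not solver failures.

## Time alignment and force-matching

Each subinterval's local simulation clock is mapped onto its observation
interval `[t_i, t_{i+1}]`, and velocities are multiplied by the chain-rule
factor `d(local)/d(global)`. The rescaling matters: GPA speeds are capped
at `L`, so without it a field integrated in experimental time could never
traverse the inter-snapshot distance.

Three schedules are available (`align.mode`):

- `per-interval`: affine, local `[0, H_i]` → `[t_i, t_{i+1}]`
  (`H_i = n_T^i·Δt_i`). Simple, but a gradient flow does most of its
  transport in its first few iterations and then crawls — mean particle
  speed on the EMT benchmark is ~0.15·L — so the affine map concentrates
  the whole fast phase into a few percent of the interval with rescaled
  speeds of order `H_i/(t_{i+1}−t_i)` ≈ 30: stiffer than the spectrally
  capped field can represent, and the field fit becomes erratic.
- `longest-horizon`: affine with a single shared rate set by `max_i H_i`;
  leaves late parts of short subintervals unsupervised.
- `relaxation` (pipeline default): the ensemble's cumulative transport
  progress `P` is distributed over the interval along the concave profile
  `P = 1 − (1−u)³` (`u` the normalized global time, exponent `align.warp`).
  Transport remains front-loaded — matching the roughly exponential
  relaxation of both the gradient flow and typical biological processes
  toward their targets — while aligned speeds stay within one order of
  magnitude, which the field fits reliably. A subinterval with no net
  transport falls back to the affine map.

The velocity field is an MLP (4 hidden layers × 64 tanh units) over
`(x, s)`. All layers are spectrally capped at 3 — enough to keep the field
Lipschitz (stable integration, smooth interpolation) while allowing
gain > 1 per layer; a cap of 1 would bound the whole field's Lipschitz
constant by 1 and rule out even `v = −x`. Training is mini-batch Adam on the
mean squared velocity error (batch 256, lr 1e-3, 2000 epochs by default); a
seeded 10% held-out split warns when its loss exceeds twice the training
loss. Trajectories are integrated by forward Euler at 200 steps per unit
time, starting by default from the earliest snapshot's observed cells.
Field-fit quality is the accuracy bottleneck of the whole pipeline — the
integrated cloud can only track the particle paths as well as the
regression tracks the recorded velocities — so the training budget is the
first thing to raise when reconstructions fall short of the GPA endpoints.

## Metrics

Entropic OT cost exactly in the form
`Σ γC + ε Σ γ(log γ − 1)` (so two unit atoms at distance r cost `r² − ε`,
and the debiased Sinkhorn divergence of two atoms is `r²` for every ε),
solved by log-domain Sinkhorn with geometric ε-annealing from `max(C)/10`
down to the target. Defaults: marginal L1 tolerance 1e-4, 2000 iterations,
warning with the residual on non-convergence. The relatively loose default
is deliberate: for well-separated clouds at small ε the cost stabilizes
orders of magnitude before the marginal residual does (measured < 0.1%
value change tightening to 1e-6/10k); exactness-sensitive uses can pass
tighter settings. "W2" in the evaluation report is the entropic cost at the
smallest grid ε (0.01), not its square root.

Squared MMD uses the V-statistic with diagonal terms (γ = 1 by default), so
it is non-negative and exactly zero for identical point sets. TV and KL for
1-D gene marginals use a shared equal-width histogram over the pooled range
with `max(10, ⌈√n⌉)` bins, KL smoothing δ = 1e-10; an all-identical pooled
sample returns 0 by convention.

Baselines: OT-coupling interpolation places mass `γ_ij` at
`(1−t)x_i + t y_j` using the entropic plan (support prunable to the
highest-mass pairs for tractability); random coupling pairs each source
point with a seeded draw from the target (a Monte-Carlo product coupling).

## Downstream statistics

- **Permutation tests**: pooled relabelling with groups of the original
  sizes, p = (#{perm ≥ observed}+1)/(n_perm+1) — the add-one form keeps
  p ≥ 1/(n_perm+1) and finite logs downstream.
- **Fate/origin classification**: k-means on a reference time point with k
  chosen by mean silhouette over candidates {2..8}, then nearest-centroid
  assignment of predicted states (ties to the lowest centroid index).
- **Displacement stratification**: per-cell Euclidean displacement between
  two trajectory times; Gaussian KDE (Scott bandwidth) on a 512-point grid;
  local minima found as peaks of the negated density with prominence
  ≥ 1e-4 of the density maximum; the two smallest-x minima are the
  low/medium/high cutoffs, degrading to 2 or 1 groups (with a warning) when
  fewer minima exist. Summary statistics: mean, sd, IQR, CV (0 when the
  mean is 0), and Shannon entropy (nats) of a 64-bin histogram over the
  KDE grid range.
- **Divergence profiles**: between-group mean expression difference
  normalized by its own peak over time, so the profile lies in [−1, 1] and
  is scale-invariant; a gene is flagged divergent when |profile| first
  reaches 0.5 and convergent when it first drops more than 0.5 below its
  running peak. An identically-zero difference is flagged degenerate.
- **Differential expression**: `log2((mean_a + c)/(mean_b + c))` with
  pseudocount c = 1e-9 (log-normalized inputs), Welch two-sample t-test
  (p = 1 for genes with zero variance in both groups), and BH-FDR reported
  alongside raw p.

## Reproducibility

Every stochastic stage draws its seed deterministically from the run seed
(`sha256(seed:stage) mod 2^31`). A pipeline run writes its configuration,
stage seeds and output hashes to `provenance.json`; re-running the same
configuration reproduces the trajectory tables byte-for-byte.

## Problem sizes used in the shipped benchmarks

The packaged benchmark runs are scaled for a single CPU: the synthetic EMT
run uses 100 replicates (the fixture generator defaults to the full 500),
latent dimension 2, GPA at `dt = 0.25` with stopping threshold 0.01 and a
450-iteration budget (these follow the protocol of selecting the benchmark's
hyperparameters by alignment with its held-out snapshots; the package-wide
GPA defaults remain `dt = 0.1`, threshold 0.05), 1000 force-matching
epochs, and a 600-iteration cap on the evaluation-stage Sinkhorn solver.
The Gaussian transport checks use 200 particles per snapshot. These sizes
are the package's test conditions, and all reported numbers in the README
were produced at them. Benchmark entry points pin the BLAS thread pool to
one thread so their results do not depend on the host's core count.

One caveat the EMT benchmark makes visible: at the second held-out day the
between-snapshot motion is small, and both the reconstruction and the
random-coupling interpolant come close to the held-out snapshot's own
sampling-noise floor (the Sinkhorn divergence between two disjoint halves
of that snapshot is of the same order as either method's error). Rankings
that close are dominated by sampling noise and can flip between simulation
seeds even when the reconstruction is working as designed; the first
held-out day, where the motion is large, separates the methods by a wide
margin at every ε.

## Known limitations

- No population dynamics: proliferation and death are not modelled, so a
  selective expansion is indistinguishable from a phenotypic shift.
- Single modality; no spatial or chromatin information.
- GPA residuals scale with within-snapshot spread (see the stopping-rule
  note above); on data whose between-time motion is small relative to
  within-time heterogeneity, reconstructed means sit up to ~0.3σ short of
  the target snapshot.
- The dual potential is refit per outer iteration from a warm start; a
  potential that is badly underfit can silently slow transport (monitored
  only via warnings).
- Euler integration is first-order; halving the step should roughly halve
  the endpoint error, and the default 200 steps/unit has been adequate for
  latent scales of order 10.
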