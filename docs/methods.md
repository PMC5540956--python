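# Methods

This note documents the models, algorithms and numerical choices behind
`perconet`, what the synthetic generators do and do not emulate, and the
design decisions taken where several reasonable options existed.

## Weighted LFR benchmarks (`perconet.lfr`)

The generator plants a known community structure in a graph with the
heavy-tailed features of brain functional networks.

**Sampling.** Node degrees follow a truncated power law with exponent τ_d
on [k_min, max_k]; k_min is solved numerically (Brent's method on the
closed-form truncated-power-law mean) so the expected mean equals ⟨k⟩. A
sampled sequence is accepted when its mean is within ±2% of ⟨k⟩ (up to 100
resamples), because finite samples only hit ⟨k⟩ in expectation. Community
sizes follow a truncated power law with exponent τ_c on
[min_c, max_c]; sizes are accumulated until they cover N and the excess is
shaved off the largest communities (never below min_c).

**Assignment and wiring.** Each node's internal degree is
(1−μ_t)·k_i with *stochastic* rounding (floor plus a Bernoulli draw on the
fraction), which keeps the expected internal fraction exactly 1−μ_t —
deterministic rounding measurably biases the realized mixing. Nodes are
placed into communities by the standard LFR random-insertion/eviction loop
under the feasibility constraint internal_i ≤ community size − 1.
Intra-community degree sequences are realized *exactly* by Havel–Hakimi
construction followed by degree-preserving double-edge swaps (10·|E| swap
attempts) for randomization; random stub matching with repair is hopeless
for hub nodes whose internal degree approaches the community size.
Inter-community stubs are paired globally with a repair loop that reshuffles
self-pairs, duplicates and within-community pairs; irreparable stubs are
dropped (a per-mille effect on the mean degree). At exact μ_t = 0 any stubs
shed by parity repairs are dropped rather than externalized, so communities
stay mutually disconnected.

**Weights.** Node strength is targeted as s_i = k_i^β (default β = 1.5,
exposed as `strength_exponent`), split (1−μ_w) : μ_w between internal and
external incident edges; an edge carries the mean of its two endpoints'
per-edge shares. This reproduces the target strength and weight-mixing
profile to well within the generator's ±0.05 mixing tolerance.

**Connectivity.** When μ_t > 0 the graph is restricted to its giant
component if that covers ≥ 95% of nodes and regenerated otherwise
(percolation analysis presumes a giant component); realized mixing further
than 0.05 from the target also triggers regeneration (up to 20 attempts,
then an error naming the achieved mixing). Community labels are emitted in
decreasing size order. Everything is a pure function of the parameter set
including the seed.

## Time-series simulation (`perconet.simulate`)

**Target conditioning.** The planted adjacency (zero diagonal, weights on
the LFR scale) is projected onto the positive-definite cone by eigenvalue
clipping at `eig_floor` (default 1e-8) — for a symmetric matrix this single
eigendecomposition *is* the Frobenius-nearest PSD matrix. The result is a
**covariance** target: node variances emerge from the projection (hubs get
larger variance) and the subject-level Pearson step renormalizes per node.
The alternative of forcing a unit-diagonal correlation target
(`adjacency_to_target(..., mode="correlation")`, backed by
`nearest_positive_definite` — Higham alternating projections with Dykstra
correction, iteration cap 200, convergence at 1e-10 Frobenius) requires
rescaling every weight by the largest hub weight, which compresses the
implied correlations by nearly an order of magnitude and with it the
signal-to-noise contrast of the whole downstream chain; it is retained for
inputs already on a correlation scale.

**Generation.** With C = LL^T (Cholesky), per-subject series are
Y = LX + baseline where X is i.i.d. standard Gaussian white noise per node
and timepoint, so cov(Y) = C holds exactly in population. Defaults: 150
timepoints, baseline 100 signal units. Temporal autocorrelation of BOLD is
*not* modeled; consequences are discussed under Limitations.

**Noise.** Rician noise in the standard two-channel magnitude form: each
sample y becomes √((y+g₁)² + g₂²) with g₁, g₂ ~ N(0, σ_N²), where
σ_N = S̄ / SNR and S̄ is the mean absolute value of the noiseless
(baseline-shifted) series, ≈ baseline. σ_N is computed once per series
panel (globally, not per subject). At the default baseline 100 and unit
signal variance, SNR 35 corresponds to σ_N ≈ 2.86 — i.e. noise ~3× the
neural fluctuation amplitude, which attenuates observable correlations by
roughly 1/(1+σ_N²/var) and is precisely what makes weak edges
noise-dominated. Subject k draws from the deterministic sub-seed
`SeedSequence(seed, spawn_key=(k,))`, making cohorts platform-stably
reproducible.

## Group connectivity (`perconet.connectivity`)

Pairwise Pearson correlations per subject (≥ 3 timepoints, zero-variance
series rejected naming the node), then Fisher averaging: r is clipped to
±(1−1e-7), z = atanh r averaged across subjects, and tanh back-transformed
so the group matrix stays on the correlation scale (the back-transform is a
design choice; leaving the average in z-space would only rescale the
threshold axis). For graph analysis the diagonal is dropped and negative
group correlations are discarded — percolation and all three detection
methods operate on non-negative weights.

## Percolation (`perconet.percolation`)

Sparsification keeps edges with weight ≥ t (closed convention: every
observed weight is an attainable threshold, so t\* is always a grid
element). The default grid is the exact set of distinct positive weights; a
`quantile:K` grid bounds the sweep on dense matrices (K defaults to 200 at
the CLI). Giant components are found by breadth-first search (ties toward
the lowest node id; an edgeless graph has giant size 1); the threshold
sweep itself uses an incremental union-find over descending thresholds,
verified in tests to agree with BFS recomputation at every grid point.

"Starts breaking apart" is operationalized as: **t\* = the largest grid
threshold at which the thresholded giant component still contains every
node of the unthresholded giant component** (rule `preserve`). The
alternative reading — the threshold just before the largest single drop in
giant size — is available as rule `maxdrop`. Disconnected inputs are
handled relative to their giant component, with a warning.

## Community detection (`perconet.community`)

**Modularity / Louvain.** Weighted Newman modularity at resolution 1
(no resolution parameter is exposed; none is needed for the validation
protocols). Louvain runs local moves (ties in gain broken toward the lower
community label) and graph aggregation until no move improves Q, restarted
`n_restarts` times (default 16) with seeded node-order shuffles; the best-Q
partition is returned, never scoring below the single-community baseline
(Q = 0). The returned partition's Q matches an independent recomputation
exactly, and on small graphs Louvain attains the exhaustive maximum in
≈ 96% of random instances (asserted ≥ 90% in tests).

**Asymptotical Surprise / PACO.** AS = W · D(q ‖ ⟨q⟩), the binomial
divergence between the observed intracluster weight fraction
q = w_intra/W and the expected intracluster pair fraction
⟨q⟩ = Σ_c n_c(n_c−1)/2 ÷ N(N−1)/2, **one-sided**: AS = 0 whenever
q ≤ ⟨q⟩. Surprise is asymptotically −ln P(X ≥ x), a right-tail
improbability, which vanishes when the observed density does not exceed the
expectation; the two-sided divergence would reward anti-community
partitions and is not a community quality function. Conventions:
0·ln 0 = 0; the all-singleton partition (⟨q⟩ = 0) scores 0 when q = 0.
The PACO-style optimizer starts from singletons and visits edges in
decreasing weight order, merging endpoint communities when AS increases,
followed by single-node move refinement (including spin-off into a new
singleton), iterated to convergence; `n_trials` (default 16) restarts use a
pure Kruskal order first and randomized-greedy jittered orders afterwards
(weight × U(0.5,1)) — with distinct weights, tie-shuffling alone would make
all restarts identical. One additional trial is seeded from a modularity
partition and refined under the AS objective: pure agglomeration can stall
well below the reachable AS on large sparse graphs, and the seeded start
raises the attained objective substantially (e.g. +10% AS on a 600-node
benchmark). On small graphs PACO attains the exhaustive AS maximum in 100%
of tested instances (asserted ≥ 90%).

**InfoMap.** Adapter over python-igraph's `community_infomap`
(map-equation description-length minimization, 10 optimization trials,
igraph RNG seeded per call). The optimizer itself is deliberately not
re-implemented; an unknown or missing backend raises a configuration error
and the pipeline records the method as missing while others proceed.

## Evaluation (`perconet.evaluation`)

NMI is computed from the overlap (contingency) table in natural logs; the
normalization (sum of marginal entropies) makes the log base cancel. Edge
cases: both partitions trivial → 1 (identical); zero-overlap terms
contribute 0. Matching for sensitivity/specificity pairs each planted
community with the retrieved community of largest overlap — many-to-one,
ties toward the smaller retrieved label — and TP/FP/TN/FN are tabulated per
planted community, then averaged unweighted over planted communities.
Specificity's 0/0 case (the planted community covers all nodes) is defined
as 0; sensitivity's cannot occur since communities are non-empty.

## Pipelines and presets (`perconet.pipeline`)

Both protocols are pure functions of their `SimulationConfig` (master seed
included; every stage derives its own sub-seed). Protocol 1 sweeps the
three methods directly over the LFR weights; protocol 2 runs the full
observational chain first. At each grid threshold the method runs on all
non-isolated nodes of the thresholded graph (detection methods handle
disconnected graphs natively) and detached degree-0 nodes become
singletons, since NMI needs every node assigned. t\* is always computed on
the exact unique-weight grid and injected into the sweep grid. Reports are
byte-stable tidy CSVs plus a per-method summary (t\* band across
replicates, peak NMI, NMI at t\*).

Two presets ship: `scaled` (N = 150, 10 subjects, 150 timepoints, SNR 35,
3 replicates, quantile-40 grid) — the routine validation size, chosen so a
full protocol-2 run takes about a minute — and `full` (N = 600, 20
subjects, 5 replicates) for the full-scale protocol. Benchmark defaults
follow the standard parameter set: τ_d = 2, τ_c = 1, ⟨k⟩ = 12,
max_k = 50, community sizes 5–50, μ_t = μ_w = 0.2, cohorts at SNR 35/70.

## What the synthetic data does and does not emulate

Emulated: heavy-tailed degrees and community sizes, controlled topological
and weight mixing, inter-subject variability (independent realizations of a
shared covariance target), magnitude-domain MR noise at realistic SNR, the
subject-then-group Pearson/Fisher pipeline. Not emulated: hemodynamic
response and temporal autocorrelation (white-noise innovations mean
effective sample sizes per correlation are optimistic relative to real
BOLD), physiological noise and motion, spatial smoothing, negative true
correlations (the planted adjacency is non-negative), and task structure.
Passing tests therefore validate the *method logic* under controlled
conditions, not performance on any particular empirical dataset.

## Known limitations

- Asymptotical Surprise prefers fine partitions by construction. At reduced
  network size (N = 150 with communities up to 50 nodes — a third of the
  network), splitting large sparse communities can genuinely increase AS
  once the graph is thresholded to its backbone, so Surprise's NMI at t\*
  hovers near 90% of its grid maximum and can dip below it for some seeds;
  at N = 600 the AS optimum aligns closely with the planted partition.
- The percolation threshold is a single global cut; networks whose
  communities live on very different weight scales fragment asymmetrically,
  and `maxdrop` may be the more informative rule there.
- The LFR generator drops a small number of unmatched inter-community stubs
  (realized mean degree typically 0.5–2% below nominal) rather than
  iterating to an exact match; the acceptance checks budget for this.
- Louvain and PACO are greedy heuristics; their optimality rates are
  measured on small graphs only, and at scale the restart counts trade
  quality for time.
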