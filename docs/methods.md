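# Methods

This note documents the models implemented in ecsampler, the default
parameters and why they were chosen, what the synthetic benchmark systems
do and do not emulate, and the numerical conventions used throughout.

## ΔSEC scoring

For a selected set of coupled residue pairs, `couplings.delta_sec` computes
SEC as the plain sum of pair distances in a conformation and ΔSEC as that
sum minus the same sum in a reference structure. The literal summed-distance
difference is used — per-pair differences are not taken individually or in
absolute value — so the score is additive over disjoint pair subsets and
invariant under rigid motion of the conformation. Positive ΔSEC means
farther from the reference; a "max ΔSEC" strategy explores away from a
known state (e.g. activation away from an inactive reference), a
"min score" strategy moves toward coupled-pair contacts (folding,
association). Cluster scores average ΔSEC over up to 50 randomly chosen
member frames (`n_samples=50`); clusters smaller than that use every
member, which makes the score the exact cluster mean.

Selection of pairs supports both a score cutoff (keep score ≥ c) and a
top-n rank rule; ties at a top-n boundary are broken by canonical pair
order (chain label, then residue index) so selections are reproducible.
Coupling tables are 1-based alignment indices; `structio` maps index k to
the k-th resolved residue of a chain, with an optional integer offset for
constructs whose alignment does not start at the first resolved residue.

Pair distances default to Cα–Cα, the standard convention in evolutionary
contact work; closest-heavy-atom distances are available through
`DistanceSpec(mode="closest_heavy")`. The atom convention matters when
comparing to published distance sums, so it is an explicit, recorded
parameter rather than a hidden default.

## Markov state models

Transition counts use a sliding window (every frame is a window start) at
lag τ; counts are then restricted to the largest strongly connected
component of the count graph, since the reversible estimator is only
well-posed on an ergodic set. The reversible maximum-likelihood transition
matrix is found by the standard self-consistent fixed point on the
symmetric flux matrix x:

    x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j),   T_ij = x_ij / x_i,

iterated until the flux matrix changes by less than 1e-10 (max-norm),
capped at 10⁶ iterations. π comes from the converged flux row sums, which
satisfies detailed balance exactly by construction. Implied timescales are
t_i = −τ/ln λ_i with eigenvalues computed on the π-symmetrized matrix
(numerically real for reversible estimates); non-positive eigenvalues have
no relaxation interpretation and are reported as NaN.

tICA solves the generalized eigenproblem C_τ v = λ C_0 v with the
symmetrized time-lagged covariance and a diagonal regularization of
ε = 1e-10 · trace(C₀)/d on the instantaneous covariance, enough to make
rank-deficient feature sets solvable without visibly perturbing
well-conditioned ones. Probability propagation (`msm.propagate`) applies
p ← pT stepwise rather than forming the matrix power: cheaper for vectors
and bitwise-reproducible against a stepwise reference.

## Kinetic Monte Carlo

Discrete-time KMC draws u ~ U[0,1) per step and selects the next state by
the cumulative-sum rule: move to state j when S_{j−1} ≤ u < S_j for the
cumulative sums S of the current row. The half-open convention means u = 0
selects the first state with positive probability, and rows are validated
to sum to 1 within 1e-9 before sampling. Hit times are counted in frames
× τ: a trajectory absorbed on its first transition has hit time 1τ.
Per-trajectory random streams derive from (seed, trajectory index) via
numpy's sequence seeding, so ensembles are reproducible and independent of
launch order. Mean first-passage times are cross-checked against the
fundamental-matrix closed form (I − Q)⁻¹·1 on absorbing chains.

## Transition path theory

Committors solve the boundary-value linear system directly (dense solve;
the models this package targets have ≤ a few thousand states). Net flux
F_ij = max(0, f_ij − f_ji) with f_ij = π_i q⁻_i T_ij q⁺_j. Pathways are
extracted from the net-flux network by iterative widest-path search:
Dijkstra with max–min relaxation finds the maximum-bottleneck A→B path,
its bottleneck flux is subtracted along the path, and the search repeats
until k paths are found or residual flux drops below 1e-12. Ties between
equal-bottleneck routes break toward fewer hops, then smaller predecessor
state index — a deterministic rule chosen for reproducibility.

## Adaptive sampling engine

A round launches N trajectories of length S from the current seeds,
checks target membership on every frame as trajectories are generated
(first-passage semantics, not round-end checks), pools the frames sampled
so far (cumulative by default; per-round pooling is an option), clusters
the pool, scores clusters, and applies the seed strategy. Total simulation
time at the first hit is exactly (trajectories completed before the
hitting one) × S + (frames of the hitting trajectory up to and including
the hit), with trajectories ordered by (round, launch index). This
hitting-frame accounting is the stricter of the two plausible conventions
(the alternative charges the full final round); grid experiments that
assume round-granularity accounting will read slightly higher values.

Discrete samplers cluster trivially by state label (microstates are the
clusters). Continuous samplers cluster with k-means on the pooled frames;
the pool may be strided (`cluster_stride`) before clustering, which keeps
the cost of cumulative pooling bounded without changing what the pool
represents. An optional `frame_filter` predicate excludes frames from
clustering only — target detection still sees every frame — and serves
use cases like dropping dissociated frames beyond a center-of-mass cutoff
in association runs.

First-passage grids (`fpt_grid`) scan trajectory length S against a
trajectory-count axis: the number of parallel trajectories for the serial
protocol, and the total trajectory count N·R (N fixed, default 10) for
the adaptive protocols. Cells record the median total time over a
configurable number of replicates, with an infinite sentinel for
exhausted budgets; medians over replicates stabilize desk-scale
experiments where single realizations are noisy.

## The 2-D Brownian benchmark

The overdamped particle follows the Euler–Maruyama update

    x_{t+1} = x_t − (D Δt / kT) ∇U(x_t) + sqrt(2 D Δt) ξ_t,

with defaults D = 1 (length²/time), Δt = 2·10⁻⁴ (time), kT = 1 (energy);
well depths are therefore in kT units. Positions beyond 1000× the domain
scale abort the run with a suggestion to reduce Δt. The inner loop is
JIT-compiled (numba) with a pure-numpy fallback; noise is drawn as one
block per trajectory so batched and single-trajectory runs agree under
the same streams.

The shipped default surface is a rugged funnel on [0, 3]²: a deep start
well at (3, 3), a deeper target well at the origin, four metastable
stepping-stone wells along the diagonal (depth 10 kT, σ = 0.16, spaced
0.5 apart), a deterministic field of shallow decorating wells, weak
isotropic confinement (κ = 0.3 about the center), and a channel term
(κ = 3) quadratic in the perpendicular distance from the start–target
line so the corridor cannot be bypassed through flat terrain. The
stones give effective inter-well barriers of roughly 8 kT: a single
serial trajectory (300 000 steps = 60 time units) rarely crosses all six
barriers in sequence, while adaptive reseeding — which restarts all ten
trajectories at the frontier stone each round and retains progress in the
metastable stones — crosses within a few rounds per barrier. The surface
was designed once, from this barrier-height reasoning, to make the
qualitative strategy ordering the benchmark's subject; its exact energies
are conventional, configurable through YAML, and not calibrated to any
molecular system. Benchmark protocol constants: 10 serial trajectories ×
300 000 steps versus adaptive 10 trajectories × 10 000 steps × 30 rounds
with 100 clusters — equal aggregate data for both strategies.

## Synthetic fixtures: what they emulate, and what they don't

`generate_msm` builds a 1-D nearest-neighbor Metropolis chain over a
double-well energy profile (start well, barrier of configurable height in
kT, deeper target well, mild seeded ruggedness). Metropolis acceptance
gives detailed balance by construction, so π ∝ exp(−E) is known in closed
form — the property every MSM and KMC test leans on. The per-state
coordinate |i − target|/(n−1) plays the role of ΔSEC: a scalar,
monotone-to-target guidance signal. `generate_guided_landscape` adds
seeded Gaussian noise to that coordinate and verifies (regenerating at
decreasing noise if needed) that its Spearman correlation with the
forward committor is ≤ −0.8: guidance that is informative but imperfect,
as a real ΔSEC signal would be. 1-D chains were chosen over 2-D lattices
because their π and committors are analytic; chain topology is the main
respect in which they are milder than real conformational networks, where
multiple channels and trap states exist.

`generate_toy_complex` produces two rigid Cα chains whose native pose
(parallel strands 4 Å apart) minimizes the summed coupled-pair distance,
an inter-chain coupling table naming the native contacts, and rigid-
displacement decoys; any candidate decoy that would undercut the native
SEC is rejected, so the native minimum is guaranteed on the emitted set.
Fixture files round-trip through the same CSV/PDB readers the real
pipeline uses.

What passing tests on these fixtures show: the estimators, the
first-passage accounting, and the strategy logic are correct, and the
guided-beats-random-beats-serial ordering holds when guidance genuinely
correlates with progress. What they do not show: performance on real
molecular landscapes (rugged, high-dimensional, multi-channel), the
quality of evolutionary couplings for any particular protein family, or
force-field accuracy — none of which this package computes.

## Numerical conventions and degenerate inputs

- Transition-matrix rows are validated to 1e-9 and renormalized to remove
  float dust, so cumulative sums end exactly at 1.
- Ergodic trimming breaks component-size ties toward the component with
  more total counts, then the lower state label.
- k-means uses scikit-learn's k-means++ with a fixed `random_state`;
  assignment ties resolve to the lowest center index.
- An adaptive target containing the start state hits at round 1, frame 0,
  zero simulation time. A sampler with identity dynamics runs all R
  rounds and reports the not-reached sentinel.
- Residues lacking a χ1 gamma atom (Gly/Ala) are dropped from dihedral
  feature sets with a logged notice; collinear center-of-mass anchors
  raise a degenerate-basis error rather than returning an ill-conditioned
  frame.
- Center of mass uses atomic masses inferred from atom-name element
  prefixes; for Cα-only models this reduces to the geometric centroid.

## Known limitations

- The reversible MLE is a point estimate; no Bayesian error bars, hidden
  Markov models, or coarse-graining (PCCA) are provided.
- KMC is discrete-time only; continuous-time (waiting-time) schemes are
  out of scope.
- PDB parsing handles ATOM/HETATM, first model, altloc and insertion
  codes; mmCIF and binary trajectory formats are not read — sequences of
  `Structure` objects are the extension point.
- The committor and flux solvers are dense and target models of at most a
  few thousand states.
- `fpt_grid` counts adaptive budgets in whole rounds, so count-axis values
  below N collapse to a single round.
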