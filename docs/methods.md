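# Methods

## Objectives

For ordered groups `j = 1..M` with observations `X_{j,i}` (each a
`d`-vector) and a coefficient vector `β`, scores are `β'X`. The package
evaluates three accuracy functionals of the score distributions:

* **EHUM** `D_E(β)` — the fraction of the `n_1·n_2·…·n_M` cross-group
  M-tuples whose scores are strictly increasing in category order. This
  is the empirical plug-in estimate of the hypervolume under the ROC
  manifold (AUC for `M=2`, VUS for `M=3`).
* **ULBA `P_A`** — the mean of the `M−1` adjacent pairwise exceedance
  probabilities `P(β'X_{j+1} > β'X_j)`; `max{0,(M−1)P_A−(M−2)}` lower
  bounds the true hypervolume.
* **ULBA `P_M`** — the minimum of those exceedances; an upper bound.

All indicators are strict: ties contribute zero. Consequently tied data
make the objectives discontinuous on measure-zero sets of `β`, and a
dataset with heavily discretized markers can have objectives that
under-state the accuracy a continuous model would assign. All three
functionals are invariant to positive rescaling of `β`, so the
evaluators accept raw vectors; only the optimizers insist on unit norm.

`D_E` is computed by dynamic programming over categories: group `j−1`'s
scores are sorted once and the number of strictly increasing chains
ending at each observation is accumulated with prefix sums, giving
`O(n log n)` per evaluation instead of enumerating all tuples. A direct
enumerator (`ehum_bruteforce`) is retained and the two are checked
against each other on random (including tied) instances up to 10^5
tuples.

## The spherical pattern search

The optimizer maximizes a black-box `f(β)` over the unit sphere. One
iteration perturbs each coordinate `i` by `±s` and adds to the other
(active) coordinates the smaller-magnitude root `t` of

    m t² + 2t Σ_active β_k + (2sβ_i + s² − Σ_zeroed β_k²) = 0,

which restores `||β|| = 1` exactly (`m` = number of active coordinates;
coordinates with `|β_k|` below the sparsity threshold `λ` are zeroed
first and excluded). The smaller-magnitude root is the one that vanishes
as `s → 0`, so small steps are genuinely local; when the discriminant is
negative the move is impossible at that step and the direction's local
step is divided by the decay rate `ρ` until a real root appears (one
always exists for small enough `|s|` when the active-coordinate sum is
nonzero) or the local step falls below the threshold `φ`, in which case
the direction is skipped for that iteration.

The `2d` candidates plus the incumbent are compared; the best strictly
improving candidate is adopted (ties among candidates: lowest coordinate
index, `+` before `−`). When no candidate improves but one **ties** the
incumbent, the tying candidate is adopted: the objectives are piecewise
constant, and drifting along a plateau repositions the exploration
ladder, which is frequently what carries the search off a plateau onto a
better one. The incumbent value never decreases either way. If the
iteration improved the value by less than `tol_fun`, the global step is
divided by `ρ`.

Iterations continue until the step drops below `φ` (or `max_iter`); that
constitutes one *run*. Each new run restarts the step at `s_initial`
from the previous run's solution. The chain stops when two consecutive
runs return the same point (component-wise within 1e−12), when
`stall_runs` consecutive runs fail to improve the value (under plateau
drift the solution point can keep moving at constant value, so value
stagnation is the robust signal), or at `max_runs`.

### Tuning parameters (defaults)

| parameter | default | role |
|---|---|---|
| `s_initial` | 2.0 | initial / per-run step; 2 spans the coordinate range [−1, 1], so any single coordinate value is reachable in one move |
| `rho` | 2.0 | geometric step divisor on stalled iterations |
| `phi` | 1e−6 | step threshold ending a run |
| `tol_fun` | 1e−6 | minimum improvement that keeps the step |
| `lam` | 0.0 | sparsity threshold (0 = off) |
| `max_iter` / `max_runs` | 50000 / 1000 | hard caps |
| `stall_runs` | 10 | runs without improvement before stopping; larger values buy extra plateau exploration at proportional cost |
| `parallel` | 1 | concurrent candidate evaluations (threads); results are identical to sequential evaluation by construction |

The default start for data-driven fits is the neutral equal-weight
vector `(1,…,1)/√d`. An informative alternative (`sign_adjusted_start`,
equal magnitudes with each sign chosen by the marker's individual EHUM
orientation) is provided but deliberately not the default: on
well-behaved data it sits so close to the population optimum that the
fitted vector inherits the start rather than the data, which biases
resampling studies of the estimator's sampling behavior.

`d = 1` is degenerate (the sphere is `{+1, −1}`); both points are
evaluated directly.

### Known limitations

The step ladder `s/ρ^k` has gaps proportional to the distance from the
current anchor. A strictly better region whose angular width is smaller
than the local ladder gap can be straddled from every reachable anchor
and therefore missed; on `d = 2` problems with `n = 10` per group this
affects a few percent of random instances, where the global optimum
occupies an arc a few thousandths of the circle wide. This is inherent
to geometric-ladder pattern search — no derivative-free method of this
family guarantees the global optimum of a piecewise-constant objective —
and is why the d=2 exhaustive-grid comparison in the acceptance suite is
an equality check on most, but not provably all, random instances.

## Comparator estimators

* **Anchored Nelder–Mead** — the first coordinate is fixed at ±1
  (whichever orientation maximizes marker 1's individual EHUM); the
  remaining `d−1` coordinates are optimized by simplex search
  (`scipy.optimize.minimize`, `xatol = fatol = 1e−4`) starting from zero
  with a unit-step initial simplex — on a piecewise-constant objective a
  conventional tiny initial simplex cannot cross any decision boundary
  and stalls immediately. The result is normalized to unit norm.
* **Step-down** — markers ranked by individual EHUM (descending, ties in
  column order); the leader's coefficient is its best sign; each further
  coefficient is fitted one at a time by a 401-point grid on [−5, 5]
  refined by bounded scalar minimization between the best point's grid
  neighbours, with grid ties resolved toward the smallest |c| (a marker
  that adds nothing keeps a small coefficient). Final vector normalized.
* **Min-max** — each subject's markers are reduced to (max, min); the
  single free direction of the 2-dimensional combination is found by a
  3600-point search of the unit circle (first-argmax tie break). After
  the reduction the cost is independent of `d`. For `M ≥ 3` the same
  reduction is used with the M-group objective.

The comparator inner-search settings are this package's own choices of
conventional values; comparator results are therefore approximations to
any specific historical implementation.

## Synthetic designs

Three generators emulate common biomarker configurations with class
index `i = 0..M−1` and marker index `j = 1..d`:

1. independent `d`-variate normals, means
   `μ_ij = (−1)^j · i · (1 + 0.1(j−1))`, identity covariance — markers
   individually weak with alternating orientations; the
   population-optimal direction is `μ_1 − μ_0` up to scale (equal
   covariances), giving closed-form oracle values
   `Φ(||μ_1 − μ_0||/√2)` used as test anchors;
2. the same means with AR(0.5) covariance `a_st = 0.5^{|s−t|}` —
   correlated predictors;
3. independent three-parameter Weibull margins: marker `j` in class `i`
   is `γ_j + λ_i W`, `W ~ Weibull(shape k_j)`, with `λ_i = i+1`,
   `k_j = 0.5j`, `γ_j = (−5)^j` — skewed and heavy-tailed for small
   shapes, with classes differing only through scale and marker
   locations differing by orders of magnitude. "Multivariate Weibull" is
   interpreted as independent coordinates since only marginal parameters
   are specified.

The replication harness mirrors a train/test design: per replication a
training set is simulated, `β` is fitted by the chosen method/objective,
an independent test set of identical design is simulated, and the
test-set EHUM at `β̂` is recorded; the summary is the replication mean
with its SD and SE (both exposed, since "standard error in parentheses"
conventions differ). These generators produce clean, independent
subjects from known parametric families; they do not emulate missing
data, measurement batch effects, discretized or bounded marker scales,
or covariate-dependent class prevalence — passing benchmarks here
demonstrates correct estimation under the stated designs, not robustness
to those real-data features.

`coefficient_mse` averages squared Euclidean distance after flipping
each estimate into the truth's halfspace, since `β` and `−β` define the
same direction up to the orientation convention.

## Clinical utilities

* **Greedy correlation screening** — repeatedly drop the marker with the
  highest mean absolute pairwise correlation until all `|r|` are below
  the threshold (default 0.8); ties drop the earliest column; constant
  columns are rejected (undefined correlation).
* **Youden cut-points** — for each adjacent split (categories ≤ j vs
  > j) the threshold maximizing sensitivity + specificity − 1 over the
  midpoints of adjacent sorted unique scores (a finite, exhaustive
  candidate set). The multi-class summary is the mean of the per-split
  maxima; this aggregation is a convention of this package, and the
  per-split values are always exposed alongside it.
* **Grade collapsing** — order-preserving merges of ordinal grades, with
  non-monotone maps rejected and resulting class sizes reported.
* **Bootstrap** — resampling is stratified within outcome categories
  (preserving the ordered-group design; no category can empty out).
  Coefficient replicates are sign-aligned to the point estimate before
  the standard error is computed. Intervals are normal-theory
  `estimate ± z_{α/2}·se_B`; with few replicates or a strongly skewed
  statistic (EHUM near 1) percentile intervals would be preferable, a
  deliberate non-goal here.

## Problem sizes in the test and acceptance suites

The acceptance suite reproduces benchmark cells at their printed scale
(100 train/test replications per cell; `d` up to 20, up to 30 subjects
per class) and runs the property checks at 50–1000 random instances
each; the full suite completes in a few minutes on one CPU. Monte-Carlo
moment checks for the generators use 10^5 draws with 4-standard-error
bands.
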