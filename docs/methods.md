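# Methods

## Model

The community state is a vector of genus-level relative abundances
`x ∈ (0, 1]^k` with `Σ x_i ≤ 1`. One simulated day applies, in order:

1. **Growth with a non-extinction floor.** Each genus follows a discrete
   logistic update with pairwise interactions,
   `g_i = x_i (1 + α_i (1 − x_i) + Σ_j x_j β[j,i])`, and the whole product
   is floored at `1e-6`. The floor models mucosal and other refuge niches:
   a genus can fall below sequencing detection but not leave the system.
   The floor applies to the complete bracket product, not to its inputs.
2. **Conditional defecation normalization.** If the community total
   exceeds 1, every genus is divided by the total; otherwise the state
   passes through. Biomass grows freely inside the host, but the excess
   leaves with the stool, so the *relative* state never leaves the unit
   simplex.

The interaction matrix is oriented source-row/target-column:
`β[j, i]` is the effect of genus `j` on genus `i`, so the term felt by
genus `i` is the row-vector product `Σ_j x_j β[j,i]`. The diagonal is
pinned to zero — self-limitation is already carried by the logistic term —
and every coefficient is box-constrained to `[−3, 3]`. A k-genus model
therefore has `k + k(k−1)` free parameters (169 at k = 13).

The unconstrained comparator (`model="glv"`) is the same bracket with no
floor and no normalization. Its states may go negative or diverge; a
trajectory that leaves the representable range is truncated at the last
finite day and flagged, rather than raised, so multi-day prediction
scoring can still use finished pairs. Where neither the floor nor the
normalization engages the two updates are algebraically identical, and the
test suite checks their elementwise agreement to 1e-12 in that regime.

## Fitting

Training data are pairs of observed compositions one day apart. The
objective is the raw cumulative squared deviation
`L = Σ_pairs Σ_genera (one-step prediction − observation)²` — a sum, not a
mean or a root. Longer horizons (2–3 days) are evaluation-only: the update
is iterated and per-pair errors are reported with diverged comparator
pairs excluded and counted.

The optimizer is a seeded multi-start bounded least-squares refinement
(`scipy.optimize.least_squares`, trust-region reflective, `xtol` and
`ftol` both 1e-12, evaluations capped). For states where neither branch
engages the prediction is *linear* in the parameters, so the first start
is the exact per-genus linear regression solution clipped to the box;
further starts are uniform draws from the box. A controlled-random-search
global backend (`algorithm="crs2"`, NLopt GN_CRS2_LM) is wired in for
environments that have nlopt, but the default path has no dependency on
it. Results are deterministic given the seed.

**Identifiability.** If every training start lies exactly on the unit
simplex, then `Σ_{j≠i} x_j = 1 − x_i` and the transformation
`α_i → α_i + δ_i`, `β[j,i] → β[j,i] − δ_i` (all `j ≠ i`) leaves the growth
bracket unchanged: the parameters are structurally non-identifiable along
a k-dimensional family. Strictly normalized observation tables (every
column summing to 1) sit exactly in this degenerate set, so coefficients
fitted to such data are meaningful only up to this shift — one reason
fitted growth-rate signs should be interpreted cautiously. States whose
totals vary below 1 break the degeneracy, and the floored/normalized
dynamics produce such states whenever total growth falls short of 1. The
parameter-recovery benchmark therefore draws its random starts as
Dirichlet profiles scaled to community totals uniform in [0.4, 1]; with
100 noiseless pairs at k = 4 the refit recovers every coefficient to
machine precision.

## Stable-state search

Random starting communities are symmetric Dirichlet draws on the simplex.
The default shape 0.2 per genus produces sparse, few-genus-dominated
profiles spanning the spread of real faecal samples (the census ensembles
of interest combine 1000 such draws with observed compositions). Entries
below the floor are raised to it and the draw renormalized.

A run is **static** when, over the trailing 100 simulated days, the sum
over genera of squared per-genus variances is below `1e-20`. The
grammatically plausible alternative reading — each squared variance below
the threshold individually — is available as `per_genus=True`; it is the
weaker condition (the sum bound implies it). Runs simulate 400 days, then
extend in 100-day blocks until static or a 5000-day cap; a run that never
settles is reported as unresolved, which is a value, not an error (the
unconstrained comparator genuinely oscillates for `α > 2`, e.g. the
period-doubling regime of the discrete logistic map — under the
normalized update the overflow branch absorbs that oscillation by
clamping a saturated genus to 1, which is a fixed point).

Resolved stable states are grouped into **statuses** by hierarchical
clustering: Ward linkage on the condensed Bray–Curtis distance matrix
(`Σ|u−v| / Σ(u+v)`), cutting the tree at the smallest number of clusters
whose every group has maximum within-group distance ≤ `grouping_tol`
(default 0.05). Fixed points from the same basin coincide to near machine
precision, so the cut is insensitive to the tolerance over orders of
magnitude; a tolerance cut was chosen over a fixed cluster count to avoid
a human-in-the-loop dendrogram inspection. Statuses are numbered by
descending frequency and labelled with the dominant genus of the
member-mean profile (argmax; exact ties resolve to the first genus in
order, which can occur in symmetric engineered systems).

## Interventions

Two perturbations act on the *post-growth-step* faecal state of their
scheduled day (treatments happen to the standing community; a laxative on
day 50 and a dose on day 51 occupy distinct slots):

- **Probiotic-like**: add an absolute increment (e.g. 0.05 for "+5%") to
  one genus, then renormalize the total to exactly 1. The increment is
  absolute, not relative to the current total — the distinction matters
  precisely after a laxative, when the standing total is far below 1 and
  a small absolute dose becomes a large share of the renormalized
  community. A relative reading would make post-purge dosing no more
  effective than full-density dosing.
- **Laxative-like**: multiply every genus by a retention fraction
  (default 0.01, i.e. purge to 1% of standing mass). The floor is *not*
  applied at dosing time, so relative proportions are preserved exactly;
  it re-engages on the next growth step. Exploratory strengths (5%, 10%,
  0.1%) are plain values of the same parameter.

Within a day, a laxative executes before a probiotic. After the last
scheduled action the scenario engine keeps simulating until the staticness
criterion is met (first check 400 days after the last action, then every
100 days) or a day cap; with an empty schedule this reproduces the plain
run-to-stability loop bit for bit, which the tests assert.

## Synthetic data

The generator samples `α ~ U(0.1, 1.0)` and off-diagonal
`β ~ U(−0.5, 0.5)` by default: positive inherent growth (bacterial
populations proliferate; fitted growth rates of real faecal series under
this model are positive) and interactions weaker than self-limitation,
which yields communities that converge to interior or boundary fixed
points rather than saturating or collapsing. Trajectories start from a
Dirichlet draw and run `n_days` (default 100), giving `n_days − 1`
consecutive-day training pairs.

Observation noise, when enabled, is a Dirichlet resample of each day's
composition with mean the true state and total concentration `c`
(coordinate variance ≈ `x_i(1−x_i)/(c+1)`), floored and renormalized —
compositional noise for compositional data; additive Gaussian noise would
leave the simplex. What the generator does **not** emulate: sequencing
depth and read-count discreteness, taxonomic misassignment, sample
mislabelling, or autocorrelated host effects (diet, travel, illness).
Passing recovery tests on this generator therefore demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to the full error structure of real 16S time series.

## Numerical choices and limitations

- All arithmetic in double precision; the simplex invariant carries a
  1e-12 tolerance to absorb accumulated rounding.
- Day-pair construction uses exact calendar-day arithmetic; when two
  samples share a date the first in file order is used and the duplicate
  count logged.
- Observed columns may contain exact zeros, which the strictly positive
  state type forbids; entries below 1e-6 are raised to the floor and the
  column rescaled to its original total when model states are built from
  a table.
- Genus selection keeps taxa with dataset-wide mean abundance > 1% and
  lumps the rest into a trailing `other` genus, conserving per-sample
  totals exactly; `other` is always present, possibly all-zero.
- The fitted-parameter benchmarks run at k = 4 (20 free parameters, 100
  pairs, 5 replicates), sized so the full recovery experiment completes in
  seconds on one CPU while still exercising every code path; k = 13 fits
  are supported but their global optimization is the user's compute
  budget, not the test suite's.
- Stability here is established empirically (long-run variance), not
  analytically (no Jacobian eigenvalue analysis); periodic or chaotic
  attractors are reported as unresolved rather than characterized.
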