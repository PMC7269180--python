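# Methods

## Model and assumptions

`atacdecon` performs *partial* deconvolution: the cell-type signatures are
known (derived from purified reference samples) and only the mixing
proportions are estimated. The measurement of one bulk mixture is modeled
as `m = B f` with `f` on the probability simplex. The implicit assumptions
are (i) linear mixing of intensities — accurate for read-count-derived peak
intensities when library depth is normalized; (ii) the reference cell types
span the mixture's composition (no unmodeled type); and (iii) reference and
mixture intensities are on comparable scales after normalization and the
shared monotone transform.

## Peak atlas

Per-sample peak calls are filtered at −log10(q) > 2 (removal at ≤ 2, i.e.
q-value FDR 0.01) and against an optional blacklist (≥ 1 bp overlap under
0-based half-open coordinates removes the peak). Redundancy across samples
is resolved by score-ranked greedy selection: rank all peaks by score
descending (ties broken lexicographically by chromosome, then start, for
cross-platform determinism), keep the top peak, discard everything it
overlaps, repeat. The result is deterministic, order-independent, and
idempotent. Peaks are not resized to a fixed width; an upstream pipeline
that standardizes widths can feed its output in unchanged.

## Reference normalization

Quantile normalization forces every reference sample onto the common
distribution given by the row means of the column-sorted matrix; ties
within a column receive the mean of the reference quantiles they span (the
limma convention), so output is deterministic. Mixtures are *not* quantile
normalized against the reference: normalization is a batch-effect control
among replicated pure samples, and forcing a mixed sample onto the pure
samples' distribution would distort the very composition signal being
estimated.

The median filter computes one global median over all entries of the
normalized matrix and keeps a feature iff its row **maximum** reaches it.
Keying on the maximum (rather than the row mean) protects markers of rare
cell types: a peak open in a single cell type still survives. The median is
computed once; the filter is a single pass, not iterated.

## Cell-type-specific peaks

For each feature the candidate type is the argmax of per-type mean
intensity. Specificity is an intersection–union test: one-sided Welch
two-sample t-tests of candidate > other for every other type, combined by
`p = max(p_k)` — significant only if the candidate beats *every*
competitor. The IUT is conservative under the global null (the passing
fraction at level α is ≤ α up to Monte-Carlo noise), which the test suite
verifies by simulation. Each cell type needs ≥ 2 replicates (within-type
variance is undefined otherwise). p-values are floored at 1e-300 so the
π-value stays finite when a test saturates.

Ranking uses the π-value `log2FC × (−log10 p)`, the standard score
combining effect size and significance. The fold change compares the
candidate mean to the **runner-up** (second-highest) type mean with
pseudocount 1 on both means — stricter than comparing to the average of all
others, and consistent with the IUT's every-competitor logic. No
multiple-testing correction is applied by default (the goal is ranking, not
inference); a Benjamini–Hochberg option adjusts within each cell type.

An equivalent formulation — a linear regression of intensity on cell-type
indicators with one-sided contrasts of the candidate against each other
type — yields the same comparisons; the direct Welch form is used for
speed and transparency.

## Signature matrix

For each per-type count `n` in `g..G` (defaults 50 and 150, the sweep range
standard for condition-number-optimized signature selection), the candidate
feature set is the union of each type's top-`n` CTSPs by π-value; since
each feature is assigned to exactly one type, the union is a disjoint
union. The candidate is scored by the 2-norm condition number of the
z-scored cell-type-means matrix; the minimum wins and ties go to the
smaller `n` (fewer features, same stability). Candidates whose smallest
singular value is below 1e-12 of the largest score as singular and are
skipped; if every candidate is singular the build errors.

Two deliberate choices here:

- **Z-scoring is column-wise** (each cell type standardized across
  features). Standardizing each *row* across the k cell types would center
  every row at zero, placing the all-ones vector in the matrix's null
  space — every candidate would be exactly singular and the sweep
  meaningless. Column z-scoring removes per-type scale and offset so the
  condition number reflects the geometry of the marker patterns, not
  intensity magnitudes.
- **Deconvolution uses the raw means matrix**, not the z-scored copy.
  Z-scoring is a scoring normalization inside the sweep; regressing the
  mixture on a z-scored B would destroy the nonnegative mixing semantics
  of `m = B f`.

A cell type with fewer than `g` CTSPs contributes all it has (with a
warning); a type with none is an error, since no signature could represent
it.

## Data transformation

The Box–Cox profile log-likelihood is maximized over λ ∈ [−2, 2] on the
pooled mixture values (pseudocount 1 added first; intensities contain
zeros). The mixture is the measured quantity whose distribution drives fit
quality, so λ is estimated there and the identical transform is applied to
both B and m. λ̂ is snapped to the nearest of the three named transforms —
boundaries at 0.25 and 0.75, ties snapping upward toward linearity:
log2(x+1) for λ̂ < 0.25, √x for 0.25 ≤ λ̂ < 0.75, identity otherwise. All
three are strictly monotone, so within-column ranks are preserved.

λ's identifiability scales with the data's coefficient of variation: as
CV → 0 all power transforms become affinely equivalent and λ̂'s sampling
variance blows up (≈ 2/(n·CV²)). The synthetic "normal-positive" scenario
therefore uses CV 0.2 (normal with mean 50, sd 10), where the three
scenarios are cleanly distinguishable at n = 5,000; at CV 0.05 no method
can reliably tell them apart, and the choice barely matters for the same
reason.

## SIMPLS

The regression core is de Jong's SIMPLS, implemented from the cross-product
matrix S = XᵀY: each component takes the dominant right singular direction
of the current S, forms the X-weight r = S q, normalizes the score t = X r,
accumulates loadings, and deflates **S itself** (not X) by the orthonormal
basis of X-loadings — the defining difference from NIPALS-style PLS2.
Predictors are mean-centered but not unit-scaled: the signature's intensity
magnitudes carry information. Coefficients are returned for centered data;
with as many components as (full-rank) predictors the solution equals
ordinary least squares, and for a single response it coincides with NIPALS
PLS1 at every component count — both serve as independent oracles in the
test suite.

`n_components` defaults to the number of cell types, capped at the rank of
the centered predictor block (with a warning when reduced). Each mixture is
fit independently — compositions of different samples are unrelated, and
per-sample fits keep failures local.

Post-processing: negative coefficients are set to 0 and the remainder
divided by its sum. If every coefficient is ≤ 0 the estimate is flagged
degenerate (all-zero fractions, no fit p-value) rather than fabricating a
composition.

## Evaluation

RMSE and Pearson correlation compare predicted and true fractions when the
truth is known (per mixture, plus pooled across all mixture-by-type pairs).
Goodness of fit without truth uses the Wasserstein-1 distance between the
*value distributions* of the observed m and the reconstruction B f̂ (for
equal-length vectors: the mean absolute difference of the sorted values) —
an order-free comparison of distributional similarity. The null draws
f ~ Dirichlet(1,…,1), scores B f against m, and the p-value is the add-one
estimator `(1 + #{d_null ≤ d_obs}) / (n_draws + 1)` — always in
[1/(N+1), 1], monotone in d_obs, and approximately uniform when the
"reconstruction" is itself a null draw (verified by simulation). Default
1,000 draws, seeded. An `asymptotic=True` option replaces the empirical
count with a normal approximation to the null distances; the Monte-Carlo
estimator is the default and the calibrated, tested path.

## Synthetic data generator

The generator works at the intensity level (no read-level resampling): a
lognormal background (median 20, log-sd 1 — a realistic dynamic range for
normalized peak intensities), per-type marker blocks multiplied by
`marker_fold` (default 10), optional collinearity blending of type pairs'
mean profiles to emulate lineage-adjacent similarity, replicates and
mixtures perturbed by multiplicative lognormal noise with unit mean and a
chosen CV (default 0.1), and Dirichlet(1) compositions (uniform over the
simplex). Default study conditions: 5 cell types, 2,000 features, 100
markers per type, 3 replicates per type, 100 mixtures.

What it does *not* emulate: count discreteness and depth-dependent shot
noise, batch effects between reference and mixture, unmodeled cell types,
GC/mappability biases, and peak-boundary mismatch between reference and
mixture quantification. Passing tests therefore demonstrate the method's
correctness and calibration under its own assumptions, not its field
performance on arbitrary real data.

## Numerical choices and degenerate inputs

- Condition numbers use SVD with a relative singularity tolerance of 1e-12.
- SIMPLS stops early (with a warning) if the cross-product is exhausted
  before the requested number of components.
- Quantile-normalization ties are interpolated on average ranks —
  deterministic across platforms.
- Welch tests with two zero-variance groups fall back to p = 0 (strictly
  greater) or 1; p-values are floored at 1e-300.
- Greedy atlas ties on score break lexicographically.
- All simulation and Monte-Carlo randomness flows through
  `numpy.random.default_rng` seeded from a single user-supplied seed.

## Known limitations

- Proportions are relative, not absolute abundances; total cellularity is
  unidentifiable from `m = B f` alone.
- Strongly collinear cell types (e.g. a stem type and its immediate
  progenitor) trade off against each other: their estimation errors are
  anti-correlated, and the sum of the pair is estimated much better than
  either member. The condition-number sweep mitigates but cannot remove
  this.
- The median filter and quantile normalization assume a few hundred or more
  features; tiny feature sets trigger warnings.
- Complete deconvolution (estimating B and f jointly) is out of scope.
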