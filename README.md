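# atacdecon

Cell-type deconvolution for bulk chromatin-accessibility (ATAC-seq) and
gene-expression mixtures.

Bulk assays measure an average over the cell types present in a specimen;
shifts in cell composition confound nearly every downstream comparison.
Given reference samples of purified cell types, `atacdecon` estimates the
cell-type proportions in each bulk mixture. It is built for open-chromatin
peak intensities — where distal regulatory elements are highly cell-type
specific — but runs unchanged on RNA-seq or microarray expression tables.

## Model

Each mixture profile is modeled as a linear combination of cell-type
signatures:

```
m = B f,   f >= 0,  sum(f) = 1
```

where `m` is the features-by-1 measurement of one mixture, `B` the
features-by-cell-types **signature matrix** of characteristic intensities,
and `f` the unknown proportion vector. The workflow:

1. **Peak atlas** — per-sample peak calls (narrowPeak/BED) are stripped of
   weak peaks (−log10 q ≤ 2) and blacklist overlaps, then collapsed into a
   non-redundant atlas by score-ranked greedy selection.
2. **Normalization** — the reference count matrix is quantile-normalized
   across samples; features never reaching the global median intensity are
   dropped.
3. **Cell-type-specific peaks (CTSPs)** — each feature's candidate type is
   its intensity argmax; an intersection–union test (one-sided Welch
   t-tests of candidate vs. every other type, combined by max-p) declares
   specificity, and candidates are ranked by the π-value
   `log2FC × (−log10 p)`.
4. **Signature matrix** — per-type marker counts are swept from `g` to `G`
   (default 50–150); the candidate `B` with the smallest 2-norm condition
   number `σ_max/σ_min` (scored after column z-scoring) is kept, favoring a
   stable, well-conditioned linear system.
5. **Transform** — Box–Cox λ is estimated on the pooled mixture values and
   snapped to log2 (λ≈0), square root (λ≈0.5) or none (λ≈1); signature and
   mixture are always transformed identically.
6. **SIMPLS deconvolution** — de Jong's SIMPLS partial least squares solves
   `m = B f` per mixture (components = number of cell types); negative
   coefficients are clipped to zero and the rest renormalized to sum to 1.
7. **Evaluation** — RMSE and Pearson r against known truth, plus a
   Monte-Carlo goodness-of-fit p-value from the Wasserstein-1 distance
   between `m` and `B f̂` under a Dirichlet(1) null.

## Worked example

A fully synthetic study — 5 cell types, 100 marker peaks each at 10-fold
elevation, 3 replicates per type, 10% multiplicative noise, 100 mixtures
with Dirichlet-sampled compositions:

```bash
atacdecon simulation --n-cell-types 5 --n-features 2000 \
    --n-markers-per-type 100 --n-mixtures 100 --seed 7 --outdir sim/
atacdecon deconvolution --pure sim/reference.tsv --phenotype sim/phenotype.tsv \
    --mixture sim/mixtures.tsv --truth sim/truth.tsv --seed 7 --outdir out/
cat out/report.json
```

```json
{
  "chosen_transform": "log2",
  "n_mixtures": 100,
  "condition_number": 1.1456482758159747,
  "mean_rmse": 0.03102523344660251,
  "pooled_pcc": 0.9861825138910812
}
```

The sweep selected a 450-peak signature with condition number ≈ 1.15
(near-orthogonal cell-type columns). Across all 500 mixture-by-type
fractions, predictions correlate with the planted truth at r ≈ 0.986 with a
mean per-mixture RMSE ≈ 0.031 — i.e. estimated proportions are typically
within ~3 percentage points of the truth. `out/proportions.tsv` holds the
per-mixture fractions plus each mixture's RMSE and Wasserstein fit p-value.

The same `deconvolution` subcommand runs on real data: pass your own
reference/phenotype/mixture TSVs (and optionally `--peaks`/`--blacklist`
through `preprocess` to build the atlas first).

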