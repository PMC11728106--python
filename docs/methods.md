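# Methods

## Synthetic data model

The generator emulates a MaxLFQ-scale label-free quantification table.
On the log2 scale each cell is

    x_ij = b_i + Σ_l λ_il f_lj + δ_i · 1[group(j) = treated] + ε_ij

- `b_i ~ N(baseline_mean, baseline_sd²)` — protein baseline abundance;
  defaults (25, 3) place raw intensities around 2²⁵ with a realistic
  dynamic range of several orders of magnitude.
- `λ_il ~ N(0, factor_loading_sd²)`, `f_lj ~ N(0, 1)` — latent factors
  shared across proteins. They create the protein–protein correlation
  that local-similarity (kNN, LLS, RF) and low-rank (SVD, PPCA, BPCA)
  imputers need to outperform single-value methods. Defaults: 5 factors
  with loading sd 1.
- `δ_i = ±log2_fc_magnitude` for a `de_fraction` of proteins (sign
  random), 0 otherwise; the shift is applied to the second group only.
  Default |δ| = 1, matching the fold-change-2 significance cut used in
  the evaluation. `de_fraction · n_proteins` rounds to the exact DE count.
- `ε_ij ~ N(0, noise_sd²)` — replicate noise, default sd 0.5 log2 units.
- Two groups of five replicates by default (group sizes are explicit
  parameters, not derived from any particular experiment).

The returned matrix is `2^x` (raw scale), complete, and paired with the
ground-truth DE flags. Everything is a pure function of the spec and its
seed.

What the generator does **not** emulate: peptide-level structure,
nonlinear or heterogeneous protein–protein dependencies, sample-batch
effects, and intensity-dependent noise. Two consequences matter for
interpreting the benchmark (see "Known limitations"): the data are
exactly linear-Gaussian on the log2 scale, which favours least-squares
and low-rank imputers over forests, and the raw scale is log-normal with
a heavy upper tail, which makes raw-scale NRMSE comparisons
normalizer-dominated.

## Missingness injection

For total missing rate α and MNAR share β on an `n × p` matrix with
`N = np` cells: `n_mis = round(αN)` cells are masked, of which
`n_mnar = round(β·n_mis)` are MNAR and the rest MAR.

- `hard_censor` (default): the MNAR cells are exactly the `n_mnar`
  lowest-intensity cells of the whole matrix — a deterministic detection
  limit, which makes the 100%-MNAR condition exactly reproducible. MAR
  cells are drawn uniformly from the remainder.
- `probabilistic`: MNAR cells are sampled without replacement with
  probability ∝ `exp(−γ·r)`, `r` the cell's intensity rank fraction
  (γ = 10 by default) — a softer, more realistic censoring.

Censoring thresholds are computed on the stored (raw) intensities; log2
is monotone, so the selected cell set is identical either way. A row
guard keeps at least `min_observed_per_row` (default 1) observed cells
per protein by freeing cells in offending rows (MAR first, then the
highest-intensity MNAR cells) and relocating the labels to eligible
cells elsewhere, keeping the counts exact; with the guard active at
β = 1 the masked set can therefore deviate slightly from the exact
lowest-cell set. Infeasible combinations raise an error naming the row.

## The ten imputers

All methods receive whatever scale the caller provides — logarithmization
is an explicit upstream step, never implicit — and satisfy one contract:
output complete, observed cells bit-exact, deterministic given the seed.

- **LOD**: every missing cell ← global observed minimum.
- **SampMin**: missing cell in row i ← row i's observed minimum.
- **ND** (normal downshift): per sample column, missing cells are drawn
  from `N(µ_m − 2.2σ_m, (0.3σ_m)²)` where µ_m, σ_m are the column's
  observed mean and sd (sample sd, ddof 1; a column with one observed
  value degenerates to σ_m = 0 and imputes the mean exactly). The
  per-column scope is the conventional choice for downshifted-normal
  imputation; a `global` scope switch is provided.
- **kNN** (k = 6): rows are observations; the distance between two rows
  is the Euclidean distance over their commonly observed columns scaled
  by `sqrt(p / n_shared)` (no shared columns ⇒ infinite). Each missing
  cell takes the inverse-distance-weighted mean of the k nearest rows
  observed in that column; ties break by row index; zero-distance
  neighbours reduce to their simple mean.
- **LLS** (k = 150): neighbours ranked by absolute pairwise-complete
  Pearson correlation and required to be observed at the target's
  missing columns; the target's observed values are regressed on the
  neighbours' values at those columns (`lstsq`, minimum-norm when
  rank-deficient; neighbour gaps in the design pre-filled with row
  means) and the coefficients predict the missing cells.
- **LSA**: each missing cell gets a protein-based estimate ĝ (simple
  regression on the single most-correlated protein row observed there)
  and a sample-based estimate â (same, on the most-correlated sample
  column); the returned value is `w·ĝ + (1−w)·â` with one global
  w ∈ [0, 1] chosen by closed-form least squares on a seeded 5% holdout
  of temporarily re-masked observed cells. The method is known in the
  field by name only, without a canonical published formulation; this
  adaptive protein/sample mixture is the package's concrete reading.
- **RF** (ntree = 100): missForest-style iterative imputation. Missing
  cells start at column means; columns are visited in order of
  increasing missingness, each regressed on all other columns with a
  seeded scikit-learn `RandomForestRegressor` fitted on its observed
  rows. Sweeps repeat until the normalized sum of squared changes of
  the imputed cells first increases (the previous sweep's matrix is
  returned) or `max_iter` is reached. All variables are continuous, so
  the categorical branch of the original algorithm is omitted.
- **SVD** (nPCs = 4): missing cells start at row means; iterate
  column-centering, rank-q truncated SVD, and re-filling missing cells
  from the reconstruction until the relative Frobenius change of the
  imputed cells drops below `tol` (default 1e-5, `max_iter` 100).
- **PPCA** (nPCs = 1): EM for `x = µ + Wz + ε`, ε isotropic, with the
  E-step conditioning on each row's observed coordinates (rows grouped
  by missingness pattern; exact ECM updates for µ, W, σ² including the
  missing-cell covariance corrections). Missing cells ← posterior
  predictive mean. Convergence is monitored on the observed-data
  log-likelihood — the quantity EM provably never decreases — with
  relative-change tolerance `tol`; seeded random initialization of W.
- **BPCA** (nPCs = 4): variational Bayesian PCA with an
  automatic-relevance-determination prior on the loading columns
  (precision `α_k = d / E‖w_k‖²`), posterior covariance on both scores
  and loadings, and iterative re-filling of the missing cells from the
  current reconstruction. The ARD feedback drives superfluous
  components to zero, making the method robust to overspecified nPCs.
  Convergence on the relative change of the noise precision τ.

## Statistics and metrics

- Differential testing: two-sided pooled-variance Student t per protein
  (a Welch switch exists), df `n_a + n_b − 2`; zero pooled variance
  yields t = 0, p = 1 with a degeneracy flag. "Adjusted p-value" means
  Benjamini–Hochberg (delegated to statsmodels). Fold change is the
  difference of group means on log2 data and the log2 ratio of group
  means on raw data; these differ on skewed data and each is reported
  on its own scale. Significance: adjusted p ≤ 5%, optionally with
  |log2 FC| ≥ 1.
- NRMSE over masked cells only, normalized by the sample variance
  (ddof 1) of the true masked values; zero variance returns NaN as an
  undefined-result marker.
- ROC/AUC: scores are `1 − adjusted p` from the imputed dataset;
  reference labels are the complete-data calls at FDR 5%. AUC uses the
  rank (Mann–Whitney) formulation with mid-rank ties, which equals the
  trapezoidal area under the swept ROC. A single-class reference is
  recorded as missing, not fatal.
- PCA separation: column-standardized PCA of the significant-protein
  submatrix with samples as points; the silhouette score of the group
  labelling in the first two PCs summarizes numerically what is usually
  judged qualitatively from scatter plots.

## Pipeline

Stage 1 derives one child seed per (α, β, replicate) via
`SeedSequence((base_seed, i_α, i_β, rep))`, so conditions are decoupled:
adding replicates or conditions never changes earlier datasets. Each
imputer failure is recorded per record with an error note rather than
aborting the grid. Stage 2 counts true positives against ground-truth
DE flags when available (always, for synthetic data); on real data
without ground truth it falls back to a majority-vote consensus of the
evaluated methods' calls, and the report says which reference was used.

## Problem sizes and tolerances

Unit and acceptance tests run at deliberately modest sizes chosen as
representative of the regime of interest: 40–500 proteins × 8–10
samples, 10–20 seeded replicates per property, trend medians at
500 × 10 with α = 0.25. Convergence tolerances default to 1e-5
(relative change); the exact-completion test for SVD tightens `tol` to
reach its 1e-6 recovery target. The "does not worsen" comparison of
log2 pre-transformation uses a 0.05 absolute slack on median NRMSE to
express qualitative equality.

## Known limitations

- The linear-Gaussian generator is the regime where least-squares and
  low-rank imputers are provably strong; iterative random forest, which
  dominates on real LFQ data with nonlinear structure, does not attain
  the minimum NRMSE here. Passing (or failing) method orderings on this
  synthetic benchmark therefore bound what real-data behaviour they can
  certify.
- Raw-scale NRMSE on log-normal data is dominated by the heavy upper
  tail of the normalizer; comparisons across the raw/log2 pipelines
  inherit that artifact, and single-value left-censored methods look
  artificially good on the raw scale at random missingness.
- The LSA formulation is the package's own concrete reading of a method
  that circulates by name without a canonical formulation.
- No peptide-level simulation or imputation; no batch-effect modelling;
  no moderated-variance (limma-style) testing.
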