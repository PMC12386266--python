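# Methods

## The problem this package addresses

Sarcopenia — the age-related loss of skeletal muscle mass and function — is
increasingly targeted with nutritional interventions, but transcriptomic
biomarkers that report whether an intervention actually worked are scarce.
`sarcomark` implements, as a reusable and fully tested pipeline, a screening
procedure for such nutrition-responsive aging biomarkers in bulk muscle
RNA-seq: it finds genes whose expression changes with age, keeps those whose
change is direction-consistent with muscle mass and expressed at a useful
level, quantifies how strongly each dietary intervention moves each gene
back, and cross-references the survivors against a transcription-factor
target list.

The emulated study design is five groups of mice: a young "Mature" control
(n = 6), an aged "Middle" control (n = 6), and three aged intervention
groups (n = 4 each) receiving allulose (ALL) or low/high molecular weight
collagen hydrolysate (LCOL/HCOL). Eight muscle phenotypes are measured per
animal (quadriceps, tibialis anterior and gastrocnemius weights, hindlimb
thickness, total muscle and fat mass, muscle-to-fat ratio, grip strength),
all normalized to 100 g of body weight except the dimensionless ratio.

## Differential expression engine

Counts are modeled as negative binomial with `Var(y) = mu + phi * mu^2`.
The engine follows the edgeR methodology and its numerics are cross-checked
against Bioconductor edgeR in the test suite:

* **TMM normalization.** For each sample against an automatically chosen
  reference (upper quartile closest to the mean upper quartile), log ratios
  (M) of library-size-scaled counts are trimmed 30% on each side, average
  abundances (A) 5% on each side, and the surviving genes averaged with
  inverse delta-method variance weights. Factors are rescaled to geometric
  mean 1. The tests verify agreement with edgeR's `calcNormFactors` to 1e-6
  and with an independent straight-line transcription of the formula to 1e-8.
* **logCPM.** `log2((y + p_s) * 1e6 / (L_s + 2 p_s))` with a prior count
  `p_s = prior * L_s / mean(L)` (default prior 2) on effective library
  sizes `L_s = lib_size * factor`. The prior is proportional to the
  *relative* library size, so logCPM is invariant to sequencing depth only
  up to `O(prior/count)` — exact at the depths of interest, documented as a
  bound in the tests.
* **GLM fitting.** Per-gene NB GLM with log link and `log L_s` offset,
  fitted by IRLS vectorized across genes (the design matrix is shared; only
  working weights differ), with step halving on the deviance. Agrees with
  `statsmodels` `GLM(NegativeBinomial)` to 1e-6 per coefficient.
* **Dispersion.** The common dispersion maximizes the Cox–Reid adjusted
  profile likelihood (APL: profile log-likelihood minus
  `0.5 * logdet(X'WX)`) summed over genes; tagwise values maximize
  `APL_g(phi) + (prior_df / residual_df) * mean APL(phi)` on a log-spaced
  grid with cubic-spline interpolation — weighted-likelihood shrinkage
  toward the common value with fixed prior degrees of freedom (default 10,
  no trend). Dispersions are floored at 1e-6. The common estimate matches
  edgeR's `estimateGLMCommonDisp` to ~1e-4 in the cross-check.
* **Testing.** Each contrast `(numerator, denominator)` is tested on the
  samples of those two groups by a likelihood-ratio test of the group
  coefficient against chi-square(1). The quasi-likelihood F-test was
  deliberately not used: the LRT is fully defined from first principles and
  calibrates well at these sample sizes (measured type-I error ~5-6% at
  alpha = 5%, n = 6 vs 6). The reported logFC is the group coefficient of a
  refit on counts augmented with a library-size-proportional prior count of
  0.125 per observation, which keeps zero-count groups finite. All-zero
  rows are excluded from testing and reported as filtered. Benjamini–
  Hochberg FDR is applied within each contrast separately; the aging
  contrast (Middle vs Mature) defines the single DEG family, and
  intervention contrasts (each intervention vs Middle) contribute only
  fold changes to the effect score.

## Candidate filtering

Aging DEGs (FDR < 0.05) are reduced by two strict filters: average
logCPM > 0, and quadrant consistency — in the plane of aging logFC (x)
versus the Pearson correlation of the gene's logCPM with total muscle mass
per 100 g body weight (y), only quadrants I (+/+) and III (-/-) survive.
Exact zeros on either axis are excluded (quadrant membership undefined).
The muscle correlation pools all samples of all five groups: a single
coefficient per gene is plotted against a single aging logFC, and the
pooled scope is kept as the default (`correlation_scope` switching was
judged unnecessary because the per-group alternative answers a different
question and is not used downstream). Named "inconsistent-direction" genes
are handled by the quadrant rule itself, not a blacklist. Every rejected
gene carries the exact set of filters it failed.

## Effect score

For an aging DEG with aging logFC `a` (Middle vs Mature) and intervention
logFC `b` (intervention vs Middle),

    effect score = |b| / |a|

so 1 means the intervention moved expression by exactly the aging change.
The source material for this statistic is ambiguous about which ratio
orientation is intended (its prose states both monotonicities and the
typeset formula lost its fraction bar), so both orientations are
implemented; the default follows the reading consistent with the
"score >= 1 in every intervention" responsiveness cut, under which a
higher score is a stronger response. Whether the intervention change
actually opposes the aging change is reported as an `is_reversal` flag
rather than folded into the score (the formula uses absolute values);
`require_reversal_sign=True` zeroes same-direction genes. Ranking within
an intervention is by descending score with ties broken by ascending aging
FDR then gene ID, making reruns bit-identical. The responsiveness filter
keeps genes passing the threshold (default 1) in *every* intervention,
with both `>=` and `>` comparisons available because both cuts appear in
practice.

## Phenotype association and cross-referencing

Gene–phenotype association is the Pearson correlation of a gene's logCPM
with each per-100 g-normalized phenotype, pooled over all samples, with the
regression slope, intercept, `x_mean`, `s_xx` and residual SD emitted so a
95% confidence band can be drawn. The muscle-to-fat ratio is left
unnormalized (the body-weight factors cancel). Grip strength is the mean of
three trials. The TF cross-reference is pure set algebra —
`candidates ∩ responsive ∩ targets` with successive counts and per-gene
provenance — consuming any user-supplied GMT or plain gene list;
constructing the target list (ChEA retrieval, network analysis) is out of
scope by design.

## Synthetic data generator

The generator emulates the five-group design so every stage is testable
without external data:

* Gene baseline abundances are log2-uniform over `baseline_log_mean_range`
  (default (3, 10)), rescaled so the expected library size is
  `lib_size_mean` (default 1e6); per-sample library sizes are
  truncated-normal with CV `lib_size_cv` (default 0.1). Counts are drawn
  gamma–Poisson with a single shared dispersion by default
  (`per_gene_dispersion` draws log-uniform per-gene values instead).
* Default dispersion is phi = 0.04, i.e. a biological coefficient of
  variation of 0.2 — the canonical value for genetically identical model
  organisms such as the inbred mice of the emulated design.
* A fraction `frac_aging_genes` (default 0.1) of genes receive a signed
  Middle-vs-Mature logFC (default magnitude 1.0, signs random). All aged
  groups start from the Middle mean; per intervention, a subset of aging
  genes (default 30%, half of them from a core shared by all interventions
  via `reversal_overlap`) get an opposing logFC of
  `reversal_fraction_of_aging_lfc` times the aging logFC stacked on top.
  Non-reversal aging genes keep the Middle mean under intervention, so the
  ground truth for effect-score recovery is clean.
* Phenotypes are `baseline + scale * (sum_g coupling_g * z_g + noise)` with
  `z_g` the standardized logCPM of driver genes and per-phenotype natural
  baselines/scales (e.g. tibialis anterior 0.10 ± 0.008 g, grip strength
  180 ± 12 gf). Driver couplings carry the sign of the gene's aging logFC,
  which makes the planted genes direction-consistent by construction; half
  of the aging genes (default) drive total muscle mass. Body weight is
  drawn per group with the Mature group lighter (28 g vs ~36-38 g), so
  per-100 g normalization is non-trivial. The muscle-to-fat ratio is
  computed from the sampled masses, never sampled. Because a closed form
  exists for the correlation of this linear-Gaussian coupling
  (`r = c / sqrt(c^2 + sigma^2)`), correlation recovery is testable
  exactly.

What the generator does *not* emulate: read-level artifacts (GC/length
bias, duplication), age-dependent library composition shifts, batch
effects, cell-type composition changes within muscle, sex effects, or
gene–gene correlation beyond the planted group structure and shared
phenotype couplings. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated NB model, not robustness to
those real-data pathologies.

## Numerical choices and degenerate inputs

* IRLS: init from a log-linear least-squares fit on `log(y + 0.5)`,
  linear predictor clipped to ±50, ridge 1e-10 on the normal equations,
  step halving up to 12 times, convergence at relative deviance change
  1e-10, 200 iterations max.
* Dispersion search: bounded scalar optimization on log phi in
  [1e-6, 20]; tagwise grid spans 2^±8 around the common value in 15
  points; if the common value sits at the floor (near-Poisson data) the
  tagwise step is skipped and the common value is used throughout.
* Zero-variance genes or phenotypes yield r = 0 with an explicit flag,
  never NaN. Samples with zero total counts, rank-deficient designs,
  contrasts with < 2 samples per group, NaN p-values, nonpositive body
  weights, missing phenotype cells and duplicate IDs are hard errors.
* Ties in effect-score ranking are broken by aging FDR then gene ID;
  reranking the same table reproduces the identical permutation.

## Problem sizes used in the test and acceptance runs

Simulation-backed checks run at 300–5000 genes and the design's own group
sizes: null calibration at 5000 genes (one seed), logFC recovery at 400
genes × 20 seeds, effect-score recovery at 300 genes × 50 seeds (6/6/4
groups), candidate recovery at 500 genes × 20 seeds, and the end-to-end
golden run at 200–2000 genes. These sizes give stable Monte-Carlo
estimates for the quantities asserted (binomial/KS tolerances are stated
per test) while keeping a full run of the suite around a minute.

## Known limitations

* The LRT is mildly liberal at very small n (measured ~6% at nominal 5%
  with n = 6 vs 6 and estimated tagwise dispersions); the quasi-likelihood
  F-test, which corrects this, is out of scope.
* No trended dispersion: data with a strong mean–dispersion trend will be
  over-shrunk toward a single common value.
* Exact reproduction of any specific edgeR-version pipeline (test flavor,
  filtering, dispersion settings) is a non-goal; agreement is verified at
  the level of the shared methodology (TMM, CR-APL common dispersion,
  NB GLM LRT at fixed dispersion).
* The effect score is a point statistic; no uncertainty is propagated from
  the two fold-change estimates into the score or the ranks.
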