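# Methods

## The classification model

The mesenchymal (Mes) classifier is deliberately minimal: a per-gene median
threshold and a unanimity rule. Given a gene panel S of size k and a reference
sample set R, each gene's threshold is t_g = median over R of x_g (even-count
medians are the mean of the two central order statistics). A sample's gene
score is s_g = **1**{x_g > t_g}. The comparison is strict: a value exactly at
the threshold scores 0. We read "exceeds" literally, and the strict rule is
the one consistent with samples whose panel expression is high yet not called
Mes. The Mes score is (1/k) Σ s_g and a sample is Mes iff the score equals 1.
A relaxed cutoff (`mes_cutoff < 1`) exists but is off by default.

Consequences worth knowing:

* Every quantity depends on within-gene ranks only, so the classifier is
  invariant under any strictly increasing per-gene transform applied to the
  matrix and the reference together (log2, quantile scaling, etc.). Tested as
  a property.
* With thresholds at cohort medians, at most ⌊n/2⌋ samples can score 1 on any
  single gene, and under exchangeability (no signal, independent genes) the
  probability of a Mes call is about 2^−k — the unanimity rule is extremely
  specific.
* The reference population is an explicit argument (`"all"` or a sample-id
  list), never inferred, because both conventions (all tumors; primary tumors
  only) occur in practice.

**Missing genes.** Signatures routinely lose a transcript or two on a given
platform. Thresholded genes absent from the scored matrix are recorded per
call and the score renormalized over the remainder; below 50% availability
(`n_used < ⌈k/2⌉`) classification is refused rather than degraded silently.

## Signature z-scores and the stromal contrast

The signature z-score of sample j for gene set S is the unweighted mean of
z_gj = (x_gj − mean_g) / sd_g over g ∈ S, with per-gene standardization across
the samples of one data set. The sample standard deviation (n−1) is used; the
choice is a convention (nothing downstream is sensitive to n vs n−1 beyond a
constant factor) and is documented because implementations differ.
Standardization tolerance is 1e-9 on row means and sds. Zero-variance genes
are dropped and listed. Z-scores are never computed across merged cohorts:
each data set is standardized within itself.

The stromal contrast is R_j = Z_omental(j) − Z_primary(j), positive when the
sample's stroma resembles omental-metastasis stroma. The quantity is described
in the field as a signed "ratio" of the two signature scores; we implement the
signed combination additively because z-scores take negative and near-zero
values, which makes a literal quotient unstable and sign-ambiguous. A
literal-quotient mode exists behind `mode="quotient"` for sensitivity
analysis. Both signature scores are means of mean-zero rows, so the cohort
mean of R is 0 (within 1e-9) and group means are directly interpretable as
deviations. By linearity, the mean of per-sample contrasts equals the
contrast of group-mean z-scores, so the two plausible readings of a group
summary coincide.

## Concordance and contingency statistics

Cohen's kappa is computed from the 2-class (Mes vs non-Mes) confusion table:
kappa = (p_o − p_e)/(1 − p_e) with p_o = trace/n and p_e = Σ row_i·col_i / n².
The degenerate p_e = 1 case (all mass in one diagonal cell) is defined as 1.0.
A k-class mode falls out of the same formula. Samples labeled `unclassified`
in either scheme are excluded before tabulation.

The two-sided Fisher exact test uses the point-probability rule — the p-value
sums hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed table — matching mainstream statistical
software; two-sided Fisher has competing definitions, so this is stated
explicitly. The implementation delegates to `scipy.stats.fisher_exact`; the
test suite checks it against a full integer-arithmetic enumeration oracle on
random tables with n ≤ 60. Tables with a zero margin carry no information and
return p = 1. Pairwise group tests report raw p-values with a
Benjamini–Hochberg column alongside; the adjustment never gates output.

## Cell-content association

Cell-type content is the percent of one class among the three annotated
classes (fibroblast, epithelial cancer cell, immune) — not of all cells — so
percents always sum to 100 and are scale-invariant in the raw quantities.
Correlations default to Pearson (continuous scores vs percents), with Spearman
available; the method is always recorded in the output. P-values are
two-sided. Strata with fewer than 3 complete pairs, or constant inputs, are
reported as untestable rather than raising.

## The synthetic cohort generator

The generator encodes the biological structure the analysis is designed to
detect, and nothing else:

* **Archetypes.** Four cell classes: primary-site stroma, metastatic-site
  stroma, cancer epithelium, immune. Per-gene baseline means are drawn
  log-uniform on [16, 1024] (arbitrary linear units) and *shared across
  classes*; biology enters as multiplicative fold effects: the Mes panel and
  the omental stromal signature are elevated in metastatic stroma (defaults
  ×8 and ×6), the primary stromal signature in primary stroma (×6). Sharing
  baselines makes the fold ratios exact by construction and keeps the null
  (all folds = 1) genuinely exchangeable.
* **Samples.** Cell fractions ~ Dirichlet; expression = Σ_class fraction ×
  archetype mean, times lognormal noise (sigma 0.15 on the natural-log
  scale). The noise is multiplicative because the emulated inputs are
  continuous normalized intensities, not counts; a count model is out of
  scope.
* **Cohort structure.** The default 200-sample design has four route × stage
  strata: ov-ov stage I-II (n=40, primary stroma, Dirichlet (3,6,1) —
  epithelium-rich), ov-ov stage III-IV (n=80, 25% metastatic stroma), ov-per
  stage III-IV (n=50) and per-per stage III-IV (n=30), the last two fully
  metastatic with Dirichlet (5,4,1) — fibroblast-rich. The effect sizes and
  concentrations are conventions chosen once so that the cohort reproduces
  the qualitative stratum patterns of real site-annotated HGSC cohorts (no
  Mes in pelvis-confined ov-ov, majority Mes at peritoneal sites); no
  quantitative effect sizes exist to copy.
* **Ground truth.** A sample is *intended Mes* iff its stroma is metastatic
  AND its fibroblast fraction is ≥ 0.2. The floor is a generator convention,
  not a biological claim: the Mes program is carried by fibroblasts, so a
  nearly stroma-free bulk sample cannot express it regardless of stroma
  identity.
* **Determinism.** All randomness flows from one integer seed through a named
  `numpy` generator; fixture bundles (TSV/GMT/JSON) are byte-identical across
  runs with the same seed and design, and the manifest hash changes iff the
  design changes.

What the generator does *not* emulate: gene–gene correlation beyond class
mixing, platform effects, probe saturation, count noise, copy-number
structure, or annotation errors. Passing tests therefore demonstrate that the
pipeline's statistics recover the designed signal under the stated mixture
model — not that the biological hypothesis holds in real cohorts, where those
statistics must be recomputed on real data.

## Problem sizes and numerical conventions

The test suite's simulation-backed checks use the default 200-sample cohort
for end-to-end recovery; 50 replicates of n=100 for the slope-recovery power
check; and 200 replicate cohorts of n≈50 on a reduced gene universe for the
null-calibration (type-I error) check — sizes chosen to make each property
sharply decidable while keeping the suite fast. Duplicate gene symbols in
input files are collapsed by keeping the highest-mean row (configurable:
first / mean / max-mean); missing values are rejected unless row-dropping is
requested, because median thresholds and z-scores are ill-defined under
silent missingness. Matrix orientation is genes × samples; transposed files
must be declared, never guessed. The gene panels shipped with the generator
are synthetic stand-ins (real exemplar stromal genes plus canonical
CAF/matrix genes for the Mes panel; placeholder symbols for the two 21-gene
stromal signatures) — in real analyses the published lists are supplied as
GMT files.

## Known limitations

* The Mes call is a hard unanimity rule; near-threshold samples flip with
  platform noise. The score itself (not the call) should be used when a
  continuous readout is wanted.
* Kappa and accuracy are computed on the collapsed 2-class problem by
  default; the 4-subtype problem is supported but not the primary interface.
* Exact tests are limited to 2×2 tables; no chi-square fallback is provided.
* The generator's null calibration is checked for the Fisher test and the
  classifier only; it says nothing about correlation p-values under
  non-normal noise.
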