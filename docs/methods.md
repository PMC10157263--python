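# Methods

This note documents the statistical models behind `seromark`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that matter.

## 1. Cross-omics discovery of a tumour-derived serum marker

**Model.** Two abundance layers — a serum proteome and a tissue
transcriptome — over a shared gene space of ~1000 protein–mRNA pairs. A
gene is a *tumour-derived serum marker candidate* when three independent
pieces of evidence line up:

- serum protein differential: |log2FC| ≥ log2 1.2 and BH q < 0.05,
- tissue transcript differential: |log2FC| ≥ log2 1.5 and BH q < 0.05,
  in the same direction as the protein (concordance required by default),
- positive across-subject Spearman correlation between protein and
  transcript (raw p < 0.05, ρ > 0), computed on the subjects profiled in
  both layers.

**Choices.** The per-feature test is a two-sided Wilcoxon rank-sum: it is
distribution-free, matches the rank-based style of everything downstream,
and is robust to the heavy tails of abundance data. FDR control is
Benjamini–Hochberg within layer. Correlation significance is deliberately
*unadjusted* (exposed as `alpha_corr`, with a BH option): the correlation
criterion is a filter applied jointly with two FDR-controlled differentials,
and the intersection's null expectation is `alpha_corr x alpha_de^2 x
n_pairs` ≈ 0–2 genes per thousand, which the null-simulation tests confirm.
log2 fold changes are computed on library-size-normalised abundances
(columns scaled to the layer's mean total; can be disabled) with a
pseudocount of half the smallest nonzero value per layer. Correlations need
at least 5 complete pairs; below that the pair is emitted flagged-undefined
rather than with an unstable p.

## 2. Absolute κ/λ monoclonality score

A monoclonal B-cell population expresses a single light chain, pushing the
κ:λ output ratio away from the polyclonal balance in *either* direction.
The score

    s(κ, λ) = | log2(κ + ε) − log2(λ + ε) |,    ε > 0 small

is 0 at balance, symmetric under chain swap (implemented as a difference of
logs so the symmetry is exact in floating point), and strictly increasing
in the log-imbalance. The exact functional form is a module-level choice
(`log2` | `log10` | `maxmin`): all variants are strictly monotone
transforms of one another, so every downstream use — rank-sum group
comparisons, per-group Spearman correlations with the serum marker or the
other omics layer — is invariant to the choice. `log2` with ε = 1e-3 is the
default. On the transcript side κ is the single constant-region gene and λ
the *sum* of the λ constant-region paralogs; on the protein side the two
constant-region abundances are used directly.

## 3. Biomarker evaluation

**ROC.** Thresholds run over the unique observed values plus a +∞ sentinel
with the "positive if value ≥ t" convention, so sensitivity is
non-increasing and specificity non-decreasing along the grid. AUC is the
tie-corrected rank (Mann–Whitney) form — exactly pair counting with ties
worth ½. The CI is a stratified bootstrap (resampling within class,
percentile method, 2000 resamples by default, seeded); a bootstrap was
preferred over an asymptotic variance because it behaves sensibly at the
modest class sizes involved (~70 vs ~140).

**Cutoffs.** Two cutoffs with different logics:

- *ROC cutoff*: maximises Youden's J = sens + spec − 1 (a
  closest-to-corner strategy is available); ties break toward the higher
  specificity, then the lower threshold, deterministically.
- *Minimal-AIC cutoff*: for every candidate c in a grid (default: unique
  observed values between the 5th and 95th percentiles) fit
  `logit P(case) = b0 + b1·1[x ≥ c]` and keep the c with the smallest AIC
  (ties toward smaller c). This reading — a dichotomisation scan — is used
  because the step's output is a cutoff in g/L; an alternative reading
  (choosing the spline's knot count by AIC) is provided as
  `rcs_knot_scan` but not used in the default pipeline.

The lower of the two cutoffs bounds the ordinal *mid* band from below, the
higher from above; boundary values belong to the upper level. Under the
default study conditions the AIC cutoff falls below the Youden cutoff
(≈0.8–1.1 vs ≈1.3–1.5 g/L); the code orders them explicitly rather than
assuming.

**Linearity.** Restricted cubic splines in the Harrell form: k strictly
increasing knots give k−1 design columns including the linear term; the
fitted curve has two continuous derivatives and is exactly linear beyond
the boundary knots (the tests check the second derivative vanishes there
numerically). Default 4 knots at the 5/35/65/95 percentiles (3 and 5 knots
at their standard percentiles are available). The non-linearity test is a
likelihood-ratio χ² on the k−2 nonlinear coefficients against the
linear-only logistic fit; its p-value is uniform under a true linear logit
(checked by simulation at n = 500).

## 4. Logistic fitting

All logistic models go through one in-package IRLS fitter: Newton steps
with step-halving (accepting steps within a 1e-10 relative tolerance of the
current penalised log-likelihood, so the quadratic final step is not
rejected for float noise), convergence at relative log-likelihood change
< 1e-10 or 100 iterations, Wald standard errors from the observed
information, AIC = 2k − 2ℓ. Rank-deficient designs raise an error naming a
collinear column set. Complete or quasi-complete separation (diverging
coefficients, singular information) is detected and handled by refitting
with a ridge penalty of 1e-6 on the coefficients, flagged on the result —
perfect-split grids in the AIC scan would otherwise diverge. The fitter is
pinned in the tests against closed-form 2×2-table log-odds-ratios
(exhaustively) and against an independent reference implementation on
random designs.

## 5. Propensity-score matching

The propensity is a logistic model of case status on the pre-specified
covariates (sex, age, date of diagnosis — encoded as days since the
earliest date — bilateral involvement, disease site; covariates are
standardised internally for conditioning). Matching is greedy 1:1
nearest-neighbour on the *logit* of the propensity, without replacement,
processing cases in descending propensity order — deterministic and
hand-traceable, which the tests exploit by replaying the documented order.
Balance is reported as standardised mean differences (pooled-SD form;
proportion form for binary covariates) before and after matching.

Defaults are plain 1:1 (no caliper). Two optional refinements exist for
situations with partial common support, where plain greedy matching
demonstrably leaves residual |SMD| ≈ 0.1–0.15: a caliper (an absolute bound
on the logit-propensity gap; 0.2 pooled within-group SDs is the
conventional width) and `exact=` covariates on which a control must agree
with its case exactly. With both, the balance simulations reach
|SMD| < 0.1 on every covariate in effectively all runs. Cases left
unmatched (excess cases, caliper exclusions) are reported, not fatal.

## 6. The diagnostic model and nomogram

`DiagnosticModel.fit()` chains the pieces: match (EMZL vs pooled controls
by default) → determine both cutoffs and the spline linearity check on the
matched sample (de-biased threshold estimation) → ordinalise the marker on
the full input cohort → build the base design (intercept, mid/high marker
dummies, ROC-derived age indicator) → offer further covariates (lacrimal
gland involvement, bilaterality by default) to forward-AIC inclusion in
listed order, each kept iff it lowers AIC → fit → nomogram.

Nomogram points are affine images of coefficient contributions: each
predictor's levels are anchored at 0 for its minimum-contribution level and
the single largest predictor range is mapped to 100 points; predicted
probability is the inverse logit of `offset + total_points × scale`. This
makes nomogram and model probabilities identical by construction, which the
tests assert to 1e-9.

`split_and_validate` draws a seeded stratified 60/40 split by diagnosis
class (per-class proportions within ±1 subject), builds the model on the
derivation set only, and compares the model score with the continuous and
ordinal marker by ROC on both sets. Calibration bins subjects into
equal-count risk deciles (observed vs mean predicted), with an optional
bootstrap optimism correction: models refit on resamples are evaluated on
the original data and the mean apparent-minus-test gap per bin is
subtracted; degenerate resamples (single-class, or losing a predictor
level) are skipped.

## 7. Synthetic data: what it does and does not emulate

The generators define the study conditions; their defaults are fixed once.

**Paired omics** (`OmicsSimConfig`). 1003 protein–mRNA pairs; serum
proteome of 28 cases + 30 controls; tissue transcriptome of 38 cases + 31
controls; 75% of the smaller arm shared between layers (the overlap is not
known precisely, so it is exposed as a parameter); log2-normal noise of SD
0.8 around N(5, 2) feature baselines; one planted marker with log2FC 2.64
(protein) / 2.0 (transcript) and target cross-layer Spearman ρ 0.6,
induced by a shared per-subject latent factor with the Pearson loading
2·sin(πρ/6) that yields the target rank correlation under bivariate
normality. Non-planted features have zero expected fold change and zero
expected cross-layer correlation. Note the *pooled* case+control
correlation of a planted marker exceeds the latent-factor target because
the shared fold change also correlates the layers; the ρ target is checked
at zero fold change.

**Clinical cohort** (`CohortSimConfig`). Four diagnosis classes at
(68, 33, 26, 78) — EMZL, other lymphoma subtypes, lymphoid hyperplasia,
chronic inflammation; 205 patients. Serum IgM log-normal: cases
exp N(log 1.7, 0.5), controls exp N(log 0.85, 0.5) g/L — chosen to sit in
the physiological range and to give the marker a realistic discriminative
ability (AUC ≈ 0.81 at these settings). Within the control classes log IgM
declines by 0.012 per year of age (age-centred); EMZL IgM is
age-independent. Ages are truncated-normal N(58, 16) on [18, 90] with EMZL
shifted −8 years, so the age indicator carries real signal; sex is
balanced; lacrimal involvement has probability 0.5 in cases vs 0.2 in
controls (the second real predictor); diagnosis dates are uniform over ten
years. EMZL rows carry a post-treatment IgM with expected change −0.5 g/L
(additive Gaussian noise SD 0.25, floored at 0.01 g/L; the floor's bias is
negligible away from low baselines, and the generator's self-consistency
test uses a high-baseline configuration where it vanishes).

**Clonality** (`ClonalitySimConfig`). Per subject, the dominant-chain
share of total light-chain output is Beta-distributed with mean =
`restriction` (cases; dominant chain fair-coin per subject) or 0.5
(controls), concentration 1/noise_sd²; totals are log-normal around
`total_ig_scale`. At restriction = 1 the share is a point mass, giving the
closed-form maximal score. The paired variant shares the case clonal
factor across the transcript and protein layers (with independent
measurement noise) and drives a serum-marker abundance from the same
factor; controls are independent everywhere — this is what makes the
score–marker and score–score correlations case-specific.

**Not emulated:** raw spectra or reads (the generators start at abundance
matrices); batch or platform effects; missingness beyond the layer-overlap
structure; any mechanism behind Ann Arbor stage, IPI or Ki67 (carried as
inert optional columns); correlation between covariates (site, bilaterality
and sex are independent of class except where stated). Passing tests
therefore demonstrate the *inference machinery* is correct and calibrated
under the assumed generative structure — not that real serum IgM data meet
those assumptions.

## 8. Reproducibility and problem sizes

One integer seed feeds named RNG sub-streams (fixed offsets per stage), so
every table the pipeline writes is byte-identical across runs of the same
config. Simulation-based tests use deliberately moderate problem sizes —
tens of seeds for power/recovery checks, hundreds of replicates for
calibration checks at n = 500, 50 discovery replicates at the full
1003-pair scale — chosen so the whole suite illustrates each property
clearly while running in well under a minute per file. The acceptance
script averages the diagnostic-model quantities over 8 replicate
205-patient cohorts because single-cohort cutoff estimates carry visible
sampling noise.

## 9. Known limitations

- Wald standard errors and the χ² LRT are asymptotic; at very small group
  sizes the exact rank tests are the trustworthy part of the output.
- The ridge fallback under separation yields finite but shrunken
  coefficients; the `separation` flag should be checked before
  interpreting them.
- Greedy matching is order-dependent by design (deterministic, documented);
  optimal matching is out of scope.
- The AIC dichotomisation scan treats the cutoff as fixed when computing
  the model's AIC, as is conventional; it does not account for the
  selection over the grid.
- Bootstrap optimism correction refits the final model only; it does not
  replay cutoff determination or forward-AIC selection inside the loop.
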