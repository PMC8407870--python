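# Methods

## The problem

A two-sample summary-data Mendelian randomization (MR) study estimates the
causal effect beta of an exposure X on an outcome Y from per-SNP
association summaries: SNP-exposure effects (gamma_j, sigma_gamma_j) from
one GWAS and SNP-outcome effects (Gamma_j, sigma_Gamma_j) from an
independent GWAS. Validity rests on the instruments being unconfounded
with the outcome. Uncorrected population stratification — subpopulations
that differ in both allele frequencies and phenotype means — violates this
assumption at *every* SNP simultaneously, because the same ancestry
gradient leaks into each per-SNP association.

The diagnostic implemented here runs two extra MR analyses against a
*negative-control outcome*: a phenotype determined before the exposure and
outcome (so it cannot truly be downstream of either, e.g. tanning ability
or natural hair colour) but exposed to the same confounding:

1. exposure -> negative control, instrumented by the exposure's
   genome-wide-significant SNPs;
2. outcome -> negative control, instrumented by the outcome's
   genome-wide-significant SNPs.

A non-null estimate in either analysis signals instrument confounding in
the corresponding GWAS. The *pattern* across estimators separates two
mechanisms: a signal that survives outlier-robust estimators (weighted
median/mode) is consistent with a bias shared by all instruments
(stratification); a signal those estimators erase is consistent with a
pleiotropic minority of SNPs.

## Estimators

All four estimators operate on harmonized pairs (gamma_j, Gamma_j), with
per-SNP Wald ratios Gamma_j/gamma_j and first-order ratio SEs
sigma_Gamma_j/|gamma_j| (the NO-Measurement-Error approximation; the
second-order term is deliberately omitted for simplicity).

* **IVW** — beta = sum(w_j gamma_j Gamma_j) / sum(w_j gamma_j^2) with
  w_j = 1/sigma_Gamma_j^2, i.e. the zero-intercept weighted regression of
  Gamma on gamma. Default is the multiplicative-random-effects variant:
  the fixed-effect SE (sum w_j gamma_j^2)^(-1/2) is inflated by
  max(1, sqrt(Q/(J-1))), Q the weighted residual sum of squares. A single
  instrument collapses exactly to its Wald ratio.
* **MR-Egger** — weighted regression of Gamma on gamma *with* intercept,
  exposure effects first oriented positive. The intercept estimates
  average directional pleiotropy under the InSIDE assumption. SEs carry
  the dispersion floor max(1, sqrt(Q'/(J-2))) (so an exact collinear fit
  reports the pure design SE, not zero); inference uses t(J-2).
* **Weighted median** — ratios sorted ascending; with normalized weights
  w and cumulative sums S_j, breakpoints p_j = S_j - w_j/2; the estimate
  linearly interpolates the sorted ratios at p = 0.5 (clamped to the
  extremes). Consistent when valid instruments carry >= 50% of weight.
* **Weighted mode** — argmax over a 512-point grid spanning the ratio
  range of the weighted Gaussian kernel density with modified-Silverman
  bandwidth h = phi * 0.9 * min(sd, MAD/0.6745) * J^(-1/5) (phi = 1
  default; ties break to the smallest grid point; identical ratios are
  returned directly). Consistent when the largest cluster is valid.

Median and mode SEs come from a parametric bootstrap (default 1000
replicates) that redraws gamma_j* ~ N(gamma_j, sigma_gamma_j) and
Gamma_j* ~ N(Gamma_j, sigma_Gamma_j) independently and recomputes the full
estimate, including weights. Seeds are explicit everywhere; identical
seeds give bit-identical results. p-values use the normal reference for
IVW/median/mode and t(J-2) for Egger; 95% intervals are beta +/- 1.96 se
(t-quantile for Egger).

## Instrument selection and harmonization

Instruments are all SNPs with exposure p < 5e-8 (the community
genome-wide-significance convention); fewer than 5 raises an
"insufficient instruments" error, mirroring standard practice of excluding
under-instrumented exposures. Duplicate rsIDs keep the smallest p-value.
Harmonization aligns outcome records to the exposure's effect allele:
direct match, allele swap (negate beta, mirror eaf), or strand complement
then swap. Palindromic SNPs (A/T, G/C) are resolved by frequency under the
default `drop_ambiguous` policy: kept only when both effect-allele
frequencies are known, outside 0.5 +/- 0.08, and on the same side of 0.5;
everything else (including frequency-discordant palindromes) is dropped
with a recorded reason. `drop_all` drops every palindrome. **LD clumping
is not performed**: instruments are assumed approximately independent, and
that is the caller's responsibility (clump upstream against a reference
panel if needed).

## Flagging rule

Per analysis, with flagging level alpha (default 0.05, configurable):

* `no_signal` — IVW p >= alpha.
* `signal_shared_pattern` — IVW significant and the signal survives the
  robust estimators: at least one of weighted median/mode significant with
  IVW's sign, or both sharing IVW's sign; also used when J < 3 leaves the
  IVW unchallenged.
* `signal_outlier_pattern` — everything else.

The rule is an explicit operationalization of an informal reading —
stratification bias affects all instruments, so it should survive
outlier-robust estimation — and is stored in the report metadata so users
can re-derive flags differently. Flags are advisory: no multiple-testing
correction is applied, and alpha is an indication that results warrant
further investigation, not a hard cut-off. The package does not (and
cannot) validate that a supplied negative control is genuinely
predetermined and confounding-exposed; that is a design judgement.

## Synthetic cohorts

One shared truth (ancestral frequencies ~ U(0.1, 0.9); Balding-Nichols
subpopulation frequencies Beta(p(1-F)/F, (1-p)(1-F)/F), variance F p(1-p);
true effects; allele labels) generates two independent cohorts, giving a
genuine two-sample design. Per individual i in subpopulation s(i):

    X_i  = sum_j gamma_j g_ij + c_X mu_s + eps_X
    NC_i =                      c_N mu_s + eps_N   (+ sum_j alpha_j g_ij)
    Y_i  = beta X_i           + c_Y mu_s + eps_Y

The negative control has no genotype dependence by construction (it is
determined at birth); the optional alpha term exists only for the
pleiotropy scenario. GWAS are per-SNP OLS scans of phenotype on dosage,
optionally adjusting for true subpopulation indicators or the top-k
genotype principal components (covariates projected out of phenotype and
dosages; monomorphic SNPs are flagged not-assessable). Mixed-model scans
are out of scope; the adjustment axis {none, PCs, labels} spans the
phenomenon of interest.

### Desk-scale defaults and why

* n = 10,000 per cohort, 300 SNPs, 100 causal, K = 3 equal subpopulations,
  F_ST = 0.05 — sized so the full acceptance simulations run in minutes on
  one CPU.
* gamma_j = 0.25 + |N(0, 0.1)| on the exposure-increasing allele. The
  floor makes simulated instrument sets what real ones are — strong,
  clearly significant hits (z well above the 5e-8 threshold at n = 10,000)
  — rather than a cloud of near-threshold SNPs whose winner's-curse
  selection would dominate desk-scale behaviour. Phenotype units are
  residual-SD units throughout.
* mu_subpop = (-1, 0, +1) with loadings c_X = c_Y = c_N = 1 in the
  stratified scenario: subpopulation phenotype shifts of one residual SD,
  the strong-stratification end (think social phenotypes across regions),
  chosen so the detection-power properties are stable at desk scale. These
  magnitudes are artifact choices — the mechanism's literature gives no
  quantitative values.
* Pleiotropy scenario: 30% of causal SNPs get direct NC effects
  alpha_j ~ N(0.08, 0.12^2) — directional on average (so the IVW is
  genuinely displaced) but heterogeneous across SNPs. A constant alpha
  across all invalid SNPs would place every invalid Wald ratio on the same
  side at the same place, which in ratio space is a shared shift, not an
  outlier pattern; per-SNP heterogeneity is what makes the mechanism the
  outlier kind that robust estimators absorb.
* Scenarios labelled "no stratification" (null, causal, pleiotropy) set
  F = 0 outright. With F > 0, drifted causal-allele frequencies stratify a
  polygenic exposure on their own — no explicit mean shift needed — which
  would contaminate the baselines. (That emergent effect is real and worth
  knowing about; the stratified scenarios contain it on top of the
  explicit shifts.)
* True causal effect beta = 0.05 in the non-null presets — the scale of
  the effects the application domain reports. It also matters
  numerically: the IVW denominator uses gamma-hat^2, whose expectation
  exceeds gamma^2 by sigma_gamma^2, giving a relative attenuation of
  roughly sigma_gamma^2/gamma^2 (about 1.5% here). The absolute bias is
  proportional to beta while the IVW SE is not, so at desk scale (100
  strong instruments, hence a very small SE) a large beta would push
  attenuation to a visible fraction of an SE; beta = 0.05 keeps the
  interval honest at near-nominal coverage.

### What the simulator does not emulate

No LD structure (instruments are exactly independent — real clumped sets
are only approximately so), no relatedness or family structure, no
mixed-model association scans, no selection/collider bias scenario, no
case-control traits, and allele labels are synthetic (A/G, optionally A/T
via `palindrome_frac` to exercise the harmonizer). Passing tests therefore
demonstrate the pipeline's statistical behaviour under the idealized
confounding mechanism, not performance on any particular real GWAS.

## Numerical and degenerate-input choices

* Reconstructed p-values (missing in input) are two-sided normal tails of
  beta/se, clamped into (0, 1].
* p-values from exact fits (se = 0) are floored at the smallest positive
  float so they stay in (0, 1].
* The Egger fit raises a singular-design error when the oriented exposure
  effects are all equal; the mode returns the common ratio when the
  bandwidth degenerates to zero.
* Bootstrap SEs use ddof = 1; bootstrap weights are recomputed from the
  resampled draws.
* Monomorphic SNPs are flagged, never silently dropped, and excluded from
  instrument selection.
* Study seeds derive from one base seed via numpy SeedSequence spawning;
  truth, cohort A and cohort B use disjoint streams.

## Operating characteristics computed by the studies

`mrnc.experiments` re-derives, from scratch at the defaults above: the
type-I error of the exposure->NC IVW test under the null preset, 95% CI
coverage of beta under the causal preset, the negative-control detection
rate under uncorrected stratification and its return to nominal under
true-label adjustment (200 seeds each), and the mechanism contrast
(60 seeds): the across-seed displacement of the weighted median and the
IVW in units of their mean SEs under the pleiotropy and stratified
presets. The rejection-rate studies evaluate the *fixed-effect* IVW,
whose null z statistic is exactly standard normal, so its size is sharply
nominal; the multiplicative-random-effects default is conservative by
construction (inflation truncated at 1, so its size is below nominal) and
remains the reporting default. Coverage and the contrast use the
pipeline defaults. `scripts/acceptance.py` prints all of them; the test suite
asserts them at binomial tolerances. No empirical number is stated here
that those runs do not themselves compute.

## Known limitations

* The flag rule is a heuristic; disagreeing negative controls are
  presented side by side, never aggregated.
* First-order Wald SEs understate uncertainty when the causal effect is
  large relative to instrument strength.
* The weighted median is not unbiased under a one-sided invalid minority
  in finite samples: an invalid weight share q displaces it to roughly the
  0.5/(1-q) weighted quantile of the valid ratios. At q = 0.3 and many
  instruments this displacement can approach 2 bootstrap SEs even though
  the estimator is consistent; the mechanism contrast is therefore
  reported as an across-seed aggregate, not a per-seed certainty.
* Harmonization of frequency-discordant palindromes drops rather than
  flips them; reproducing published analyses can be sensitive to this
  choice.
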