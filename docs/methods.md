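# Methods

This note documents the statistical models implemented in `adburden`, the
defaults and the reasoning behind them, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter when
reproducing results.

## The ordinal burden model

The outcome is the ordered three-level variable control (0) < late-onset
case (1) < early-onset case (2). The proportional-odds model

    P(Y ≥ k | x) = logistic(β·s + γᵀc − θ_k),   k = 1, 2,   θ_1 < θ_2

shares one burden slope β across both cutpoints, which is exactly the
"ordered burden" hypothesis the design encodes: a single shift parameter
moves probability mass monotonically toward more severe outcomes. The sign
convention is fixed so β > 0 is risk-increasing. The model detects graded
signals (EOAD > LOAD > control), EOAD-specific signals and flat
case-control signals alike, at some efficiency cost for the latter two.
When one outcome level is absent the model reduces *exactly* to binary
logistic regression; the test suite asserts this to 1e-6.

`s` is the additive burden score: the per-sample sum of minor-allele
dosages over the gene × tier selection, unbounded above. `c` are six
population covariates (principal-component analogues). APOE-ε4 dosage is
deliberately **not** a covariate in the main test, because case
ascertainment in contributing cohorts can depend on APOE status; APOE
enters only through the separate interaction analysis.

Fitting is Newton-Raphson with the analytic gradient and observed-
information Hessian, step-halving (up to 40 halvings per step, relative
acceptance 1e-10·|ll|), a gradient-∞-norm tolerance of 1e-8 and a 100-
iteration cap. Frequency weights are supported so covariate-free designs
collapse to ≤ 9 distinct (outcome, dosage) rows. A fit whose line search
stalls at the floating-point plateau of the likelihood is accepted when the
gradient norm is below 1e-6 × (total weight) — at that point the parameter
error is orders of magnitude below the estimate's standard error, and
flagging such fits as failures would bias any analysis that conditions on
convergence. Slope estimates with |β| > 30 are flagged as separated.
Starting values are the empirical cumulative logits (cutpoints) and zero
(slopes).

## Genotype uncertainty and the averaged test

Genotypes are per-call posterior triples over (hom-ref, het, hom-alt).
The burden test is repeated `n_reps` times (default 25 — the design calls
for "multiple" repetitions without fixing a count; 25 keeps the Monte-Carlo
SE of the averaged P well below its rounding precision at the default noise
level) on hard genotypes drawn independently from the posteriors. Missing
calls (depth < 6) contribute a draw from the Hardy–Weinberg prior at the
variant's in-sample MAF. The reported quantities are arithmetic means of
the per-repetition P, β and SE (log-scale averaging of P is available but
not default), plus the across-repetition SD of P. Repetitions that fail to
converge are excluded and counted.

Averaging P values across genotype re-samplings is exactly faithful to the
procedure it implements but is *not* a perfectly calibrated P value: the
mean of dependent uniform variables is under-dispersed, so averaged null P
values show a deficit very close to 0 and 1. At the default noise level
this effect is small — the null rejection rate at α = 0.05 over 1,000
synthetic null genes stays inside the binomial 95% band, and λ on the
averaged P is ≈ 0.97 — but a Kolmogorov–Smirnov uniformity test at n =
1,000 can detect it (D ≈ 0.06–0.07, concentrated near p = 0.92). With hard
genotypes, or with a single repetition, the averaged P is exactly the LRT P
and uniformity holds cleanly; both facts are demonstrated in the test
suite. Users comparing tail areas very close to 0 or 1 should prefer
`n_reps=1` on hard calls or interpret the averaged P as a summary, not a
strict P value.

## Prioritization and QC defaults

* Tiers: LOF(high-confidence) ⊂ LOF+REVEL≥75 ⊂ +≥50 ⊂ +≥25. Missense
  variants without a REVEL score are excluded from missense tiers (not
  imputed) with a counted warning; low-confidence LOF never qualifies.
* MAF < 0.01 in both the sample and the reference panel, ≥ 1 carrier
  (posterior dosage > 0.5); very-rare sub-analysis at 0.001.
* Minor-allele orientation: internal AF > 0.5 flips ref/alt dosages before
  any downstream computation, making the frequency filter orientation-
  invariant.
* Missingness: drop if overall missingness > 20% (missing ≡ depth < 6) or
  if a Pearson χ² on the 2×3 missing × group table has P < 1e-4. The
  differential test and threshold are this package's choice (the design
  names the filter only); both are configurable.
* HWE: Levene–Haldane exact test on controls' hard calls, exclusion at
  P < 1e-6 (configurable). The exact P sums outcome probabilities ≤ the
  observed one; like all exact tests it is conservative (at MAF 0.01,
  n = 5,000 the true null rejection rate at 0.05 is 0.0169 by enumeration).
* cMAC: sum of expected posterior dosages, rounded half-up; testing gate
  cMAC ≥ 10.

## Two-stage inference

Discovery P values get BH-FDR q-values computed over `m_total` tests with
the listed tests occupying the smallest ranks (unlisted tests are assumed
larger than all listed — the assumption required to reproduce a published
top-table's adjusted columns from the top-table alone). Confirmation is
one-sided in the discovery direction; when an effect estimate is available
the one-sided P comes from the signed Wald statistic (equivalently P/2 or
1 − P/2 by sign agreement). The meta-analysis is fixed-effect inverse-
variance on the per-stage log-OR scale with Cochran's Q heterogeneity; a
reference mode pools case/control log-ORs with SEs reconstructed from
printed 95% CIs as (ln U − ln L)/(2·1.96), which is the mode used for the
worked-example reproductions. Familywise significance is Holm–Bonferroni
over `m_total`. P-value ties are broken by stable sort. The λ diagnostic is
median(χ²₁ quantile of 1 − p)/0.45494.

## Power simulator

A scenario is (cMAC, OR_EOAD, OR_LOAD, group sizes, α, test). Each
simulation draws the allocation of the cMAC alleles to the three groups
from a multinomial with probabilities ∝ (n_EOAD·OR_EOAD, n_LOAD·OR_LOAD,
n_control), then places the alleles on distinct chromosomes within each
group (so homozygous carriers arise with the natural probability), and runs
the chosen test: the ordinal LRT (default, covariate-free — covariates can
be simulated but default off) or Firth logistic (case/control or
EOAD-vs-rest). Power is the fraction of simulations with P < α; genes with
cMAC < 10 are never tested, so their power is fixed at exactly 0.
Allocations exceeding a group's chromosome capacity are resampled and
counted. Grid evaluations reuse a common random-number stream across cells,
which makes monotonicity in cMAC and OR hold smoothly in finite samples.
Default group sizes are the discovery-stage composition
(4,060 / 8,592 / 8,693) and the default α is 1e-6.

## Synthetic cohort generator

The generator is retrospective (case-control): group sizes are fixed and
each variant's total allele count (binomial at a population MAF drawn
log-uniformly from the gene's MAF range) is allocated to groups with the
same multinomial law the power simulator uses — matching the generative
assumption of the power analysis rather than a prospective liability model.
Read support is Poisson depth (mean 40) with per-read error 0.01; alt reads
are binomial at fraction {error, ½, 1 − error} by genotype; posteriors are
binomial likelihood × Hardy–Weinberg prior at the population MAF
(configurable to uniform — variant-calling priors are caller-specific and
not pinned by the design). A configurable fraction of calls (default 0.02,
a typical post-QC exome dropout rate) is forced below the depth-6 threshold
and flagged missing with the prior as posterior. Onset/age distributions
are truncated normals (EOAD 58 ± 5 truncated at ≤ 65, LOAD 75 ± 6 at > 65,
controls 70 ± 8): only the ordering and the 65-year boundary matter to the
pipeline, and no published control-age distribution was available to
estimate from, so these are placeholders. Covariates are standard normal
with optional group mean shifts for confounding studies; APOE-ε4 dosages
are binomial(2, f) with f = 0.35/0.30/0.14 per group, typical of AD
case-control samples.

What the generator does **not** emulate: linkage disequilibrium between
variants (alleles are independent), relatedness/pedigrees, batch effects,
X-chromosome dosage, and read-level artifacts. Passing tests on synthetic
cohorts therefore demonstrate the statistical machinery under the model's
own assumptions, not robustness to those real-data complications.

Serialization is VCF v4.2 (GT/DP/AD/PL, 1-based positions, GRCh37-style
naming, biallelic records) plus phenotype and annotation TSVs. PL is the
min-normalized Phred posterior capped at 255, so posteriors round-trip
within PL quantization (≤ 0.02 absolute).

## Sensitivity analyses

* **Age matching:** samples are binned on a fixed 2.5-year grid (cases by
  onset, controls by age); within each stratum the case:control ratio is
  clipped into [0.1, 10] by uniform downsampling; strata with one group are
  excluded. Weights default to overlap-style (cases weighted by the stratum
  control fraction and vice versa, then rescaled to preserve the retained
  count); inverse-probability weights are available — the original
  weighting scheme is described only in an unavailable supplement, so the
  choice is exposed rather than guessed. Unweighted and weighted logistic
  ORs are returned side by side.
* **APOE interaction:** LRT (χ²₁) between outcome ~ score + dosage and the
  same model plus score × dosage, on the ordinal outcome, excluding
  APOE-ascertained sub-cohorts via a phenotype flag.
* **Allelic balance:** pooled alt-read fraction across heterozygous
  posterior-mode carriers per variant, two-sided exact binomial test
  against 0.5 (a per-depth empirical reference can be supplied); flagged
  when P < 1e-4 *and* fraction < 0.4, the somatic-mosaic signature.
* **Variant validation:** selected variants with ≥ 15 carriers are tested
  by Fisher's exact 2×2 (variant carriers vs other-selection carriers ×
  case/control); variants significantly weaker than the rest (BH FDR < 0.1
  within the gene, OR < 1) are removed to form the refined selection,
  which never increases cMAC. Excluded protein-modifying variants with
  ≥ 15 carriers are logistic-tested for association as inclusion
  candidates.

## Problem sizes used in the self-checks

The bundled calibration suites use 1,000 null genes at 3,000 samples for
type-I error, 200 replicates at n = 6,000 for CI coverage, 2,000
simulations for null power and 500 per grid cell for monotonicity — sizes
at which the Monte-Carlo bands quoted in the tests are meaningful while a
full run stays in the minutes range on a single core.

## Known limitations

* The averaged P is a summary statistic, not an exact P value (see above).
* Attributable fractions use the OR as a relative-risk approximation and
  the in-sample carrier frequencies; they are in-sample estimates, not
  population projections.
* No variance-component (SKAT-type) tests, mixed models, random-effects
  meta-analysis, X-linked models, or variant merging for complete linkage.
* The ordinal model assumes proportional odds; strongly non-proportional
  signals (e.g. protective in LOAD, deleterious in EOAD) are better served
  by the per-bin multinomial estimates, which are reported alongside.
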