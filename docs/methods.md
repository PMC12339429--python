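# Methods

This note records the statistical conventions the package implements, the
design decisions taken where more than one convention is defensible, what
the synthetic-data generators do and do not emulate, and the known
limitations.

## Spontaneous-report model and ingest

A report is a set-valued record: a report id, an optional case version,
a set of normalized drug names, a nonempty set of MedDRA Preferred Terms
(PT code + name), age, sex, country, outcome set and receipt date. Only
the PT level of MedDRA is modelled; SOC/HLGT/HLT navigation is out of
scope, as is parsing the native FAERS/JADER/CVARD archive formats — ingest
is delimited text with a user-supplied column map and list separator.
Drug-name standardization is a config-supplied synonym map applied after
lower-casing and whitespace collapsing; the package ships no hard-coded
dictionary because generic-name mappings are jurisdiction-specific.

**Deduplication** collapses records sharing the composite key
(report id, sex, country). The survivor is chosen by highest case
version, then latest receipt date, then last position in file order.
The first criterion is the usual case-versioning rule; the two
tie-breaks are conventions chosen for determinism — reporting systems do
not specify them — and are therefore part of this package's contract, not
a property of the source databases. Deduplication is idempotent.

**Age bands.** Two schemes are provided, both half-open `[low, high)` so
that every age in [0, 130] falls in exactly one band: a descriptive
scheme (0–11, 12–17, 18–34, 35–64, 65–79, ≥80) for demographic tables and
a regression scheme (<18, 18–44, 45–65, >65 ⇔ [0,18), [18,45), [45,66),
[66,∞)) for modelling. Published four-band groupings are printed
inconsistently across sources ("18–44/45–65" vs "18–45/46–65"); the
half-open resolution guarantees a partition, and band labels are
overridable in config so either rendering can be produced. Missing age
maps to "unknown"; negative age is a domain error.

## Disproportionality statistics

All three statistics compare the observed count *a* of the target pair
with its expectation under independence, so their signs agree exactly;
the test suite asserts this as a property.

* ROR with log-normal CI. Any zero cell triggers the Haldane–Anscombe
  +0.5 on all four cells for the ROR only, and the result is flagged
  `corrected` — inputs are never silently changed.
* PRR with the Pearson χ² of the table. Yates continuity correction is
  off by default (the more common convention in the disproportionality
  literature) and available as a switch. A zero in *c* alone corrects the
  PRR point estimate the same way; zero row margins are a domain error.
* IC in the observed-to-expected shrinkage form
  IC = log₂[(a+½)/(E+½)], IC025 = IC − 3.3(a+½)^(−1/2) − 2(a+½)^(−3/2).
  This is the standard closed-form approximation to the BCPNN posterior;
  the shrinkage keeps all cells finite and IC025 < IC always. (Published
  tables occasionally print an "IC025" larger than the IC; no shrinkage
  IC can produce that, and the package does not try to.)
* The 2-of-3 rule defines signal status. For priority *scoring*
  eligibility a weaker ≥1-of-3 gate is the default (`scoring_gate`),
  mirroring the practice of triaging anything any method flagged while
  reserving "signal" for 2-of-3 agreement; both gates are config.

**Volcano statistics** use the two-sided Fisher exact p per PT and a
Bonferroni universe m = number of distinct PTs co-reported with the
target drug in the dataset, not all of MedDRA — the per-drug framing that
a volcano plot of one drug's events implies.

**Priority rubric.** Points per criterion: DME 2 / IME 1 / none 0;
reporting rate ≥10% → 2, [1%, 10%) → 1, <1% → 0; case-fatality rate
>50% → 2, [25%, 50%] → 1, <25% → 0; stability 3-of-3 → 2, 2-of-3 → 1,
else 0. Published band labels overlap at the edges ("0%–1%" vs "1%–10%");
the half-open resolution above is fixed by the published worked
scorecards themselves (a reporting rate of exactly 0.010 scores 1 point).
Totals 0–2 / 3–5 / 6–8 map to low / moderate / high. The score is
monotone in every input. DME/IME membership is an input flag — the EMA
lists are licensing-encumbered and not shipped.

## Logistic regression

Maximum likelihood via iteratively reweighted least squares (binomial
GLM, statsmodels backend), Wald CIs and p-values — matching the OR
(95% CI) + P presentation convention — with dummy coding against declared
reference levels. Records with unknown age or sex are removed listwise;
with categorical age bands this is the only procedure that leaves a
well-defined band model. The univariable screen carries a covariate into
the single multivariable model when any non-reference level has P < α
(default 0.05). Coefficients diverging beyond ±15 on the log scale are
reported as (quasi-)separated with an infinite-CI marker rather than
crashing; Firth correction is out of scope.

## Two-sample MR

**Instrument selection** follows the standard funnel: p < 5×10⁻⁶
(config; 5×10⁻⁸ available), greedy LD clumping in ascending-p order
discarding same-chromosome SNPs with r² > 0.001 within 10,000 kb of a
retained index SNP, then the weak-instrument filter F = (β/SE)² > 10.
Every exclusion is logged with its reason.

**Harmonization** aligns the outcome to the exposure effect allele,
resolving strand flips via complements. Palindromic A/T and C/G SNPs are
oriented by allele frequency when both EAFs are away from 0.5 and dropped
when either EAF is in [0.42, 0.58] (config), the common default window.
Exposure betas are then oriented nonnegative (flipping both members of a
pair, which leaves the Wald ratio invariant) so the Egger intercept has a
defined sign convention; the orientation is recorded per SNP.

**Estimators.** First-order weights wⱼ = se(β̂y)⁻² throughout; no
NOME/second-order correction.

* IVW: weighted regression through the origin. Default SE is the
  fixed-effect SE inflated by max(1, √(Q/(k−1))) — multiplicative random
  effects, the dominant convention for small instrument panels, which
  never narrows the CI below the fixed-effect one. Normal p-values.
  k = 1 is served only by the explicit `wald_ratio` path.
* MR-Egger: weighted regression with intercept. SEs use the plain WLS
  residual variance Q/(k−2) (no floor at 1) and p-values are Student t
  with k−2 df — the exact classical test for the weighted linear model,
  and the convention under which the published intercept p-values
  reproduce (an intercept/SE ratio of exactly 1.0 giving p = 0.351 at
  df = 7 is a t-tail, not a normal tail). The floored variant would be
  doubly conservative: its measured intercept-test size in this package's
  calibration suite is below 1% where the nominal level is 5%. A
  (near-)constant exposure-beta design is non-identifiable and raises.
* Weighted median: interpolated weighted median of the per-SNP ratios
  with weights se(ratio)⁻², se(ratio) = se(β̂y)/|β̂x|; SE by seeded
  parametric bootstrap (default 1000 draws).
* Mode estimators: argmax of the normal-kernel density of the ratios on a
  512-point grid spanning the ratios ± 3 bandwidths; bandwidth is the
  modified Silverman rule 0.9·min(sd, mad/0.6745)·k^(−1/5) scaled by a
  `bandwidth_factor` (default 1). Simple mode weights equally, weighted
  mode by se(ratio)⁻²; SE by the same seeded bootstrap.
* OR presentation is exp(β) with exp(β ± 1.96·SE) bounds for every
  method.

**Diagnostics.** Cochran's Q about the fixed-effect IVW fit (df k−1) or
the Egger fit (df k−2), with upper-tail χ² p. MR-PRESSO compares the
observed weighted residual sum of squares about leave-one-out IVW fits
with its distribution under a parametric no-outlier model (default 1000
simulations, seeded); the global p is rank-based, per-SNP outlier
p-values are each SNP's simulated residual tail, Bonferroni-adjusted by
k, flagged at α. Leave-one-out refits IVW k times and raises an
influence flag when any sub-estimate leaves the full-panel CI (note that
under multiplicative random effects a gross outlier inflates that CI, so
the flag is most informative with `random_effects=False`).

## Synthetic-data generators

`simulate.srs` draws, per report: target drug ~ Bernoulli(p_drug); target
PT ~ Bernoulli(p_event_background · rr if drug else p_event_background),
optionally shifted per age band on the logit scale; independent decoy
PTs; demographics from configurable marginals whose defaults follow a
FAERS-like case mix (≈48/47/5% female/male/unknown, 45% missing age, 17%
hospitalization, 2.1% death, US/UK/Canada-dominated countries). Default
scale is 200,000 reports with p_drug 0.5%, background rate 0.03% and
rr = 12 — a rare-event regime in which the expected ROR approximates the
planted relative risk at the strong-signal scale seen in real
growth-hormone/brain-neoplasm mining. A duplicate-injection mode
replays exact copies of sampled reports to exercise deduplication. The
generator does **not** emulate drug co-prescription correlation,
PT co-occurrence structure, reporting trends over time, or
between-database overlap; passing calibration tests therefore shows the
estimators are correct under independence, not that real reporting data
satisfy it.

`simulate.gwas` works directly on summary statistics (two-sample MR
consumes nothing else, and this keeps generation at desk scale): per-SNP
exposure effects uniform on [0.1, 0.5] with reported SE 0.05 (instrument
F in the 4–100 range typical of a small protein GWAS), outcome effects
βy = β_causal·βx + pleiotropy + heterogeneity + N(0, se_out), se_out
0.14, sample sizes 3,301 (exposure) and 178,726 (outcome) mirroring a
small proteomic exposure study against a biobank outcome. The outcome
model is applied to the *reported* exposure coefficients, so
weak-instrument regression dilution is deliberately absent: the
calibration suites measure estimator correctness, not robustness to
measurement error in β̂x. Pleiotropy is none / balanced(sd) /
directional(mean, sd); a configurable fraction of SNPs is palindromic
with intermediate EAF, and a random half of outcome rows is emitted on
the swapped allele orientation, so harmonization always has real work in
end-to-end tests. The truth record stores every latent draw, making any
generated value recomputable from the seed.

## Numerical and reproducibility choices

* z₀.₉₇₅ is used at full precision (1.959963984540054), not 1.96.
* All simulations, bootstraps and MR-PRESSO draw from
  `numpy.random.default_rng` seeded from a single config seed; pipeline
  reruns with the same config are byte-identical (TSV floats are written
  at 10 significant digits).
* Calibration problem sizes — 200 replicates for recovery/coverage/size
  suites, 500 for type-I error, 100 each for MR-PRESSO
  specificity/sensitivity, 100 for report-level ROR calibration at the
  default 200k-report scale — are the package's chosen trade-off between
  Monte-Carlo precision and suite runtime.
* Published-value checks are asserted to one unit in the last printed
  digit; printed inputs (e.g. a Q statistic at three decimals) cannot
  support tighter agreement.

## Limitations

* No EBGM/MGPS empirical-Bayes scoring or time-scan disproportionality.
* PRR/χ² are undefined on zero row margins (by design, raised as
  errors); only the ROR silently corrects, and it says so.
* MR scope: no one-sample MR, multivariable MR, Steiger filtering or
  colocalization; LD is consumed as a pairwise r² lookup, not computed
  from a reference panel.
* The regression arm reports Wald inference only; profile-likelihood CIs
  and Firth correction are not implemented.
* Real-database headline estimates (e.g. a FAERS-scale ROR or a
  biobank-scale IVW OR) are not reproducible from this package alone:
  they require the original record-level extracts and unpublished
  outcome-GWAS per-SNP statistics. The package reproduces everything
  derivable from published worked values and validates the rest by
  simulation with known truth.
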