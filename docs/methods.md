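# Methods

## The problem

A correction formula QTc = f(QT, RR) is judged good for a population if
the corrected value is statistically independent of heart rate there.
`qtcselect` operationalises the full adjudication: apply candidate
formulas, derive cohort-optimal corrections, compare residual RR
dependence, derive reference limits from a healthy subset, and ask
whether the resulting "prolonged QTc" flags predict mortality.

## Correction formulas

Six published laws are built in (Bazett, Fridericia, Dmitrienko,
Framingham, Hodges, Rautaharju); any custom power-law or linear law can
be constructed through `CorrectionFormula`. Internal units are seconds
for QT/RR and bpm for HR. The published linear coefficients
(0.154 s/s, 0.185 s/s, 0.00175 s/bpm) are dimensionally meaningful only
with RR in seconds, so the seconds convention is used end to end and
values are scaled to ms only in outputs. The Rautaharju male offset is
stored as 0.006 s. HR inside Hodges is derived as 60/RR so a single
(QT, RR) pair determines every correction. All six laws are neutral at
RR = 1 s; neutrality (and the exact 6 ms male offset) is enforced by
tests at 1e-12.

## Synthetic cohorts

The generator emulates a middle-aged, non-hospitalized cohort and is the
package's ground truth:

* **Demographics.** Sex ~ Bernoulli(female_fraction = 0.564). Age ~
  N(48.60, 9.35²) truncated to [35, 70] y by rejection. Heart rate ~
  per-sex truncated normals (M 65.99 ± 10.87, F 75.16 ± 11.59 bpm,
  truncated to [35, 140] bpm so RR = 60/HR stays physiological). RR is
  derived deterministically from HR — one free variable, no
  inconsistency between the two columns.
* **QT/RR law.** Either a power law qt = scale_sex · rr^e + ε (default
  e = 0.333; presets 0.333/0.413/0.500) or a linear law
  qt = 0.267 + 0.155·rr − 0.009·male + ε, with ε ~ N(0, qt_noise_sd²),
  default 8 ms. The per-sex scales (0.414/0.424 s = QT at RR = 1 s) put
  mean QT at each sex's mean RR near 404/396 ms, the regime the default
  demographics imply.
* **Flags.** cvd_history / medical_condition / qt_drug are independent
  per-sex Bernoulli draws (M 9.8/20.0/22.4%, F 13.9/44.4/28.1%); QRS ~
  N(97, 10.4²) ms; 2% non-sinus rhythm.
* **Survival.** Event times are exponential with rate
  h₀ · HR_true^exposure; h₀ defaults to −ln(1−0.011)/1095 ≈ 1.010e−5 per
  day, the closed-form rate giving 1.1% cumulative three-year mortality.
  Administrative censoring is N(1165, 110²) days with draws below 1095
  clipped to 1095 (a minimum three-year follow-up), so three-year
  mortality is unaffected by censoring. 56% of deaths are labelled
  cardiac. An exposure column (any binary flag) can carry a true hazard
  ratio, default 3.0.
* **Seeding.** One integer seed is split into named substreams via
  `numpy.random.SeedSequence.spawn`, so adding a stage never perturbs
  earlier draws; outputs are byte-identical across runs for a fixed
  seed.

What the generator deliberately does *not* model: QT/RR hysteresis and
within-subject variability (one ECG per subject), correlated
comorbidities, age or comorbidity effects on QT, non-proportional or
time-varying hazards, and any drug-name-level pharmacology. Passing
tests therefore demonstrate that the statistical machinery is correct
under the stated generative assumptions — not that any particular
formula is best in a given real population.

## Filters

Eligibility drops incomplete records, non-sinus rhythm, and QRS
strictly above 120 ms (exactly 120 ms is retained). The healthy subset
additionally requires all three flags clear and RR in the inclusive
interval [0.5, 1.5] s. A subject failing several criteria is tallied
once, under the first failing criterion in the listed order, so reports
reconcile exactly. "Incomplete" is operationalised as any required
field missing. If a free-text medication column and a user-supplied
drug-name list are available, `recompute_qt_drug` rebuilds the flag from
membership; otherwise the boolean flag is trusted.

## Optimum-correction methods

1. **Linear RR (+sex):** OLS qt ~ rr + male; corrected value
   qtc₁ = qt + β·(1−rr). The correction is applied in the
   neutrality-preserving form (identity at RR = 1 s) rather than as a
   raw regression prediction, mirroring how the Framingham correction is
   used in practice.
2. **Linear HR:** OLS qt ~ hr; qtc₂ = qt − β·(hr−60), neutral at 60 bpm.
3. **Log–log per sex:** OLS log qt ~ log rr within each sex; the slope β
   is the exponent and qtc₃ = qt/rr^β. Natural logs are used; the slope
   is base-invariant (tested against a base-10 oracle).
4. **Zero-correlation grid search:** d over 0.301–0.499 in steps of
   0.001, minimising |Pearson r| between qt/rr^d and rr; ties go to the
   smaller d for determinism. On noise-free power-law data the search
   returns the generating exponent exactly for every grid-aligned value.

Numerical notes: rank-deficient designs (constant rr/hr, single sex)
are rejected with descriptive errors rather than silently pseudo-
inverted. At an exactly matched exponent the corrected column is
constant up to float64 rounding; the post-correction qtc~rr r² is
reported as 0 in that degenerate case instead of regressing rounding
noise.

## Formula assessment

The slope criterion regresses QTc (ms) on RR (s) within sex; ranking is
by |slope| ascending, ties by smaller r², then by name — a total,
stable order. On noise-free power-law data the slope sign follows the
exponent ordering exactly (formula exponent above the generator's ⇒
negative slope, below ⇒ positive, equal ⇒ zero), which is the
over-/under-correction law the criterion relies on. Pairwise agreement
reports Pearson r, the paired-t mean difference, and Bland–Altman bias
with limits of agreement at bias ± 1.96·SD (ddof = 1); 1.96 is used
verbatim, as is conventional. Zero-variance differences yield an NaN
paired-t p-value but the bias and limits are still reported. Assessment
defaults to the healthy subset, the population the optimum-correction
fits use.

## Normal limits

LLN/ULN are the 5th/95th percentiles of the healthy subset per formula
and sex, using the weighted-average-at-(n+1)p percentile definition (the
default of the major commercial statistics packages, so limits are
reproducible against them); tests pin the implementation to an
independent sort-and-interpolate oracle at 1e-12. At least 20 values
are required so both percentiles are interior. CIs are nonparametric
bootstrap percentile intervals (default 2000 resamples, seeded,
vectorised); the CI method for empirical reference limits is not
standardised, and the bootstrap is this package's declared choice.

## Mortality validation

Prolongation is strict: flag = 1 iff QTc > sex-specific ULN.
Diagnostic metrics are the usual confusion-matrix ratios ×100; 0/0
ratios are reported as missing (NaN), never as 0, to avoid silently
biased summaries. Cox models use lifelines with Breslow tie handling.
Cardiac-mortality models follow the cause-specific-hazard convention:
non-cardiac deaths are censored at their death time. The stepwise
competition enters all six flags plus forced covariates (age, heart
rate) that are never removed, and repeatedly removes the flag with the
largest Wald p ≥ 0.10 (the conventional backward-Wald removal
threshold; configurable). Byte-identical duplicate flag columns would
make the design singular and are dropped up front and recorded in the
result. Non-convergence (e.g. complete separation when events are very
few) is surfaced with the step index rather than hidden.

## Pipeline

`run_pipeline` chains the stages from one config and writes seven
artifacts plus a manifest (seeds, versions, row counts); reruns with the
same config and seed are byte-identical. The survival stage needs a
prolongation exposure before QTc limits exist, so the pipeline derives a
provisional flag — Bazett-corrected QT above the sex-specific 95th
percentile of the raw cohort — and attaches the configured hazard ratio
to it. Demographic comparisons use a pooled-variance t test (Welch
configurable) and a Pearson chi-square without continuity correction.

## Problem sizes

Defaults mirror the cohort structure the generator emulates: n = 7071
subjects, of whom ~6850 are eligible and ~2950 healthy. The test suite
exercises full-scale runs where a quantity is pinned to a size
(grid-search recovery at 2000 RR points, OLS recovery at n = 7071,
mortality calibration at n = 200 000, Cox recovery at n = 20 000) and
smaller replicate studies (e.g. 100 stepwise replicates at n = 4000
with an elevated baseline hazard of 5e-5/day so each replicate has
adequate events) for Monte-Carlo properties; each test states its sizes
explicitly.

## Known limitations

* The generator's independence assumptions (flags independent of QT and
  of each other; exposure-independent censoring) are idealisations.
* Reference limits and diagnostic metrics on synthetic cohorts say
  nothing about clinically valid cutoffs; deriving those requires real
  populations and external validation.
* The stepwise competition inherits the usual caveats of stepwise
  selection (post-selection inference is not corrected).
* With very few events the Cox machinery can fail to converge; the
  package reports this honestly instead of penalising by default, and a
  user wanting ridge-stabilised fits should enlarge the cohort or the
  event rate.
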