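# Methods

This note documents the models, rules and numerical choices behind
`certscore`, and what the synthetic-data tests do and do not demonstrate.

## 1. The certificate model

A certificate follows the WHO international MCCOD form: Part 1 holds up to
four lines of the chain of events (line *a* the immediate cause, the lowest
used line the underlying cause of death, UCOD), each with an onset-to-death
interval; Part 2 holds contributing conditions. The batch CSV schema is
flat (one column per cause line, intervals encoded `value;unit`) because no
canonical register export format exists; transcribed paper certificates and
native online records are treated identically. Structural problems (an
interval unit without a value, an entirely empty Part 1, a leading blank
line above the chain) are *validation findings*, reported separately from
certification errors: they indicate unusable data rather than poor
certification, and `assess()` refuses structurally invalid records rather
than scoring them.

## 2. Error detection rules

Each of the seven error types is a deterministic predicate on the record
plus a `RuleConfig` of lexical knowledge. All matching happens on
normalized text (lower-cased, accents stripped, whitespace collapsed);
default lexicons are Spanish clinical vocabulary with English aliases.
Design points that were genuinely open, and how they were resolved:

* **Binary per type.** An error type counts once per certificate however
  many lines exhibit it. A per-occurrence count would push the score range
  above what a 2/1-weighted seven-type score can reach; the binary reading
  is the only one consistent with the score arithmetic (§3).
* **Time intervals are checked on Part 1 only** (one missing interval among
  used lines triggers the flag). Part 1 intervals are the ones online
  certification systems make mandatory and the ones coders need to order
  the chain.
* **Sequence checking** maps each used line's condition to one of ~20
  categories and tests every *adjacent* used pair: the lower line's
  category must reach the upper line's in the transitive closure of a
  shipped cause→consequence graph. Unmapped conditions are compatible (the
  rule only flags what it can positively identify as improbable), and a
  UCOD whose category is marked *non-initiating* (a mode of dying) is
  flagged regardless of pairing. This is a conservative, fully overridable
  automation of a human reviewer's clinical judgment; the shipped graph is
  an explicit stand-in, not a clinical authority. Only the mapped
  mode-of-dying term participates in the non-initiating mechanism by
  default — the other ill-defined terms are deliberately unmapped so that
  an ill-defined UCOD does not automatically imply an improbable sequence,
  and the two major errors stay independently plantable.
* **Blank lines** means an empty line strictly *inside* the used span.
  A leading blank (empty 1a below which the chain starts) is a structural
  finding instead, since the error concerns gaps within the chain.
* **Abbreviations** are flagged from a lexicon of common Spanish clinical
  abbreviations plus a heuristic: an all-capitals alphabetic token of 2–6
  letters not on a whitelist (Roman numerals). Parts 1 and 2 are both
  checked.
* **Additional errors** carry four reported subtypes: a bare external-cause
  UCOD lacking both an intent and a mechanism term; a neoplasm term with
  neither a site nor a behaviour qualifier (checked on every cause text);
  age recorded without units (modelled as an absent age unit); and "other"
  — unqualified hypertension, unqualified diabetes, or a UCOD-capable
  condition left in Part 2 while Part 1's UCOD is ill-defined. The
  aggregate flag is the OR of the subtypes and contributes at most one
  point however many subtypes fire.

Co-occurrence of "incorrect sequence" and "ill-defined UCOD" on one
certificate is allowed; nothing in the rubric forbids it.

## 3. Scoring

`score = 2·n_major + 1·n_minor`, range 0–11 (4 major, 3 minor types);
`correct` means zero error types. Observed cohorts rarely exhaust the
range — scores above 9 require at least three major and two minor types
simultaneously — so fitted models typically see 9–10 outcome levels. The
theoretical maximum is not truncated. Weights are configurable for
sensitivity analysis; the 2/1 default is the assessment rubric's.

## 4. Tables

Percentages are computed on unrounded counts and rounded (1 d.p.) only at
rendering. Improvement columns are percentage-point differences against the
pre-intervention arm: for error prevalences the *decline* `pre − arm`, for
the correctly-certified share the *rise* `arm − pre` (reported on the
correct row only). Months-from-training bands are `<3`, `3–6` (3-month
boundary inclusive), `>6`; those rows cover only certificates carrying the
field (the trained arm). Attribute categories with zero certificates are
omitted rather than shown as empty rows, and no ordering or smoothing is
imposed on non-monotone attribute patterns (e.g. seniority).

## 5. Inference

* **Pearson chi-square** with expected counts from the margins,
  `df = (r−1)(c−1)`; a zero margin is an error (collapse upstream).
* **Welch t-test** (unequal variances, Welch–Satterthwaite df). Welch is
  the safer default when group variances differ; nothing in the pipeline
  guarantees equal variances across arms.
* **Proportional-odds model.** Cumulative-logit parameterization
  `P(Y≤k|x) = logistic(α_k − x'β)`, so `exp(β) > 1` means higher odds of a
  worse score. Reference-cell coding with defaults: pre-intervention arm,
  male, ill-defined cause group, 0–5 years seniority, general medicine,
  facility level I; any reference is overridable, and switching a reference
  is a pure reparameterization (identical maximized likelihood; the
  contrast OR equals the ratio of the base ORs — both identities are
  tested to numerical tolerance). Age enters continuously per year; when
  only age bands are available, band midpoints
  {2, 24.5, 54.5, 69.5, 79.5, 90} stand in for exact ages.

  **Optimization.** Damped Newton–Raphson on the joint
  (cutpoints, coefficients) vector, with cutpoints kept ordered through the
  transform `α_1 = θ_1, α_k = α_{k−1} + exp(θ_k)`. Analytic gradient and
  Hessian; a ridge fallback handles a singular Hessian far from the
  optimum; step-halving guarantees the log-likelihood never decreases
  (asserted in tests). Convergence at gradient max-norm `1e-8` or 100
  iterations; non-convergence returns a result flagged
  `converged=False` with a warning rather than raising. The covariance is
  the inverse observed information in the natural (α, β) space at the
  maximum. Unobserved outcome levels are collapsed implicitly (levels are
  the distinct observed values); levels with fewer than 5 observations are
  retained with a logged warning. Rank-deficient designs raise an error
  naming the aliased columns (pivoted QR).

  **Reporting.** Odds ratios `exp(β)` with delta-method standard errors
  `OR·se(β)` — the convention in which regression tables usually print the
  SE of the OR — alongside the coefficient-scale standard errors; two-sided
  Wald p-values, no multiple-testing correction. Scores clustered within
  certifying doctors are *not* given clustered standard errors; the
  reported SEs assume independent certificates, and the generator's
  optional per-doctor random intercept exists precisely to study the
  consequences of that assumption.

  Cross-checks: with a dichotomized outcome the fit reproduces the 2×2
  cross-product odds ratio and a logistic regression to 1e-6; on full
  cohorts it matches statsmodels' `OrderedModel` likelihood. These oracles
  live in the test suite only.

## 6. The synthetic-data generator

The generator emulates a three-arm certification study: 300 pre-intervention,
900 online, 900 online + training certificates (defaults).

* **Planted errors.** Each error type is drawn independently per
  certificate with an arm-specific base probability (defaults: the per-arm
  prevalences reported for this design, e.g. missing interval
  0.960/0.471/0.300, blank lines 0.113/0.002/0.003). The online system's
  hard constraints are represented *only* by these lower probabilities, not
  by a mechanistic form model. A per-year age effect of log(1.009) shifts
  every error's log-odds; a scalar per-arm offset (solved by bisection)
  keeps each arm's marginal prevalence exactly at its configured value,
  because published prevalences are arm margins, with the age effect
  redistributing risk within the arm. Additional-error subtypes are a
  per-arm categorical mixture whose weights are conditioned on the
  ill-defined flag (a bare external-cause UCOD cannot coexist with an
  ill-defined UCOD) so that marginal subtype rates stay on target.
* **Coupling.** The broad cause group is `ill_defined` exactly when the
  ill-defined-UCOD flag is planted, so "100% any-error among ill-defined
  causes" holds analytically; the published cause-group counts distribute
  the remaining certificates. Independence of error types given covariates
  is an assumption — no error-type correlation structure is published — and
  an optional shared per-doctor random intercept (default off,
  ~1.67 certificates/doctor) is provided for clustering experiments.
* **Rendering.** Certificate text is constructed so each planted flag
  manifests and each unplanted flag is guaranteed absent: valid cause
  chains come from the shipped causal graph, sequence errors from
  adjacent pairs outside its closure (or a non-initiating UCOD when the
  ill-defined flag is also planted), blank lines from a gap strictly inside
  the chain, and so on. The render→assess round trip is exact and tested
  exhaustively over all 288 plantable flag/subtype combinations × arms.
  Any profile the renderer cannot realise raises rather than silently
  dropping a flag; the only impossible combination is bare-external +
  ill-defined UCOD, which the sampler never plants.
* **What it does not emulate.** Realistic clinical narrative beyond what
  the detectors read; joint distributions of errors with certifier
  attributes beyond the published margins; certifier learning over time;
  transcription noise. Passing tests therefore demonstrate correctness of
  the *pipeline* (detection, scoring, tabulation, estimation) under known
  truth — not that the rules would reproduce a particular human reviewer's
  judgments on real certificates.

## 7. Problem sizes in tests and the acceptance script

Exact identities (round trip, closed forms, reparameterization) run at
their natural small sizes. Statistical checks use: generator calibration at
20,000 certificates/arm (binomial SE ≤ 0.36 points, against a 1-point
tolerance); Wald-interval coverage of the arm effects over 200 replicates
of the 300/900/900 design with protective odds ratios 0.283 and 0.151 and
cutpoints chosen to spread mass over score levels 0–9; coefficient bias
over 100 replicates at n = 10,000 (tolerance 0.05 on the log-odds scale);
and null p-value uniformity over 500 replicates at n = 1,000
(Kolmogorov–Smirnov). Fitted arm effects on generator output are *not*
expected to match any published regression: the generator plants
independent per-type flags, which induces its own score distribution, so
arm effects are validated by parameter recovery from the model itself.

## 8. Known limitations

* The shipped lexicons and causal graph are small, explicit stand-ins for a
  reviewer's clinical knowledge; real-world deployment should extend them.
* No ICD coding, no NLP inference on free text, no handling of scanned or
  handwritten certificates.
* SEs unadjusted for certifier-level clustering (see §5).
* The proportional-odds assumption is used, not tested.
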