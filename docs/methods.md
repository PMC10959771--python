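# Methods

This note documents the models, rules and defaults implemented in
`claimlines`, the assumptions behind them, and what validation on synthetic
data does and does not demonstrate.

## Data model

Claims are represented as per-patient bundles of three streams —
demographics, pharmacy dispensings and hospital ICD-10 diagnoses — mirroring
a linked national claims extract (pharmacy/outpatient claims, hospital
discharge diagnoses, death registry, joined on a patient identifier). Dates
have day precision. A dispensing covers the closed interval
`[date, date + days_supply − 1]`; `days_supply` defaults to 30 days, the
usual pack length for the oral agents involved, and is the main lever of the
discontinuation rule. Events are totally ordered by (date, stream, code),
with same-day diagnoses sorting before dispensings, so every derivation is
deterministic. An optional `procedures.csv` carries dated
radiotherapy/surgery markers used only for treatment-history flags; when
absent those flags are false.

## Cohort phenotyping

- **Index date**: first occurrence of an mBC-defining drug dispensing
  (CDK4/6 inhibitor, fulvestrant, everolimus) or of a secondary-malignancy
  diagnosis (prefixes C77/C78/C79, with C77.3 regional-node and C79.2 skin
  codes excluded). First evidence of mBC is identified with the index date;
  the data carry no separate diagnosis-date anchor.
- **Ascertainment**: an mBC-defining drug, OR a secondary-malignancy code
  followed — same day allowed — by tamoxifen or an aromatase inhibitor; and
  never a HER2-targeted dispensing (proxy for the HER2− subtype).
- **Eligibility**: adults (≥ 18 at index) indexed 2014-01-01..2019-06-30,
  first line containing a CDK4/6 inhibitor plus exactly one of
  {AI, fulvestrant}, no non-breast primary malignancy (C00–C97 minus C50 and
  minus the whole secondary C77–C79 block) in the 3-year lookback, no trial
  participation flag, valid records. The cascade is ordered; each patient is
  counted under the first failing step, so attrition counts plus inclusions
  equal the input population.
- **Baseline covariates**: visceral disease = any code for liver (C78.7),
  lung (C78.0), pleura (C78.2), peritoneum (C78.6), adrenal (C79.7), ovary
  (C79.6) or brain (C79.3) metastasis on/before index (bounded by available
  lookback). Charlson comorbidity uses the Quan-2005 ICD-10 lists with the
  original weights, the two malignancy categories removed (the index disease
  is not a comorbidity) and the standard severity hierarchies (complicated
  diabetes over uncomplicated, moderate/severe liver over mild); the score
  is binned 0 / 1–2 / 3–4 / ≥5. Treatment-history flags cover the 365 days
  strictly before index. The endocrine-sensitivity proxy is the absence of
  AI/tamoxifen dispensing in the 365 days strictly before first mBC
  evidence; the menopause proxy is age ≥ 50 at index for women. Age is
  `(index − birth)/365.25` floored to one decimal.

## Line-of-therapy engine

Refills of one drug class merge into a continuous exposure interval when the
next fill starts no later than the previous coverage end plus a **grace
period** (default 60 days, configurable; the common claims convention).
Stockpiling does not accumulate: the interval end is the latest single-fill
coverage end.

A line starts at the first eligible dispensing on/after the index date and
includes every class observed within the **combination window** (closed,
default 30 days) of that start. Scanning forward, the line ends at the
earliest of:

- **augmentation** — a non-exchangeable class starts while the line's supply
  is active; the next line starts that day and contains the still-active
  classes plus the new one;
- **switch** — supply exhausted and a different class starts within grace;
- **discontinuation** — supply exhausted and nothing starts within grace.
  Discontinuation is only asserted when the grace window is fully observable
  before the cutoff, or the patient died (no further refill is possible);
  otherwise the line is censored (`end_of_data`);
- **death**; a next line starting on the death day takes precedence (tie
  rule shared with the TTNT event definition);
- **end of data** — the administrative cutoff (2019-12-31).

AI and CDK4/6-inhibitor substitutions — within or between the two classes —
are *exchangeable*: such an interval starting while the line (containing
either class) is active, or within grace of its supply end, extends the
line's exposure without changing its combination-window class set. After a
full grace gap the same classes open a new line, which is what makes CDK4/6
rechallenge after intervening chemotherapy detectable. Everolimus and
tamoxifen are eligible, non-exchangeable line components. The line end for
discontinuation is the supply-exhaustion date (coverage-based, not the last
dispensing date).

## Endpoints and Kaplan–Meier estimation

- **TTTD** runs from line start to the line's terminating trigger; any of
  augmentation / switch / discontinuation / death is an event and
  `end_of_data` censors. **TTNT** runs from line start to the next line's
  start (event); without a next line the patient is censored at death or
  follow-up end, whichever is first. Death is deliberately asymmetric —
  event for TTTD, censoring for TTNT — so TTNT medians exceed TTTD medians
  mechanically as well as clinically.
- Times are months = days / 30.4375 (mean Gregorian month; fixed constant
  for reproducibility).
- The product-limit estimator is implemented natively: at each distinct
  event time, S multiplies by (1 − dᵢ/nᵢ); censored observations tied with
  an event time remain at risk. Variance is Greenwood's; pointwise 95%
  bands are computed on the log(−log S) scale (well-behaved near 0 and 1).
  The median is the smallest event time with S(t) ≤ 0.5 (ties at exactly
  0.5 take that time — the lower-middle order statistic under no
  censoring); its CI inverts the bands: the limits are the smallest event
  times at which the lower/upper band reaches 0.5, undefined when a band
  never does. An established survival library is used as an independent
  cross-check in the tests, never as the implementation.

## Reporting conventions

Percentages recompute exactly from their printed counts under **half-up**
rounding. Cells with 1–9 patients are masked `< 10` (small-cell disclosure
control typical of national claims outputs). The menopausal row uses the
female patients of each column as denominator — this convention is treated
as normative here. Treatment-history rows are not mutually exclusive.
Sequence summaries categorise each regimen as chemotherapy-based (any
chemo), CDK4/6-based (any CDK4/6 inhibitor, no chemo), ET-based, or other;
patients without the line at a given depth count as "no further treatment
observed", so categories partition each arm at every depth. The 5-category
scheme is a documented package choice.

## Synthetic-data generator

The generator emulates the observable structure of the source claims; its
defaults are fixed study conditions, not tuning knobs. Per patient: arm
(AI : fulvestrant partner = 0.67 : 0.33), index date uniform over
2014-01-01..2019-06-30, age ~ Normal(66.5, 12²) truncated to [25, 100],
female with probability 0.993. First-line duration is lognormal with median
17.3 months (σ = 0.9) on the AI arm and 9.7 months (σ = 0.9) on the
fulvestrant arm; later-line medians 4.6 and 3.2 months. Death is
exponential from index (0.009 / 0.019 per month by arm). Subsequent lines
occur with probability 0.60 / 0.75 per transition, after a uniform 75–150
day gap, with next-regimen categories loosely matched to published sequence
shares. Lookback exposures (AI 29.6% / 72.3% by arm, tamoxifen ~11%,
chemotherapy 6.7% / 13.8%), visceral coding (17.9% / 9.6%), bone-metastasis
coding, comorbidity codes at typical elderly-cohort prevalences, and small
trial/prior-primary contamination probabilities complete the streams.
Refills arrive every 30 days with ±7-day adherence jitter (kept below the
grace period so jitter alone never splits exposure); the final fill of a
planned line is truncated to the planned stop date, so the engine-derived
duration equals the drawn duration minus one day and pack quantisation adds
no systematic bias. Two notable departures from the source data: index
dates are uniform rather than concentrated in 2018–2019 (the calendar mix
is not a planted marginal, and uniform accrual spreads the administrative
censoring that the recovery tests rely on), which also makes cumulative
death proportions higher than a short-follow-up cohort would show; and
fulvestrant injections are modelled with the same 30-day supply abstraction
as oral agents.

`planted_truth` derives, without simulation: closed-form duration medians
(exponential ln2/rate; Weibull scale·(ln2)^(1/shape); lognormal e^μ); the
TTTD estimand median — the median of min(duration, death time), solved by
root-finding on S_D(t)·e^(−λt) = 0.5; and the latent TTNT median — where
p_next·P(duration + gap ≤ t) crosses 0.5 (deterministic quadrature over the
uniform gap), undefined when p_next ≤ 0.5. Under independent administrative
censoring these are exactly what the Kaplan–Meier fits estimate, so
parameter recovery is a meaningful end-to-end check.

## Validation scope and problem sizes

The test suite validates: exact arithmetic of the reporting conventions
against published-table count/percentage pairs; the KM estimator against an
exhaustive brute-force product-limit oracle (all 3002 datasets of size ≤ 8
over a 3-point time grid with censoring) and against an independent survival
library on random data; the LOT engine against hand-traced fixtures for
every rule (exchangeable swap, switch, augmentation, gap split, death,
cutoff); per-patient TTNT ≥ TTTD on 10,000 synthetic patients; recovery of
planted first-line TTTD medians within 5% relative error and arm shares
within two percentage points at n = 5000; and byte-identical outputs across
repeated runs. Problem sizes (n = 400 for integration fixtures, 5,000 for
recovery, 10,000 for the ordering property) keep the full suite under a
minute while leaving Monte-Carlo error well inside the stated tolerances.

Passing on synthetic data shows the *derivation chain* is correct under the
generator's assumptions. It does not validate the phenotyping algorithm
against clinical truth: the generator does not model coding noise,
under-recording of secondary-malignancy codes, hospital-vs-pharmacy
duplication, interrupted enrolment, or dose/intensity — so sensitivity and
specificity of the cohort definition on real claims are out of scope, as is
any covariate-adjusted or causal comparison between arms.

## Known limitations

- The grace period (60 days), combination window (30 days) and supply
  default (30 days) are conventions, configurable but not empirically
  calibrated here; line counts are monotone in the grace period
  (property-tested), so sensitivity analyses are cheap.
- Discontinuation near the cutoff is censored rather than called, slightly
  inflating TTTD medians (≈1–3% at the default conditions; visible in the
  recovery tests' positive bias).
- Visceral-disease ascertainment is bounded by the available lookback; the
  engine does not distinguish individual chemotherapy agents; overall
  survival is out of scope (deaths are reported descriptively only).
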