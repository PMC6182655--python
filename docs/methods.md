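# Methods

This note documents the models, conventions and design choices behind the
package: what the case-ascertainment rules are, how person-time is
accrued, what the estimators assume, what the synthetic registry does and
does not emulate, and which problem sizes the tests and the acceptance
script run at.

## Data model and conventions

Four tab-delimited tables form a registry bundle: persons (sex, birth /
death / immigration / emigration dates, education in three levels plus
missing, place of birth in seven categories), pharmacy dispensings (ATC
codes under A10; A10A insulins, A10B non-insulin glucose-lowering drugs),
specialist-care diagnoses (ICD-10 E10–E14) and primary-care diagnoses
(ICPC-2 T89/T90). Source-specific availability windows are enforced:
dispensings from 2004, primary care from 2006, specialist care from 2008,
all through 31 December 2014.

Dates are whole calendar days and all intervals are half-open
`[start, end)`. Diagnosis-code matching is prefix-based on the
three-character stem, uppercase. "6 months" is fixed at 183 days and
"first month" at 30 days; both are configurable in `StudyConfig`. Same-day
duplicate registrations collapse to one occasion.

## Case ascertainment

Type-2-specific registrations are E11 (specialist) or T90 (primary care).
The onset date is the first such registration. A person is an incident
case when the onset lies in [1 January 2009, 30 June 2014] and either

1. at least one A10B dispensing falls within `[onset, onset + 183 d]`
   (rule `one_dx_plus_A10B`, pharmacologically treated), or
2. type 2 registrations exist on ≥ 2 distinct dates, pooling both
   diagnosis sources (rule `two_occasions`). Such a case is
   pharmacologically treated if *any* A10 dispensing (insulin included)
   falls in the window, otherwise non-pharmacological. The confirmatory
   second registration may occur any time up to the end of data
   (31 December 2014) — which is why incident onsets stop six months
   before the data end.

Washout: any diabetes evidence strictly before 1 January 2009 (any
E10–E14/T89/T90 code or any A10 dispensing) excludes the person from
incidence; those who already met the full case criteria before study
start are labelled `prevalent_at_baseline`, the rest `excluded_washout`.

Residual persons with some evidence split into `possible_unclassified`
(diabetes-coded but never qualifying — including lone registrations and
type-1/non-specific coding) and `medication_without_diagnosis` (A10
dispensings, no diagnosis ever). A person whose first type 2 registration
falls after 30 June 2014 is a `non_case` for the incidence analysis: the
case definition can no longer be evaluated inside the study window.

Insulin-only starters cannot qualify through rule 1 (it requires A10B);
they qualify through two occasions, after which insulin inside the window
makes them pharmacologically treated. The initial regimen is classified
from the distinct substances dispensed within 30 days of the first
qualifying dispensing: metformin / sulfonylurea / other-oral monotherapy,
insulin only (all substances A10A), or a multi-drug start (≥ 2 distinct
substances).

## Open-cohort person-time

Entry is `max(study start, 30th birthday, immigration + 365 d)`; exit is
the earliest of first diabetes evidence, emigration, death, the 90th
birthday and the end of the incidence period, with ties resolved in that
order. Exit dates are exclusive: evidence and death exits are placed the
day *after* the event (the event day contributes person-time, the
standard survival convention), emigration and the 90th birthday exclude
their day, and the period end is followed inclusively (exit
1 July 2014). Anniversaries of 29 February resolve to 1 March.

A classified incident case whose onset postdates an earlier censoring
event (for example a non-specific E13 code before the first E11) exits at
that earlier evidence; `incident_cases_in_windows` drops such cases from
incidence analyses with a logged count, and `aggregate_strata` raises on
unfiltered inconsistent input.

Lexis expansion cuts each window at every 1 January and at the 50th/70th
(configurable) birthdays; the attained-age band of a segment is the band
at its start, and segments never straddle a boundary. Person-time
conservation is exact in days; person-years use 365.25 days. Birth-cohort
analyses use the fixed 10-year birth-decade label instead of attained
age.

## Estimators

*Rates.* `rate = cases / person-years × 100,000`. The 95% interval is the
log-normal interval `rate · exp(±1.96/√cases)` — the large-sample
interval for a log rate, which reproduces published national-cohort CIs
to printed precision down to a 28-case stratum; an exact Poisson
(chi-square) interval is available as `method="exact"`. No interval is
reported for zero cases. The exact coverage of the log-normal interval at
an expectation of 50 cases is 94.4%.

*Prevalence.* For each year, the numerator counts persons whose case
criteria (drug route: first E11/T90 and first A10B both observed, met at
the later of the two; or second distinct registration) were met in that
year or earlier, among the denominator of persons alive, resident and
aged 30–89 at some time in the year.

*Trend.* Yearly counts are modelled as
`log E[cases] = α + β·year + log(PY)` (Poisson GLM);
`APC = 100·(e^β − 1)` with a Wald CI. The interrupted time series uses
monthly counts with mid-period time coding in exact fractional years and
adds a slope-change term `(t − t_break)⁺`; a level-change term is off by
default and configurable. Both models interpolate noise-free log-linear
(or piecewise log-linear) expected counts exactly, which the tests
exploit as a closed-form check. The slope-change test is a Wald test on
the change coefficient; its power depends on the total number of cases,
so reduced-scale synthetic cohorts report honest but large p values while
study-scale exposure (~15.5M person-years) detects a −12% → −7.9% change
with p ≈ 10⁻³.

*Hazard ratios.* One row per person (duration = exit − entry, event =
incident case, fixed covariates), fitted with the Cox partial likelihood
(lifelines). The default time scale is follow-up time with birth cohort
as a covariate; an attained-age time scale with delayed entry is
available (`time_scale="age"`), since the appropriate choice is a
modelling judgement. Reference levels are male / 1980s cohort / high
education / born in Norway; the missing-education category is excluded
from education contrasts. Covariate levels with no events are not
identified by the partial likelihood and are reported as NaN; if the fit
still fails to converge (near-separation in small cohorts) a weak ridge
penalty (0.01) is applied and logged. Note that on the follow-up time
scale, strongly age-linked covariates (extreme birth cohorts) interact
with age-90 censoring, so their HRs need not equal the hazard multipliers
a simulator plants; the two-group recovery tests therefore use a clean
exponential design.

## Synthetic registry

Latent onsets follow a piecewise-exponential hazard on calendar time —
log-linear with the configured annual percent change, optionally with a
slope break at the ITS break date — multiplied by fixed per-person
covariate effects (sex, birth decade, education, place of birth), sampled
on a monthly grid from 2004 through 2014. The intercept is normalised by
the demography-implied mean covariate multiplier so
`baseline_rate_per_100k` is the *population-marginal* rate in the
reference year. Defaults encode the published study conditions: marginal
incidence 609 per 100,000 in 2009, APC −10.1%, 48% of onsets treated
within the window, regimen shares led by metformin monotherapy (82.6%),
4.5% prevalent at study start (76.4% of them treated), published adjusted
hazard ratios as the planted covariate effects, and Table-1-like
demography. Mortality is Gompertz (4·10⁻⁴/yr at age 30, doubling every
8 years), emigration a small constant hazard; both are independent of
disease, as the analysis assumes.

Care model: each case registers `Exp(14 d)` after onset, receives a
confirmatory follow-up visit `1 d + Exp(60 d)` later (clamped to the end
of observation), and then repeat visits at a constant rate — 6/yr when
treated, 2/yr when untreated. Each visit routes to primary care with
probability 0.93 (else specialist) and is recorded with per-register
recording probabilities (default 1.0: reporting to these registers is
compulsory and near-complete; the probabilities remain knobs for
robustness experiments). Treated cases dispense their regimen within
`U(0, 180) d` of registration and refill every 90 days; a multi-drug
start adds its second substance within the first month. Three percent of
onsets carry only non-specific coding (E10/E13/E14/T89) and 0.2% of
disease-free persons dispense A10 drugs without any diagnosis — the two
sensitivity-analysis categories. Prevalent cases draw onsets uniformly
over 1996–2008 and surface no earlier than data availability, so the
washout has real work to do.

Two deliberate realism choices matter for trend recovery and were made on
fidelity grounds: prompt confirmatory visits (otherwise late-onset
untreated cases are systematically unascertainable before the data end)
and recording probabilities of 1 (otherwise pre-study cases whose first
registration goes unrecorded escape the washout and leak into early study
years as false incident cases). With realistic visit rates both effects
are negligible, mirroring the near-absence of such artefacts in compulsory
national registers.

What the generator does *not* emulate: disease-dependent mortality,
return migration (at most one immigration/emigration pair), care-seeking
heterogeneity beyond the treated/untreated split, drug switching or
discontinuation, secular changes in coding practice, and absolute
national population counts. Passing recovery tests therefore show that
the pipeline is correct under the stated model family, not that real
registry data are free of the corresponding biases.

A note on marginal versus per-person trends: birth-decade effects are
fixed per person, so cohort turnover (high-hazard 1920s cohorts aging out
at 90, low-hazard 1980s cohorts entering at 30) adds a real ≈ −2%/year
composition drift to the marginal incidence trend on top of the
configured per-person APC. Trend-recovery experiments therefore use a
configuration whose only covariate effect is sex (its population share is
stable over calendar time), making "configured APC" and "marginal APC"
coincide; under the full default effects the pipeline correctly estimates
the steeper marginal trend.

`perfect_recording_config` gives the limit (no vital events, immediate
registration, prompt confirmation, everything recorded, no non-specific
coding) in which phenotyping must recover the truth table's incident set
exactly — an oracle-equivalence test, not a realistic scenario.

## Problem sizes and reproducibility

Everything is seeded through `numpy.random.default_rng`; identical seed
and configuration give byte-identical output files (canonical row order,
ISO dates). The pipeline fans a master seed out to stages through a fixed
SHA-256/SeedSequence derivation.

Test and acceptance runs use reduced scales chosen to keep Monte-Carlo
error well inside the asserted tolerances: APC recovery at 200,000
persons × 20 seeds (mean within ±1.5 points of the configured −10%),
Cox recovery on a 100,000-person two-group exponential design (±0.03
around HR 0.66), register-overlap calibration at 300,000 persons (within
±5 points of 26/36/39%), ITS slope-change power from 50 Poisson
simulations at study-scale exposure, and interval calibration from the
exact Poisson pmf plus 1,000 replicates. The acceptance script runs the
full chain at 150,000–250,000 persons per experiment and finishes in a
few minutes on one CPU.

## Known limitations

- The register-overlap calibration is a rough match (≈ 29/36/35 versus
  26/36/39): the shared routing probability links the treated and
  untreated overlap distributions, and a closer fit would need per-case
  source-affinity heterogeneity.
- The synthetic prevalence trajectory rises more slowly than the
  published 4.9% → 6.1% because prevalent-pool mortality is calibrated
  only through the age-varying Gompertz hazard, not to observed diabetes
  mortality.
- Cox HRs for extreme birth cohorts on the follow-up time scale are not
  comparable to the planted hazard multipliers (see above); use the age
  time scale for age-dominated questions.
- The classifier requires type-2-specific codes (E11/T90) on both
  occasions of the two-occasion rule; mixed streams such as one E11 plus
  repeated T89 remain unclassified.
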