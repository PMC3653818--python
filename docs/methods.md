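# Methods

This note records the statistical conventions, defaults and numerical
choices behind each module, what the synthetic registry does and does
not emulate, and the known limitations.

## Data model and file conventions

All analyses run off two substrates: **aggregated counts** (cases and
person-years per sex × age-group × calendar-year × disease cell) and
**individual records** (one patient per row with sex, age, diagnosis
month/year, vital status and follow-up in decimal years).  Auxiliary
inputs are the age-group scheme, standard-population weights, the
population distribution (person-years per sex/age-group/year) and
general-population life tables (annual survival probability per
sex × single-year age × calendar year).

Conventions, chosen where the file formats leave room:

* Delimiters: comma or semicolon, auto-detected from the header line;
  comma wins a tie.  Headers are mandatory and matched
  case-insensitively.
* Age-group indices in files are 1-based.  The default scheme is
  eighteen 5-year groups 0–4 … 85+; ages above the last closed bound map
  to the open-ended final group.
* Vital status is 1 = dead, 0 = alive/censored (overridable through the
  column-schema map).
* Individual records carry the follow-up time and the diagnosis/end date
  pair redundantly.  The decimal follow-up is authoritative; a
  discrepancy beyond one month is logged as a warning, not an error,
  because month-resolution dates cannot encode exact times.
* Readers never drop rows silently: by default the first invalid row
  raises with its row number and offending value; in collect mode the
  accepted rows plus the reported rejects always account for every input
  row.

## Descriptive rates

Rates are reported per 100,000 person-years.  The ASR is the
weight-normalised mean Σwᵢrᵢ/Σwᵢ, so rescaling all standard weights is a
no-op and the ASR always lies between the extreme age-specific rates.
The embedded default standard is the Segi world standard population
(weights 12000, 10000, 9000, 9000, 8000, 8000, 6000, 6000, 6000, 6000,
5000, 4000, 4000, 3000, 2000, 1000, 500, 500 for the 18 five-year
groups); a user-supplied weights file overrides it.

An age group with positive weight but no person-years is a coverage
error, not a zero rate — treating it as zero would silently bias the ASR
downward.  The truncated rate re-normalises the weights within the
35–64 window (results differ from raw truncated weights only by the
overall scale, which the normalisation removes).  Truncation bounds must
coincide with group boundaries; nothing is ever re-binned.

The cumulative rate uses age-specific rates on the proportion scale
(cases per person-year) times the group width in years, summed over the
closed groups covering 0–74, so the cumulative risk identity
1 − exp(−CumR) holds on the probability scale directly.  A scheme whose
closed groups do not tile [0, 75) exactly is rejected.

## Trend estimation (EAPC)

The trend model is ordinary least squares of log rate on calendar year;
EAPC = (e^β − 1)·100.  The 95% CI is computed on the β scale with the
t quantile at n − 2 degrees of freedom (a normal-quantile option exists
for cross-checking against software that uses z), then transformed — so
the interval is asymmetric around the EAPC but always contains it, and
can never extend below −100%.

A zero rate makes the model undefined.  The default is a hard error
naming the offending year; `drop_zero_years` exists as an explicit
escape hatch.  Silent log(0) handling is the classic way this analysis
corrupts quietly, hence no silent default.  At least three positive
years are required (two leave no residual degrees of freedom).  Years
are not weighted by case counts; the model is fitted to the
already-standardized ASR series, not to age-stratified counts.

## Case-count projection

Four candidates: {Poisson, NB2} × {age-specific slopes, common drift},
all log-linear in time with log person-years as exposure offset and T₀
(default: the last observed year) as reference — centering affects only
the meaning of αᵢ, never the projections.  Fitting is full maximum
likelihood through the statsmodels discrete count models; the NB
dispersion is estimated jointly, seeded from the Poisson solution.  On
equidispersed data the dispersion runs to its zero boundary and the line
search reports precision loss there; a solution with a vanishing score
is accepted as converged, which keeps the NB candidates comparable
(their AIC then exceeds the Poisson's by the parameter penalty, as the
nesting demands).

AIC is computed as −2ℓ + 2k with k counting every estimated parameter
including the NB dispersion, so families are penalised consistently.
Model choice is minimum AIC; exact ties break toward fewer parameters
(drift before age-specific, Poisson before NB).  The Pearson X²
statistic (family variance in the denominator, df = cells − parameters)
is reported as a diagnostic and triggers a warning when the winner fails
at the 0.05 level, but it never vetoes the AIC choice — reporting both
and letting AIC decide is the arbitration rule here.

Age groups with zero counts in every year cannot be represented on the
log scale; they are excluded from the fit, recorded on the result, and
projected as exactly zero with a logged notice.

## Standardized incidence/mortality ratio

E = Σᵢ r_ref,i·Y_target,i is treated as a known constant (the classical
convention: the reference is assumed large enough that its sampling
error is negligible).  The default CI is the exact Poisson interval by
chi-square inversion — lower bound χ²(α/2, 2D)/2E (0 when D = 0), upper
bound χ²(1 − α/2, 2D + 2)/2E — with Byar's cube-root approximation
behind a flag for comparison with software that prints it.  Mismatched
age-group schemes between target and reference are an error; expectation
is never computed over a silently re-binned intersection.

## Net-change decomposition

With reference cells (C¹ᵢ, Y¹ᵢ), target cells (C²ᵢ, Y²ᵢ),
N = ΣY, rᵢ = C¹ᵢ/Y¹ᵢ:

    net       = ΣC²ᵢ − ΣC¹ᵢ
    size      = ΣC¹ᵢ·(N²/N¹ − 1)
    structure = Σ rᵢY²ᵢ − ΣC¹ᵢ·N²/N¹
    risk      = ΣC²ᵢ − Σ rᵢY²ᵢ

The ordering convention — size applied first, then structure, risk as
the residual — is fixed and matters: component values depend on it.  It
matches the verbal definition of the method: the expected target count
applies the reference age-specific rates to the target pyramid, and
whatever the population change cannot explain is risk.  Consequences
worth knowing: structure vanishes whenever the target pyramid is
proportional to the reference *or* the reference rates are constant over
age; risk vanishes exactly when every target cell keeps its reference
rate.  Additivity is an algebraic identity, not an approximation.

The crude-rate scale divides the partition by the respective population
sizes; there the size term is identically zero (both crude rates already
normalise by their own population).  The percent scale divides by ΣC¹
and is undefined when the reference has no cases.  Rates are treated as
constant within each period: period years are pooled before
decomposition.  No inferential output is produced — the partition is a
deterministic identity and significance assessment for its components is
out of scope.

## Relative survival

Observed survival is the Kaplan–Meier product-limit estimator on exact
(continuous) follow-up times; the annual rows of the report are
evaluation points, not actuarial estimation intervals.  The variance of
log S_o accumulates the Greenwood terms d/(n(n−d)).

Expected survival uses the Hakulinen cohort estimator.  Each patient's
*potential* follow-up runs from diagnosis to the study end date
regardless of actual death or loss — this is the essential difference
from the Ederer estimators and removes the bias of mortality-dependent
follow-up.  For annual interval k the cohort conditional expected
survival is

    p̄ₖ = Σᵢ wᵢₖ·Sᵢ(k−1)·pᵢₖ / Σᵢ wᵢₖ·Sᵢ(k−1)

with pᵢₖ the life-table annual probability at the patient's attained age
(age at diagnosis + k − 1) and calendar year (diagnosis year + k − 1),
Sᵢ the individual cumulative life-table survival, and wᵢₖ the fraction
of interval k inside the patient's potential follow-up.  The fractional
weight replaces the classical actuarial half-interval adjustment for
potential withdrawals; the estimator reduces exactly to the product of
annual probabilities for a homogeneous fully-followed cohort and to the
person-weighted mixture of stratum products for several such strata.
Sub-annual evaluation raises the current year's p̄ to the fractional
power (constant hazard within years — the life tables carry no
sub-annual information).  Attained ages beyond the life table's maximum
reuse its last age row with a logged warning; a missing (sex, age, year)
cell is a hard error naming the cell.

RS = S_o/S_E with CI exp(log S_o ± z₀.₉₇₅·se)/S_E, S_E held constant.
RS may exceed 1 and is deliberately not clipped (registry cohorts can
out-survive the general population); only the lower CI bound is clipped
at 0.

## Synthetic registry

The generator draws cell counts Poisson with mean
rateᵢ·changeᵉ·person-years, assigns each case an age uniform within its
group, a diagnosis month uniform over the year, and a death time from an
additive-hazard model: constant background hazard −log(p_bg) — matching
the emitted life table exactly — plus a constant excess hazard.
Censoring happens at the study end.  Because background mortality in the
cohort and in the life table coincide by construction, true relative
survival has the closed form exp(−excess·t), giving the survival module
an analytic oracle; the manifest also records the true EAPC
(change − 1)·100, the true between-half incidence ratio and the true
decomposition components derived from the expected counts.

Defaults describe a mid-size region observed for ten years (1995–2004,
follow-up to end of 2007): an adult-onset age profile rising from ~1 per
million below age 30 to ~380 per 100,000 at ages 75–79, a pyramid of
28,000–40,000 person-years per 5-year group thinning in old age, flat
rates over time, background annual survival 0.97 and an excess hazard of
0.25/year (5-year relative survival ≈ 0.29, a poor-prognosis tumour).
One global seed fans out to independent sub-streams for counts,
demographics and survival, so a fixed seed reproduces every file
byte-identically.

What the generator does *not* emulate: age-dependent background
mortality (the life table is flat over age and calendar time),
non-proportional rate trends across age groups, within-period rate
drift, migration, loss to follow-up before study end, duplicate or
miscoded records.  Passing tests therefore validate the estimators'
mathematics and the pipeline's plumbing, not robustness to real-registry
data quality.

## Problem sizes and numerical tolerances

Exact identities (decomposition additivity, ASR vs a brute-force loop,
the cumulative-risk identity, Hakulinen's closed forms) are checked to
1e-10–1e-12 over 200–1,000 random tables.  Coverage checks run 2,000
replicates for the EAPC and SIMR intervals, 500 for the projection
slope's Wald interval (the binomial Monte-Carlo error of a coverage
estimate is ~1% at that size) and 500 cohorts of 150 patients for the
null-excess relative-survival recovery; model selection is checked on 50
four-candidate replicates.  These sizes put every Monte-Carlo standard
error well inside the asserted bands while the whole suite runs in well
under a minute.

## Limitations

No confidence intervals for crude/standardized rates; no joinpoint or
age-period-cohort trend models; no prediction intervals for projected
counts; no significance assessment for decomposition components; no
between-curve comparison tests, period analysis or excess-hazard
regression for relative survival.  The Ederer I/II expected-survival
estimators are not implemented (the Hakulinen estimator is the one
provided).
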