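# registat

Statistical analysis of disease-registry data: descriptive rates, rate
trends, case-count projection, standardized incidence/mortality ratios,
decomposition of rate changes into demographic and risk components, and
cohort relative survival.

Population-based registries (cancer registries above all) routinely need
the same small set of indicators to describe the burden of a disease, to
compare it across periods or areas, and to plan services.  `registat`
implements that repertoire as one tested Python library with a matching
command-line interface, working from plain delimited files: individual
patient records, aggregated case counts with person-years, standard
population weights, age-group definitions, population distributions and
general-population life tables.

## Methods at a glance

* **Descriptive rates** — crude rate CR = X/N; age-specific rates;
  directly standardized rate ASR = Σᵢwᵢrᵢ/Σᵢwᵢ against a standard
  population's age weights (the embedded default is the Segi world
  standard, 18 five-year groups); the truncated ASR over ages 35–64; the
  cumulative rate CumR = Σᵢ rᵢ·widthᵢ over ages 0–74 and the cumulative
  risk 1 − exp(−CumR).
* **Trend (EAPC)** — Gaussian log-linear model log ASR_T = α + β·T fitted
  by OLS; the estimated annual percent change is (e^β − 1)·100 with the
  CI transformed from the β scale (t distribution, n − 2 df).  A trend is
  *stable* when the CI contains 0, otherwise *increasing*/*decreasing*.
* **Projection** — log-linear count models
  log(C_iT/Y_iT) = αᵢ + βᵢ·(T − T₀) with age-specific slopes, or the
  parsimonious *age-drift* variant with one common slope β, each under a
  Poisson or negative-binomial (NB2) distribution with person-years as
  exposure.  The four candidates are compared by AIC with a Pearson χ²
  goodness-of-fit diagnostic; projection replaces T by the future year
  and Y_iT by the future person-years.
* **SIMR** — standardized incidence/mortality ratio D/E, where
  E = Σᵢ r_ref,i·Y_target,i expects the target's events under the
  reference population's age-specific rates; exact Poisson CI (Byar's
  approximation optional).
* **Net-change decomposition** — the change in case counts between two
  periods/areas split additively into population **size**, population
  age-**structure** and residual **risk** components (Bashir–Estève
  partition), on the absolute-case, crude-rate and percent scales.
* **Relative survival** — RS(T) = S_o(T)/S_E(T): Kaplan–Meier observed
  survival over expected survival from sex/age/calendar-year life
  tables, combined with the Hakulinen estimator in which each patient
  contributes expected survival for their full *potential* follow-up
  (diagnosis to study end).  CIs use the Greenwood standard error of
  log S_o with S_E treated as constant.

See `docs/methods.md` for assumptions, parameter conventions and
numerical details.

## Worked example

```python
import registat as rg

# a synthetic registry with known ground truth: rates rising 3%/year,
# disease excess death hazard 0.35/year
spec = rg.RegistrySpec(annual_rate_change=1.03, excess_hazard=0.35, seed=42)
reg = rg.simulate_registry(spec)
men = reg.aggregated[reg.aggregated["sex"] == 1]

summ = rg.rate_summary(men, reg.standard, spec.scheme)
print(f"CR={summ.crude_rate:.2f}  ASR={summ.asr:.2f}  "
      f"risk(0-74)={100 * summ.cumulative_risk_0_74:.2f}%")

series = [(y, rg.direct_standardized_rate(sl, reg.standard))
          for y, sl in men.groupby("year")]
print(rg.fit_eapc(series).summary())

ref, tgt = men[men["year"] < 2000], men[men["year"] >= 2000]
print(rg.compare_populations(ref, tgt).summary())

curve = rg.RelativeSurvivalModel(
    reg.individuals[reg.individuals["sex"] == 1],
    reg.life_table, spec.study_end, max_time=5).fit()
print(rg.report_table(curve).to_string(index=False))
```

prints

```
CR=73.91  ASR=50.80  risk(0-74)=6.20%
Estimated annual percent change (log-linear OLS)
  n years:       10
  beta (log/yr): 0.033220 (se 0.005789)
  EAPC:          3.38%  95% CI (2.01%, 4.77%)
  trend:         increasing
SIMR = 1.181 (D = 1885, E = 1596.00)
  95% CI (exact): (1.128, 1.236) — significant
 Risk  T    RS   LCI   UCI    OS
 3481  0 0.998 0.996 0.999 0.998
 2353  1 0.692 0.677 0.709 0.672
 1594  2 0.486 0.469 0.504 0.457
 1117  3 0.350 0.334 0.368 0.320
  700  4 0.250 0.235 0.266 0.221
  430  5 0.178 0.164 0.193 0.153
```

The fitted EAPC CI (2.01, 4.77) covers the generating 3%/year; the SIMR
of the second five-year block against the first reflects the rising
rates; and the 5-year relative survival 0.178 sits at the analytic truth
exp(−5·0.35) ≈ 0.174.  The survival report lists, per year since
diagnosis, the number still at risk, relative survival with its 95% CI,
and observed survival.

## Command line

```sh
registat simulate --seed 9 --out reg/          # synthetic registry + manifest
registat descriptive --aggregated reg/aggregated.csv --out desc.csv
registat eapc        --aggregated reg/aggregated.csv --out eapc.csv
registat expected    --aggregated reg/aggregated.csv \
                     --future-population future.csv --future-year 2014 --out exp.csv
registat simr        --reference ref.csv --target tgt.csv --out simr.csv
registat riskdiff    --input selection.csv --out riskdiff.csv
registat relsurv     --individual reg/individual_records.csv \
                     --life-table reg/life_table.csv --study-end 2007-12 --out rs.csv
```

All inputs are header-first delimited text (comma or semicolon,
auto-detected); reports are delimited text with one row per
sex × disease (or per annual time point for `relsurv`).

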