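# irbvigil

Disproportionality signal detection and time-to-onset analysis for
spontaneous adverse-event reporting databases (FAERS and JADER), built
around the post-marketing safety profile of irbesartan, an angiotensin
II receptor blocker used in hypertension.

Spontaneous reporting systems collect voluntary reports of suspected
adverse drug events (ADEs). Because there is no denominator of exposed
patients, safety signals are found by *disproportionality*: comparing
how often a drug–event pair is reported against how often it would be
reported if drug and event were independent within the database. This
package implements that pipeline end to end:

- **Ingestion** of FAERS quarterly `$`-delimited ASCII tables
  (DEMO/DRUG/REAC/THER/INDI/OUTC) and JADER Shift-JIS CSV tables,
  with explicit date-precision tracking (day / month / year / missing)
  and Japanese age-decade handling (`60歳代` → 65 years).
- **Deduplication** by the FDA rule: one report per CASEID, keeping the
  latest FDA_DT and, among ties, the higher PRIMARYID.
- **Target selection** of reports naming the drug of interest
  (case-insensitive substring over free-text drug names, configurable
  to exact) with the primary-suspect (PS) role code.
- **Four disproportionality statistics** on the report-level 2×2 table
  (a = reports with drug and event, b, c, d its complements,
  N = a+b+c+d), with a four-way composite positivity rule.
- **Subgroup scans** (sex; age < 65 / ≥ 65) with stratum-restricted
  comparators, and a **sensitivity scan** restricted to monotherapy
  reports.
- **Time to onset (TTO)**: event date minus therapy start, exclusions
  audited; descriptive quartiles, interval binning, Weibull
  maximum-likelihood fit with hazard-trend classification, and
  Kaplan–Meier cumulative incidence.
- A **synthetic-data generator** that writes FAERS- and JADER-dialect
  raw files with known ground truth (injected associations at chosen
  relative risks, duplicate case ids, controlled missingness, and
  Weibull-distributed onset intervals), so the whole pipeline is
  testable without any download.

## The statistics

With 2×2 cells a, b, c, d and N = a+b+c+d:

- **ROR** (reporting odds ratio): ROR = ad/bc, 95% CI
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). Positive when a ≥ 3 and the
  lower bound exceeds 1. A zero cell triggers the Haldane–Anscombe
  +0.5 correction (flagged).
- **PRR** (proportional reporting ratio): PRR = [a/(a+b)]/[c/(c+d)]
  with the Yates-corrected χ² = N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)].
  Positive when a ≥ 3, PRR ≥ 2 and χ² ≥ 4.
- **BCPNN information component**: IC = log₂ p₁₁/(p₁·p·₁) under
  Beta/Dirichlet priors, in closed form with its posterior variance;
  IC025 = IC − 2√V(IC) (a fixed-offset mode IC − k is also provided).
  Positive when IC025 > 0.
- **MGPS / EBGM**: the rate ratio λ of observed to expected count
  E = (a+b)(a+c)/N gets a two-component gamma mixture prior whose
  hyperparameters maximize the negative-binomial mixture marginal
  likelihood over the database's full drug×event pair grid. EBGM is
  the posterior geometric mean 2^{E[log₂ λ]}; EBGM05 the posterior 5th
  percentile. Positive when EBGM05 > 2.

A term is a **signal** when all four criteria hold at once. Scan-level
p-values are Bonferroni-adjusted (p·n capped at 1).

For TTO, the Weibull shape β classifies the hazard trend from its 95%
CI: early failure (CI entirely below 1, risk decreasing), random
failure (CI contains 1, constant), wear-out failure (CI above 1,
increasing).

## Worked example

Generate a synthetic study, scan it, and analyze onset times:

```bash
python analysis/01_simulate.py --seed 1      # writes results/sim/
python analysis/02_signal_scan.py            # writes results/scan/
python analysis/03_subgroup_sensitivity.py   # writes results/strata/
python analysis/04_tto.py                    # writes results/tto/
python analysis/05_published_soc_calls.py    # writes results/published/
```

With seed 1 the generator injects the association (IRBESARTAN, pt_005)
at relative risk 10 into a 4,000-report background (plus 320 duplicate
case ids). The drivers print:

```
ingested 4000 reports after removing 320 duplicates
626 reports name the target drug as primary suspect
PT level: 198 terms scanned, 1 composite-positive: ['pt_005']
```

so deduplication removed exactly the constructed duplicates and the
scan flagged exactly the injected association — no false positives
among the other 197 terms. The sensitivity scan keeps 415 monotherapy
reports and the signal persists. The TTO driver reports

```
Weibull fit: alpha=193.0 d, beta=0.570 [0.523, 0.622] -> early_failure
```

recovering the generator's true shape β = 0.55 (scale 200 days):
a decreasing-hazard onset profile, most events early after the start
of therapy. Re-applying the positivity thresholds to the published
irbesartan SOC-level tables reproduces the published calls: 10
ROR-positive SOCs in FAERS, 4 in JADER, 3 positive in both, with
"renal and urinary disorders" the only all-four-positive SOC in FAERS
and "metabolism and nutrition disorders" the only one in JADER.

The same machinery is available as a CLI (`irbvigil simulate|signals|
subgroup|sensitivity|tto`) for running against real FAERS/JADER
quarterly files; a user-supplied PT→SOC dictionary file stands in for
MedDRA, which is proprietary and never bundled.

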