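# Methods

This note records the models implemented in `irbvigil`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic data does and does not establish.

## Report model and ingestion

A corpus is three relational tables — reports, drug entries, reaction
entries — keyed by report id, mirroring how FAERS and JADER ship their
data. Every date is parsed with an explicit precision tag (`day`,
`month`, `year`, `missing`); a calendar-invalid string (e.g. day 30 of
February) becomes `missing` while the row is kept. Only day-precise
dates qualify for time-to-onset analysis; partial dates are excluded
there but still usable elsewhere (receipt-date ordering needs only
comparability, and a missing receipt date simply sorts lowest).

Deduplication implements the FDA recommendation at case level: among
reports sharing a CASEID, keep the one with the latest receipt date;
among ties, the higher report id, compared numerically when both ids
parse as integers (PRIMARYID is numeric in practice, but the file is
text) and lexically otherwise. The operation is idempotent and
invariant to input row order; both properties are tested over
permutations.

Drug-name matching defaults to case-insensitive substring because
FAERS free-text DRUGNAME fields carry dose and formulation suffixes
("IRBESARTAN 150MG TABLET"); exact matching is available. JADER age
decades map to the band midpoint, lower bound + 5 (so `60歳代`,
the 60–69 band, becomes 65); this keeps decade bands from straddling
the 65-year subgroup boundary. Non-numeric JADER age categories
(neonatal, elderly, gestational stages, unknown) become missing.
FAERS carries the event date on DEMO; it is copied onto that report's
reaction entries at assembly time so the TTO logic is source-agnostic.

## Counting convention

All 2×2 tables count report–event pairs: a report contributes at most
once to a given term, however many times the PT repeats, and at SOC
level a report counts once toward a SOC if at least one of its PTs
maps there. The universe N is the corpus-wide pair count and b, c, d
are derived by marginal subtraction, so margins are conserved by
construction (and re-checked by brute force in tests). The comparator
background is the full ingested corpus (all drugs).

## Disproportionality estimators

**ROR and PRR** are the closed-form frequentist estimators with the
Wald log-scale CI and the Yates-corrected Pearson χ² (correction
configurable off; p-values can alternatively come from Fisher's exact
test). When a zero cell occurs, ROR uses the Haldane–Anscombe +0.5 on
all four cells and the row is flagged; tables with an empty margin are
untestable and never satisfy any threshold.

**BCPNN.** The information component uses the closed-form posterior
with marginal priors Beta(1, 1) (α₁ = β₁ = 1, α = β = 2) and joint
prior γ₁₁ = 1, γ scaled by the margins so the prior IC expectation is
zero. The implemented IC is log₂ of the ratio of posterior means
(the standard plug-in form); its Monte-Carlo oracle in the tests
estimates the same estimand by sampling the three Beta posteriors,
because the posterior mean of the log differs from the log of the
posterior means by Jensen gaps of order 1/a, which would dominate the
comparison at small counts. IC025 defaults to IC − 2√V(IC); a
fixed-offset mode (IC − k, default k = 1.67) is provided because
published irbesartan SOC tables show a constant IC − IC025 width of
1.66–1.67, indicating a constant-width interval was used there.

**MGPS / EBGM.** The rate ratio λ (observed count a against
independence expectation E = (a+b)(a+c)/N) carries a two-component
gamma mixture prior. Its five hyperparameters are fitted by maximum
marginal likelihood — each component's marginal for a is negative
binomial NB(α_j, β_j/(β_j+E)) — over the corpus's full drug×event
grid, zero cells included: fitting on observed pairs only conditions
on a ≥ 1 and biases the mixture toward a spurious point mass. The
exposure drug for this grid is the report's primary-suspect drug name.
The optimizer is a generalized EM (monotone by construction, which
also guarantees the fitted likelihood never falls below its starting
point) from DuMouchel's classic start (0.2, 0.1, 2.0, 4.0, 1/3) with
two fallback starts; component parameters are kept within e^±13 to
stay off the degenerate point-mass ridge of the likelihood. A direct
quasi-Newton fit was found to stall at the symmetric saddle of the
mixture surface. The posterior on λ is again a two-component gamma
mixture; EBGM = exp(Σ w_j(ψ(α_j+a) − ln(β_j+E))) via the digamma
identity, and EBGM05 is root-found on the posterior mixture CDF
(verified against 10⁶-draw sampling within 0.5%).

**Thresholds.** ror_pos: a ≥ 3 and ROR025 > 1; prr_pos: a ≥ 3, PRR ≥ 2,
χ² ≥ 4; bcpnn_pos: IC025 > 0; mgps_pos: EBGM05 > 2; a signal requires
all four. These are the community-standard cutoffs and reproduce every
positive/negative call in the published irbesartan SOC tables.
Multiplicity uses Bonferroni over the scan's tested terms,
p_adj = min(1, p·n).

## Subgroup and sensitivity scans

Subgroups are sex (female/male) and age (< 65 / ≥ 65, both databases);
reports missing the stratification variable are excluded, never
misassigned. The comparator background defaults to the same stratum
(a stratified 2×2) rather than the global corpus, since the point of
the subgroup scan is to remove stratum-specific reporting propensity;
the global background remains available by option. The sensitivity
scan keeps only reports whose every drug entry matches the target-name
list — any concomitant, interacting or other-suspect drug excludes the
report — and reruns the scan against the unchanged background.

## Time to onset

TTO is the raw day difference event − start (not difference + 1);
same-day pairs are valid at 0 days. A record is excluded, with an
audited reason, when either date is missing, either is not
day-precise, or the interval is negative. One TTO per report–PT pair;
the overall distribution takes the minimum onset per report
(first-event convention, configurable), while SOC-level analyses may
use all pairs. Quartiles use the inclusive linear-interpolation
convention (checked against the standard-library implementation).
Interval bins are right-closed with 0 included in the first bin
([0,30], (30,60], (60,90], (90,180], (180,360], (360,∞) days) so the
counts always partition the records.

The Weibull fit maximizes the likelihood by Newton iteration on the
profile score equation for the shape β (the scale α is closed-form
given β), with a bracketed root as fallback; zero onsets are shifted
to 0.5 days inside the likelihood only, the distribution having
positive support. The 95% CI for β comes from the inverse observed
information (central-difference Hessian) on the log(β) scale and is
then exponentiated, which keeps the bounds positive at small n.
Classification: early failure iff the CI upper bound is below 1,
wear-out iff the lower bound exceeds 1, random otherwise. At the
study's scale (n ≈ 1,000 valid records) the CI covers the true β at
the nominal rate (96.2% over 500 simulations). The fit refuses fewer
than 10 records or a degenerate all-equal sample.

Kaplan–Meier cumulative incidence is 1 − Ŝ(t) from the product-limit
estimator (lifelines); with no censoring — the default, since every
valid TTO record is an event — it equals the empirical CDF, and the
censored path is verified against a hand-computed product limit. The
SOC-level comparison is a Kruskal–Wallis rank test over SOCs with at
least 10 valid records; the published analysis does not name its test,
and Kruskal–Wallis matches the reported use of medians and IQRs.

## Synthetic data: what it emulates and what it does not

The generator draws reports whose primary-suspect drug and event PTs
are independent apart from three deliberate structures: injected
drug–PT associations at configured relative risks (the recoverable
ground truth), per-drug "label profiles" — every background drug gets
3 mildly enriched PTs with lognormal-dispersed relative risks (median
4, σ = 0.4) — because real reporting databases are heterogeneous and
an empirical-Bayes prior fitted to a perfectly independent background
would legitimately shrink every true signal away, and optional
subgroup-specific effects. Onset intervals are Weibull (default
α = 200 days, β = 0.55, the early-failure regime at a ~100-day
median); therapy starts are uniform over 2010–2022. Duplicate case
ids are emitted with an earlier receipt date and lower id, so the
dedup rule must drop exactly them. Missingness (sex 10%, age 25%,
weight 60%, dates 35% per side, 10% partial dates) is
missing-completely-at-random. One seeded stream drives everything;
a config reproduces its files byte for byte.

Not emulated: drug-name misspellings beyond dose-suffix tokens,
realistic country/indication marginals, correlated missingness,
reporting delays that depend on outcome, and true duplicate reports
with *differing* content. Passing tests therefore show the pipeline's
logic and estimators are correct under the stated statistical
structure, not that real FAERS/JADER artifacts (name noise, informative
missingness) are handled optimally.

## Problem sizes

The test suite and drivers run at deliberately modest scale: 4,000
reports (plus 8% duplicates) for the end-to-end injected-signal
recovery with expected injected count ≥ 20; twenty 1,500-report null
replicates for the specificity bound (composite-positive fraction
≤ 2%); 2,000 onset draws for shape recovery and 500 × 987 for CI
coverage; 10⁶ posterior draws for the EBGM quantile oracle. These
sizes put every stochastic acceptance band well inside its sampling
noise while keeping a full run at minutes on one CPU.

## Known limitations

- The MGPS prior fit needs a heterogeneous pair universe; on a corpus
  with a single drug (no background) the mixture is weakly identified
  and the fit warns below 20 pairs.
- Stratified MGPS expectations (DuMouchel's stratified E) are out of
  scope; E is always the whole-corpus independence expectation.
- Duplicate detection beyond the CASEID rule (probabilistic record
  linkage) is not attempted.
- The PT→SOC dictionary is user-supplied; unmapped PTs are routed to
  an `UNMAPPED` class and counted, never dropped silently.
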