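"""Time-to-onset (TTO) analysis.

TTO is the interval in days from therapy start (drug entry START_DT)
to event onset (EVENT_DT).  Pairs with a missing or partial date on
either side, or a negative interval, are excluded with an audited
reason.  The valid intervals feed four analyses: descriptive quartiles,
interval binning, a Weibull maximum-likelihood fit whose shape
parameter β classifies the hazard trend (early / random / wear-out
failure), and the Kaplan–Meier cumulative incidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._dates import DAY
from .model import Corpus

EXCLUSION_REASONS = ("missing_date", "imprecise_date", "negative_interval")

#: default interval edges in days: [0,30], (30,60], (60,90], (90,180], (180,360], (360,inf)
DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)
DEFAULT_BIN_LABELS = ("0-30", "31-60", "61-90", "91-180", "181-360", ">360")


def compute_tto_records(
    corpus: Corpus,
    drug_names=None,
    role: str = "PS",
    match: str = "substring",
):
    """Extract one candidate TTO per report–PT pair and audit exclusions.

    The therapy start for a report is the earliest day-precise start
    date among its drug entries with the given role (optionally
    restricted to ``drug_names``).  Returns ``(records, audit)`` where
    ``records`` has columns report_id / pt / onset_days and ``audit``
    carries per-reason exclusion counts plus the effective-report
    percentage round(100·n_reports_valid/N_reports, 1).
    """
    from .ingest import matches_target

    drugs = corpus.drugs
    if role is not None:
        drugs = drugs[drugs["role"] == role]
    if drug_names is not None:
        drugs = drugs[drugs["drug_name"].map(lambda n: matches_target(n, drug_names, match=match))]

    start_by_report: dict = {}
    start_prec: dict = {}
    for row in drugs.itertuples():
        prec_rank = {"day": 0, "month": 1, "year": 2, "missing": 3}
        prev = start_prec.get(row.report_id)
        # prefer day-precision starts; among day-precise, earliest date
        cand = (prec_rank[row.start_precision],
                row.start_date if row.start_date is not None else pd.Timestamp.max.date())
        if prev is None or cand < prev:
            start_prec[row.report_id] = cand
            start_by_report[row.report_id] = (row.start_date, row.start_precision)

    audit = {r: 0 for r in EXCLUSION_REASONS}
    records = []
    pairs = corpus.reactions.drop_duplicates(subset=["report_id", "pt"])
    for row in pairs.itertuples():
        start = start_by_report.get(row.report_id, (None, "missing"))
        s_date, s_prec = start
        e_date, e_prec = row.event_date, row.event_precision
        if s_date is None or e_date is None:
            audit["missing_date"] += 1
            continue
        if s_prec != DAY or e_prec != DAY:
            audit["imprecise_date"] += 1
            continue
        onset = (e_date - s_date).days
        if onset < 0:
            audit["negative_interval"] += 1
            continue
        records.append({"report_id": row.report_id, "pt": row.pt, "onset_days": float(onset)})

    rec = pd.DataFrame(records, columns=["report_id", "pt", "onset_days"])
    n_total = corpus.n_reports
    n_valid_reports = rec["report_id"].nunique()
    audit.update({
        "n_candidate_pairs": int(len(pairs)),
        "n_valid_pairs": int(len(rec)),
        "n_reports": int(n_total),
        "n_valid_reports": int(n_valid_reports),
        "effective_pct": round(100.0 * n_valid_reports / n_total, 1) if n_total else 0.0,
    })
    return rec, audit


def first_event(records: pd.DataFrame) -> pd.DataFrame:
    """One TTO per report: the minimum onset (first-event convention)."""
    if records.empty:
        return records
    idx = records.groupby("report_id")["onset_days"].idxmin()
    return records.loc[idx].reset_index(drop=True)


def tto_summary(onset_days) -> dict:
    """Median, quartiles, min, max (linear-interpolation quartiles)."""
    x = np.asarray(onset_days, dtype=float)
    if x.size == 0:
        raise ValueError("no TTO records")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": int(x.size), "median": float(med), "q1": float(q1),
            "q3": float(q3), "min": float(x.min()), "max": float(x.max())}


def bin_tto(onset_days, edges=DEFAULT_BIN_EDGES, labels=None) -> pd.DataFrame:
    """Counts and percentages per onset interval.

    Bins are right-closed with 0 included in the first bin, so the
    counts always partition the records.  Percentages are against the
    number of valid records, rounded to 2 decimals.
    """
    x = np.asarray(onset_days, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if labels is None:
        labels = DEFAULT_BIN_LABELS if tuple(edges) == tuple(DEFAULT_BIN_EDGES) else [
            f"bin{i}" for i in range(len(edges) + 1)]
    idx = np.searchsorted(edges, x, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    n = x.size
    return pd.DataFrame({
        "interval": list(labels),
        "n": counts.astype(int),
        "pct": [round(100.0 * c / n, 2) if n else 0.0 for c in counts],
    })


# ---------------------------------------------------------------------------
# Weibull fit

@dataclass(frozen=True)
class WeibullFit:
    """MLE of the Weibull TTO model with hazard-type classification."""

    scale_alpha: float
    shape_beta: float
    beta_lo95: float
    beta_hi95: float
    classification: str  # early_failure | random_failure | wearout_failure
    loglik: float
    n: int


def weibull_loglik(t, alpha: float, beta: float) -> float:
    t = np.asarray(t, dtype=float)
    z = t / alpha
    return float(t.size * (np.log(beta) - beta * np.log(alpha))
                 + (beta - 1.0) * np.log(t).sum() - np.power(z, beta).sum())


def classify_hazard(beta_lo95: float, beta_hi95: float) -> str:
    """Hazard trend from the shape-parameter CI: decreasing hazard
    (early failure) when the whole CI sits below 1, increasing
    (wear-out) when above 1, constant (random) when the CI contains 1."""
    if beta_hi95 < 1.0:
        return "early_failure"
    if beta_lo95 > 1.0:
        return "wearout_failure"
    return "random_failure"


def fit_weibull(onset_days, zero_shift: float = 0.5, tol: float = 1e-10, max_iter: int = 200) -> WeibullFit:
    """Weibull maximum-likelihood fit of onset times.

    Same-day onsets (0 days) are shifted to ``zero_shift`` inside the
    likelihood only (the distribution has positive support).  The shape
    β solves its profile score equation by Newton iteration with the
    scale α closed-form given β; the 95% CI for β comes from the
    inverse observed information on the log(β) scale, which keeps the
    bounds positive.
    """
    t = np.asarray(onset_days, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 onset records for a Weibull fit")
    if np.any(t < 0):
        raise ValueError("onset days must be non-negative")
    t = np.where(t == 0.0, zero_shift, t)
    if np.ptp(t) == 0.0:
        raise ValueError("degenerate sample: all onset times equal")

    logt = np.log(t)
    mean_logt = logt.mean()

    def score(beta):
        tb = np.power(t, beta)
        return 1.0 / beta + mean_logt - (tb * logt).sum() / tb.sum()

    def score_deriv(beta):
        tb = np.power(t, beta)
        s1 = tb.sum()
        s2 = (tb * logt).sum()
        s3 = (tb * logt ** 2).sum()
        return -1.0 / beta ** 2 - (s3 * s1 - s2 ** 2) / s1 ** 2

    beta = 1.2 / max(logt.std(), 1e-6)  # moment-style start
    converged = False
    for _ in range(max_iter):
        step = score(beta) / score_deriv(beta)
        new = beta - step
        if new <= 0:
            new = beta / 2.0
        if abs(new - beta) < tol * max(1.0, beta):
            beta = new
            converged = True
            break
        beta = new
    if not converged and abs(score(beta)) > 1e-6:
        # robust fallback: bracketed root
        try:
            beta = optimize.brentq(score, 1e-3, 1e3)
            converged = True
        except ValueError as err:
            raise RuntimeError(f"Weibull shape iteration failed: score={score(beta):.3g}") from err
    alpha = float(np.power(np.power(t, beta).mean(), 1.0 / beta))

    # observed information in (log alpha, log beta) by central differences
    la, lb = np.log(alpha), np.log(beta)
    h = 1e-4

    def ll(p):
        return weibull_loglik(t, np.exp(p[0]), np.exp(p[1]))

    H = np.empty((2, 2))
    p0 = np.array([la, lb])
    for i in range(2):
        for j in range(2):
            pp = p0.copy(); pp[i] += h; pp[j] += h
            pm = p0.copy(); pm[i] += h; pm[j] -= h
            mp = p0.copy(); mp[i] -= h; mp[j] += h
            mm = p0.copy(); mm[i] -= h; mm[j] -= h
            H[i, j] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * h * h)
    cov = np.linalg.inv(-H)
    se_lb = float(np.sqrt(max(cov[1, 1], 0.0)))
    lo = float(beta * np.exp(-1.959963984540054 * se_lb))
    hi = float(beta * np.exp(+1.959963984540054 * se_lb))
    return WeibullFit(
        scale_alpha=alpha, shape_beta=float(beta), beta_lo95=lo, beta_hi95=hi,
        classification=classify_hazard(lo, hi),
        loglik=weibull_loglik(t, alpha, beta), n=int(t.size),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and SOC comparison

def km_cumulative_incidence(onset_days, event_observed=None) -> pd.DataFrame:
    """Kaplan–Meier cumulative incidence 1 − Ŝ(t) as (time, estimate).

    Without censoring (the default: every valid TTO is an event) the
    curve equals the empirical CDF.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(onset_days, dtype=float)
    if t.size == 0:
        raise ValueError("no TTO records")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=event_observed)
    sf = kmf.survival_function_
    return pd.DataFrame({
        "time": sf.index.to_numpy(dtype=float),
        "cumulative_incidence": 1.0 - sf.iloc[:, 0].to_numpy(dtype=float),
    })


def compare_tto_across_socs(records: pd.DataFrame, min_n: int = 10):
    """Kruskal–Wallis rank test of onset times across SOC groups.

    ``records`` needs columns ``soc`` and ``onset_days``.  Only SOCs
    with at least ``min_n`` valid records enter; fewer than two
    eligible groups is an error.  Returns ``(statistic, p, table)``
    with the per-SOC median/IQR table sorted by median.
    """
    sizes = records.groupby("soc")["onset_days"].size()
    eligible = sizes[sizes >= min_n].index
    groups = [records.loc[records["soc"] == s, "onset_days"].to_numpy() for s in eligible]
    if len(groups) < 2:
        raise ValueError("need >=2 SOC groups with enough records")
    stat, p = stats.kruskal(*groups)
    rows = []
    for s in eligible:
        summ = tto_summary(records.loc[records["soc"] == s, "onset_days"])
        rows.append({"soc": s, **summ})
    table = pd.DataFrame(rows).sort_values("median").reset_index(drop=True)
    return float(stat), float(p), table
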