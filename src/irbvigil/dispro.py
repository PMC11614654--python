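"""Drug–event disproportionality statistics.

Four estimators over the 2×2 report table (a = reports with the target
drug and the target event, b/c/d its complements, N = a+b+c+d):

* ROR — reporting odds ratio (a·d)/(b·c) with a Wald log-scale CI;
* PRR — proportional reporting ratio with a Yates-corrected χ²;
* BCPNN information component — closed-form posterior mean and
  variance of log2[p11/(p1·p·1)] under Dirichlet/Beta priors;
* MGPS EBGM — empirical-Bayes geometric mean of the observed/expected
  ratio λ under a two-component gamma mixture prior fitted by
  maximizing the negative-binomial mixture marginal likelihood.

A term is a composite signal when it passes all four positivity
thresholds simultaneously (a ≥ 3 & ROR025 > 1; a ≥ 3 & PRR ≥ 2 &
χ² ≥ 4; IC025 > 0; EBGM05 > 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import MeddraMap, map_pt_to_soc
from .model import Corpus

_LN2 = math.log(2.0)
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2×2 counts for one drug–event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError("contingency cells must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    @property
    def untestable(self) -> bool:
        return self.a + self.c == 0 or self.a + self.b == 0


@dataclass
class ScanConfig:
    """Tunable knobs of a disproportionality scan."""

    counting: str = "report_pair"       # a report counts once per event term
    yates: bool = True                  # continuity correction in the χ²
    zero_cell: str = "haldane"          # +0.5 to all cells when any cell is 0 ("none" to disable)
    ic025_method: str = "bate"          # "bate": ic - 2*sqrt(v); "fixed_offset": ic - k
    ic025_offset: float = 1.67
    min_count: int = 3                  # minimum a for ROR/PRR positivity
    alpha: float = 0.05
    p_method: str = "chi2"              # or "fisher"
    prior_scope: str = "database"       # fit the MGPS prior on all drug-event pairs ("scan": target only)


# ---------------------------------------------------------------------------
# pair universes

def report_event_pairs(corpus: Corpus, meddra: MeddraMap | None, level: str = "pt") -> pd.DataFrame:
    """Distinct (report_id, term, code) pairs at PT or SOC level.

    A report contributes at most once per term: repeated PTs on one
    report, or several PTs mapping into one SOC, collapse to a single
    pair.
    """
    if level not in {"pt", "soc"}:
        raise ValueError("level must be 'pt' or 'soc'")
    if level == "pt":
        if meddra is not None:
            reac, _ = map_pt_to_soc(corpus, meddra)
            pairs = reac[["report_id", "pt", "pt_code"]].rename(
                columns={"pt": "term", "pt_code": "code"})
        else:
            pairs = corpus.reactions[["report_id", "pt"]].rename(columns={"pt": "term"})
            pairs["code"] = -1
    else:
        if meddra is None:
            raise ValueError("SOC-level pairs require a MedDRA map")
        reac, _ = map_pt_to_soc(corpus, meddra)
        pairs = reac[["report_id", "soc", "soc_code"]].rename(
            columns={"soc": "term", "soc_code": "code"})
    return pairs.drop_duplicates(subset=["report_id", "term"]).reset_index(drop=True)


def mgps_pair_universe(
    corpus: Corpus,
    meddra: MeddraMap | None,
    level: str = "pt",
    role_filter=frozenset({"PS"}),
):
    """(a, E) for every drug–term pair in the corpus.

    The MGPS hyperparameters are estimated from the whole database's
    pair counts — the shrinkage prior models the spread of
    observed/expected ratios across all drugs, not just the target.
    Exposure is the report's primary-suspect drug name (verbatim,
    case-folded).
    """
    pairs = report_event_pairs(corpus, meddra, level=level)
    drugs = corpus.drugs[corpus.drugs["role"].isin(set(role_filter))][
        ["report_id", "drug_name"]].copy()
    drugs["drug"] = drugs["drug_name"].astype(str).str.strip().str.casefold()
    drugs = drugs.drop_duplicates(subset=["report_id", "drug"])
    merged = pairs.merge(drugs[["report_id", "drug"]], on="report_id", how="inner")
    # full drug x term grid, zero cells included: the mixture likelihood
    # needs the unobserved combinations, not only a >= 1
    grid = merged.groupby(["drug", "term"], sort=False).size().unstack(fill_value=0)
    ab = merged.groupby("drug", sort=False).size().reindex(grid.index)
    ac = pairs.groupby("term", sort=False).size().reindex(grid.columns)
    n = len(pairs)
    a = grid.to_numpy(dtype=float).ravel()
    e = np.outer(ab.to_numpy(dtype=float), ac.to_numpy(dtype=float)).ravel() / n
    keep = e > 0
    return a[keep], e[keep]


def build_contingency(pairs: pd.DataFrame, target_report_ids, term: str) -> ContingencyTable:
    """2×2 table for one term against the pair universe.

    ``pairs`` is the full-corpus pair table from
    :func:`report_event_pairs`; ``target_report_ids`` the reports
    exposed to the target drug.  b/c/d are derived by marginal
    subtraction.
    """
    targets = set(target_report_ids)
    is_target = pairs["report_id"].isin(targets)
    is_term = pairs["term"] == term
    a = int((is_target & is_term).sum())
    ab = int(is_target.sum())
    ac = int(is_term.sum())
    n = len(pairs)
    t = ContingencyTable(a=a, b=ab - a, c=ac - a, d=n - ab - ac + a)
    if t.untestable:
        warnings.warn(f"term {term!r} untestable (empty margin)", stacklevel=2)
    return t


# ---------------------------------------------------------------------------
# frequentist statistics

def compute_ror(t: ContingencyTable, zero_cell: str = "haldane"):
    """ROR with 95% Wald CI; Haldane–Anscombe +0.5 applied only when a
    zero cell occurs (returned flag says whether it was)."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0:
        if zero_cell == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        else:
            return np.nan, np.nan, np.nan, False
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - _Z95 * se)
    hi = math.exp(math.log(ror) + _Z95 * se)
    return ror, lo, hi, corrected


def compute_prr(t: ContingencyTable, yates: bool = True, p_method: str = "chi2"):
    """PRR plus the 2×2 Pearson χ² (Yates-corrected by default) and its
    upper-tail p-value (or Fisher's exact p when requested)."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return np.nan, np.nan, np.nan
    prr = np.inf if c == 0 else (a / (a + b)) / (c / (c + d))
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    if p_method == "fisher":
        p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
    else:
        p = float(stats.chi2.sf(chi2, df=1))
    return prr, chi2, p


# ---------------------------------------------------------------------------
# BCPNN information component

def compute_bcpnn(t: ContingencyTable, method: str = "bate", offset: float = 1.67):
    """Closed-form IC posterior mean and IC025.

    Priors: marginals Beta(1, 1) (α1 = β1 = 1, α = β = 2) and joint
    cell prior γ11 = 1 with γ scaled so the prior IC expectation is 0.
    ``method='bate'`` sets IC025 = IC − 2√V(IC); ``'fixed_offset'``
    subtracts a constant (default 1.67).
    """
    a, b, c = float(t.a), float(t.b), float(t.c)
    n = float(t.n)
    if n <= 0:
        raise ValueError("empty table")
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    ic = math.log2((a + g11) * (n + al) * (n + be)
                   / ((n + gamma) * (a + b + a1) * (a + c + b1)))
    v = (1.0 / _LN2) ** 2 * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - a - b + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - a - c + be - b1) / ((a + c + b1) * (1 + n + be))
    )
    if method == "bate":
        ic025 = ic - 2.0 * math.sqrt(v)
    elif method == "fixed_offset":
        ic025 = ic - offset
    else:
        raise ValueError(f"unknown ic025 method {method!r}")
    return ic, ic025


# ---------------------------------------------------------------------------
# MGPS / EBGM

@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the rate ratio λ."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    loglik: float = field(default=np.nan, compare=False)

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes/rates must be positive")
        if not 0 < self.mix_p < 1:
            raise ValueError("mix_p must be in (0, 1)")


def _nb_logpmf(a, alpha, beta, e):
    # marginal of a | E under lambda ~ Gamma(alpha, rate beta): NB(alpha, beta/(beta+E))
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


def mgps_marginal_loglik(theta, a, e):
    """Σ log NB-mixture at unconstrained theta = (log α1, log β1, log α2, log β2, logit p)."""
    la1, lb1, la2, lb2, lp = theta
    alpha1, beta1, alpha2, beta2 = np.exp([la1, lb1, la2, lb2])
    p = float(np.clip(special.expit(lp), 1e-12, 1.0 - 1e-12))
    l1 = _nb_logpmf(a, alpha1, beta1, e) + np.log(p)
    l2 = _nb_logpmf(a, alpha2, beta2, e) + np.log1p(-p)
    return float(np.logaddexp(l1, l2).sum())


_DEFAULT_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
_EXTRA_STARTS = (
    (20.0, 20.0, 2.0, 0.5, 0.95),
    (1.0, 1.0, 1.0, 0.2, 0.5),
)


def _em_fit(a, e, start, max_iter: int = 150, tol: float = 5e-7):
    """EM for the two-component NB mixture; returns (params, loglik).

    A generalized EM: each M-step improves (not necessarily maximizes)
    the weighted component likelihoods, which preserves monotonicity.
    """
    a1, b1, a2, b2, p = (float(x) for x in start)
    gl_a1 = special.gammaln(a + 1.0)
    # counts repeat heavily across the pair universe; evaluating gammaln on
    # the unique counts only makes each likelihood call ~cheap
    ua, inv = np.unique(a, return_inverse=True)

    def nb_ll(alpha, beta):
        # vectorized NB(alpha, beta/(beta+E)) log-pmf over all pairs
        q = beta / (beta + e)
        with np.errstate(divide="ignore", invalid="ignore"):
            tail = a * np.log1p(-q)
        return (special.gammaln(ua + alpha)[inv] - special.gammaln(alpha) - gl_a1
                + alpha * np.log(q) + np.where(a == 0.0, 0.0, tail))

    def component_nll(theta, resp):
        if np.any(np.abs(theta) > 13.0):  # keep components off the point-mass ridge
            return 1e12
        with np.errstate(over="ignore", invalid="ignore"):
            ll = resp @ nb_ll(np.exp(theta[0]), np.exp(theta[1]))
        return 1e12 if not np.isfinite(ll) else -ll

    prev = -np.inf
    for _ in range(max_iter):
        l1 = np.log(p) + nb_ll(a1, b1)
        l2 = np.log1p(-p) + nb_ll(a2, b2)
        tot = np.logaddexp(l1, l2)
        ll = float(tot.sum())
        r1 = np.exp(l1 - tot)
        p = float(np.clip(r1.mean(), 1e-6, 1.0 - 1e-6))
        for which, resp in ((1, r1), (2, 1.0 - r1)):
            cur = (a1, b1) if which == 1 else (a2, b2)
            res = optimize.minimize(component_nll, np.log(cur), args=(resp,),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 80})
            if which == 1:
                a1, b1 = np.exp(res.x)
            else:
                a2, b2 = np.exp(res.x)
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll
    return (a1, b1, a2, b2, p), prev


def fit_mgps_prior(a, e) -> MgpsPrior:
    """Fit the gamma-mixture hyperparameters by maximum marginal likelihood.

    ``a`` are the observed pair counts, ``e`` the expected counts
    (a+b)(a+c)/N.  The negative-binomial mixture marginal is maximized
    by EM (monotone, so the optimum never scores below its start) from
    DuMouchel's classic starting point plus multi-start fallbacks;
    raises if every start fails.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape or a.size == 0:
        raise ValueError("a and e must be equal-length non-empty arrays")
    if np.any(e <= 0):
        raise ValueError("expected counts must be positive")
    if a.size < 20:
        warnings.warn("fewer than 20 pairs: hyperparameter fit may be unstable", stacklevel=2)

    best = None
    best_ll = -np.inf
    for start in (_DEFAULT_START,) + _EXTRA_STARTS:
        try:
            params, ll = _em_fit(a, e, start)
        except (FloatingPointError, ValueError):
            continue
        if np.isfinite(ll) and ll > best_ll:
            best, best_ll = params, ll
    if best is None:
        raise RuntimeError("MGPS hyperparameter fit failed from every start")
    a1, b1, a2, b2, p = best
    return MgpsPrior(alpha1=a1, beta1=b1, alpha2=a2, beta2=b2, mix_p=p, loglik=best_ll)


def posterior_mixture(a: float, e: float, prior: MgpsPrior):
    """Posterior on λ given (a, E): gamma components and their weights."""
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    logw = np.array([
        math.log(prior.mix_p) + _nb_logpmf(a, prior.alpha1, prior.beta1, e),
        math.log1p(-prior.mix_p) + _nb_logpmf(a, prior.alpha2, prior.beta2, e),
    ])
    w = np.exp(logw - special.logsumexp(logw))
    return shapes, rates, w


def compute_ebgm(a: float, e: float, prior: MgpsPrior):
    """EBGM = 2^{E[log2 λ]} and EBGM05, the posterior 5th percentile.

    The geometric-mean exponent uses the digamma identity
    E[ln λ | Gamma(s, r)] = ψ(s) − ln r; the percentile is root-found
    on the two-component posterior gamma-mixture CDF.
    """
    shapes, rates, w = posterior_mixture(a, e, prior)
    e_ln = float(np.dot(w, special.digamma(shapes) - np.log(rates)))
    ebgm = math.exp(e_ln)

    def cdf(x):
        return float(np.dot(w, stats.gamma.cdf(x, shapes, scale=1.0 / rates)))

    lo = min(float(stats.gamma.ppf(1e-4, s, scale=1.0 / r)) for s, r in zip(shapes, rates))
    hi = max(float(stats.gamma.ppf(0.999999, s, scale=1.0 / r)) for s, r in zip(shapes, rates))
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, max(lo, 1e-300), hi))
    return ebgm, ebgm05


# ---------------------------------------------------------------------------
# composite rule, multiplicity

def evaluate_thresholds(a, ror_lo95, prr, chi2, ic025, ebgm05, min_count: int = 3) -> dict:
    """Four-way positivity flags and their conjunction.

    ror_pos ⟺ a ≥ min_count and ROR025 > 1; prr_pos ⟺ a ≥ min_count,
    PRR ≥ 2 and χ² ≥ 4; bcpnn_pos ⟺ IC025 > 0; mgps_pos ⟺ EBGM05 > 2.
    NaN statistics (untestable tables) never satisfy a threshold.
    """
    def ok(x):
        return x is not None and np.isfinite(x)

    ror_pos = bool(a >= min_count and ok(ror_lo95) and ror_lo95 > 1.0)
    prr_pos = bool(a >= min_count and ok(prr) and prr >= 2.0 and ok(chi2) and chi2 >= 4.0)
    bcpnn_pos = bool(ok(ic025) and ic025 > 0.0)
    mgps_pos = bool(ok(ebgm05) and ebgm05 > 2.0)
    return {
        "ror_pos": ror_pos, "prr_pos": prr_pos,
        "bcpnn_pos": bcpnn_pos, "mgps_pos": mgps_pos,
        "all_four_pos": ror_pos and prr_pos and bcpnn_pos and mgps_pos,
    }


def bonferroni_adjust(p_raw, n_tests: int | None = None):
    """p_adj = min(1, p·n) over the scan's n tested terms."""
    p = np.asarray(p_raw, dtype=float)
    n = len(p) if n_tests is None else n_tests
    if n == 0:
        return p
    return np.minimum(1.0, p * n)


# ---------------------------------------------------------------------------
# the scan

def run_signal_scan(
    corpus: Corpus,
    meddra: MeddraMap | None,
    target_report_ids,
    level: str = "pt",
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Full disproportionality scan of every term observed for the target.

    ``corpus`` is the deduplicated background (all drugs); the target
    exposure is the set of report ids.  Returns one row per term with
    a ≥ 1, sorted by a descending, including volcano-plot coordinates
    (log2 ROR, −log10 Bonferroni-adjusted p).
    """
    cfg = config or ScanConfig()
    pairs = report_event_pairs(corpus, meddra, level=level)
    targets = set(target_report_ids)
    n_pairs = len(pairs)
    is_target = pairs["report_id"].isin(targets)
    ab = int(is_target.sum())

    term_tot = pairs.groupby("term", sort=False).size()
    target_counts = pairs[is_target].groupby("term", sort=False).size()
    codes = dict(zip(pairs["term"], pairs["code"]))

    rows = []
    for term, a in target_counts.items():
        ac = int(term_tot[term])
        t = ContingencyTable(a=int(a), b=ab - int(a), c=ac - int(a),
                             d=n_pairs - ab - ac + int(a))
        ror, lo, hi, corrected = compute_ror(t, cfg.zero_cell)
        prr, chi2, p_raw = compute_prr(t, yates=cfg.yates, p_method=cfg.p_method)
        ic, ic025 = compute_bcpnn(t, method=cfg.ic025_method, offset=cfg.ic025_offset)
        rows.append({
            "term": term, "code": codes.get(term, -1), "level": level,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d, "expected": t.expected,
            "ror": ror, "ror_lo95": lo, "ror_hi95": hi, "zero_corrected": corrected,
            "prr": prr, "chi2": chi2, "p_raw": p_raw, "ic": ic, "ic025": ic025,
        })
    if not rows:
        return pd.DataFrame(columns=[
            "term", "code", "level", "a", "b", "c", "d", "expected",
            "ror", "ror_lo95", "ror_hi95", "zero_corrected", "prr", "chi2",
            "p_raw", "p_adj", "ic", "ic025", "ebgm", "ebgm05",
            "ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "all_four_pos",
            "log2_ror", "neglog10_p_adj",
        ])
    out = pd.DataFrame(rows)

    if cfg.prior_scope == "database":
        a_all, e_all = mgps_pair_universe(corpus, meddra, level=level)
        prior = fit_mgps_prior(a_all, e_all)
    else:
        prior = fit_mgps_prior(out["a"].to_numpy(), out["expected"].to_numpy())
    ebgm_pairs = [compute_ebgm(a, e, prior) for a, e in zip(out["a"], out["expected"])]
    out["ebgm"] = [x[0] for x in ebgm_pairs]
    out["ebgm05"] = [x[1] for x in ebgm_pairs]

    out["p_adj"] = bonferroni_adjust(out["p_raw"].to_numpy())
    flags = [
        evaluate_thresholds(r.a, r.ror_lo95, r.prr, r.chi2, r.ic025, r.ebgm05,
                            min_count=cfg.min_count)
        for r in out.itertuples()
    ]
    for key in ("ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "all_four_pos"):
        out[key] = [f[key] for f in flags]

    with np.errstate(divide="ignore"):
        out["log2_ror"] = np.log2(out["ror"])
        out["neglog10_p_adj"] = -np.log10(out["p_adj"])
    out.attrs["prior"] = prior
    return out.sort_values(["a", "term"], ascending=[False, True]).reset_index(drop=True)
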