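"""Synthetic FAERS-like and JADER-like raw file sets with known truth.

The generator emulates the statistical structure the pipeline assumes:
a background of reports whose drug and event assignments are
independent, chosen drug–event pairs oversampled by a configured
relative risk, duplicate case ids with differing receipt dates to
exercise the deduplication rule, controlled missingness and partial
dates, and Weibull-distributed onset intervals.  Everything derives
from a single seeded random stream, so a config reproduces its files
byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

TARGET_DRUG_FAERS = "IRBESARTAN"
TARGET_DRUG_JADER = "イルベサルタン"

_FAERS_SUFFIXES = ("", "", "", " 150MG", " 300MG TABLET", " (APROVEL)")


@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus."""

    n_reports: int = 5000
    n_drugs: int = 20
    n_pts: int = 200
    n_socs: int = 27
    target_share: float = 0.10          # fraction of reports whose PS drug is the target
    injected_signals: tuple = ()        # (drug_name, pt, relative_risk)
    duplicate_rate: float = 0.05        # fraction of case ids emitted twice
    missing_sex_rate: float = 0.10
    missing_age_rate: float = 0.25
    missing_weight_rate: float = 0.60
    missing_date_rate: float = 0.35     # either start or event date blank
    date_imprecision_rate: float = 0.10  # date truncated to YYYYMM or YYYY
    tto_scale: float = 200.0            # Weibull scale alpha, days
    tto_shape: float = 0.55             # Weibull shape beta (early-failure regime)
    concomitant_rate: float = 0.30      # chance of an extra non-target drug entry
    events_per_report_mean: float = 1.6  # >=1, Poisson-shifted
    # every background drug gets its own mildly enriched "label" PTs, the
    # heterogeneity real reporting databases show and shrinkage priors rely on
    background_signals_per_drug: int = 3
    background_signal_rr: float = 4.0   # median label-effect RR
    background_signal_sigma: float = 0.4  # lognormal spread of label RRs
    subgroup_effects: tuple = ()        # (pt, variable, level, relative_risk)
    seed: int = 0

    def __post_init__(self):
        for r in (self.target_share, self.duplicate_rate, self.missing_sex_rate,
                  self.missing_age_rate, self.missing_weight_rate,
                  self.missing_date_rate, self.date_imprecision_rate,
                  self.concomitant_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for _, _, rr in self.injected_signals:
            if rr <= 0:
                raise ValueError("relative risks must be positive")


def _pt_name(i: int) -> str:
    return f"pt_{i:03d}"


def _drug_name(i: int) -> str:
    return f"DRUG_{i:02d}"


def generate_meddra_fixture(n_pts: int, n_socs: int, seed: int, path) -> Path:
    """Write a deterministic synthetic PT→SOC dictionary (TSV).

    Synthetic stand-in for a real MedDRA export; every PT maps to one
    of ``n_socs`` classes (round-robin with a seeded shuffle), so SOC
    sizes differ by at most one and none is empty for n_pts >= n_socs.
    """
    if n_socs > 27:
        raise ValueError("n_socs must be <= 27")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pts)
    lines = ["pt\tpt_code\tsoc\tsoc_code"]
    for i in range(n_pts):
        soc_idx = int(order[i]) % n_socs
        lines.append(f"{_pt_name(i)}\t{10_000_000 + i}\tsoc_{soc_idx:02d}\t{20_000_000 + soc_idx}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _degrade_date(rng, d: _dt.date, missing_rate, imprecise_rate) -> str:
    u = rng.random()
    if u < missing_rate:
        return ""
    if u < missing_rate + imprecise_rate:
        return d.strftime("%Y%m") if rng.random() < 0.5 else d.strftime("%Y")
    return d.strftime("%Y%m%d")


def _draw_reports(config: SimConfig, rng):
    """Sample the latent per-report truth shared by both dialects."""
    n = config.n_reports
    target = TARGET_DRUG_FAERS
    drug_pool = [_drug_name(i) for i in range(1, config.n_drugs)]
    injected = {}
    for drug, pt, rr in config.injected_signals:
        injected.setdefault(drug, {})[pt] = rr
    sub_effects = {}
    for pt, var, lvl, rr in config.subgroup_effects:
        sub_effects.setdefault((var, lvl), {})[pt] = rr

    # infeasible-injection guard: expected a for an injected target pair
    for drug, pts in injected.items():
        share = config.target_share if drug == target else (1 - config.target_share) / max(len(drug_pool), 1)
        for pt, rr in pts.items():
            expected_a = n * share * config.events_per_report_mean * rr / config.n_pts
            if expected_a < 1.0:
                raise ValueError(
                    f"infeasible config: injected pair ({drug}, {pt}) expects {expected_a:.2f} reports")

    base_w = np.ones(config.n_pts)
    pt_names = [_pt_name(i) for i in range(config.n_pts)]
    pt_index = {p: i for i, p in enumerate(pt_names)}

    # background drug "label" profiles (drawn first so report sampling is
    # reproducible regardless of how many profiles exist)
    label_profiles: dict = {}
    if config.background_signals_per_drug > 0:
        for d in drug_pool:
            idx = rng.choice(config.n_pts, size=min(config.background_signals_per_drug, config.n_pts),
                             replace=False)
            label_profiles[d] = {
                pt_names[j]: float(config.background_signal_rr
                                   * np.exp(rng.normal(0.0, config.background_signal_sigma)))
                for j in idx
            }

    reports = []
    for i in range(n):
        is_target = rng.random() < config.target_share
        ps_drug = target if is_target else drug_pool[rng.integers(len(drug_pool))]
        sex = "" if rng.random() < config.missing_sex_rate else ("F" if rng.random() < 0.5 else "M")
        age = np.nan if rng.random() < config.missing_age_rate else float(np.clip(rng.normal(62, 15), 1, 100))
        weight = np.nan if rng.random() < config.missing_weight_rate else float(np.clip(rng.normal(75, 15), 35, 160))

        w = base_w.copy()
        for pt, rr in label_profiles.get(ps_drug, {}).items():
            w[pt_index[pt]] *= rr
        for pt, rr in injected.get(ps_drug, {}).items():
            w[pt_index[pt]] *= rr
        for (var, lvl), pts in sub_effects.items():
            hit = (var == "sex" and lvl == {"F": "female", "M": "male"}.get(sex)) or (
                var == "age" and not np.isnan(age)
                and ((lvl == "<65" and age < 65) or (lvl == ">=65" and age >= 65)))
            if hit and ps_drug == target:
                for pt, rr in pts.items():
                    w[pt_index[pt]] *= rr
        p = w / w.sum()
        k = 1 + rng.poisson(max(config.events_per_report_mean - 1.0, 0.0))
        events = [pt_names[j] for j in rng.choice(config.n_pts, size=min(k, config.n_pts),
                                                  replace=False, p=p)]

        start = _dt.date(2010, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 4500)))
        onset = float(rng.weibull(config.tto_shape) * config.tto_scale)
        event_date = start + _dt.timedelta(days=int(round(onset)))
        conco = None
        if rng.random() < config.concomitant_rate:
            conco = drug_pool[rng.integers(len(drug_pool))]
        reports.append({
            "case": f"C{i:07d}", "primaryid": f"{1000000 + i * 10}",
            "ps_drug": ps_drug, "conco": conco, "events": events,
            "sex": sex, "age": age, "weight": weight,
            "start": start, "event_date": event_date, "onset": onset,
            "fda_dt": start + _dt.timedelta(days=int(rng.integers(0, 3000))),
        })
    return reports


def generate_corpus(config: SimConfig, outdir, dialect: str = "faers"):
    """Write one synthetic raw file set plus a ground-truth sidecar.

    Returns ``(paths, ground_truth)`` where ``paths`` feeds straight
    into :func:`irbvigil.ingest.read_faers_quarter` /
    :func:`~irbvigil.ingest.read_jader` and ``ground_truth`` records
    injected associations, true Weibull parameters, the per-pair
    report counts, and the number of constructed duplicates.
    """
    if dialect not in {"faers", "jader"}:
        raise ValueError("dialect must be 'faers' or 'jader'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    reports = _draw_reports(config, rng)

    n_dup = int(round(config.duplicate_rate * config.n_reports))
    dup_idx = sorted(rng.choice(config.n_reports, size=n_dup, replace=False)) if n_dup else []

    target = TARGET_DRUG_FAERS if dialect == "faers" else TARGET_DRUG_JADER
    truth_counts: dict = {}
    for r in reports:
        if r["ps_drug"] == TARGET_DRUG_FAERS:
            for pt in r["events"]:
                truth_counts[pt] = truth_counts.get(pt, 0) + 1

    if dialect == "faers":
        paths = _write_faers(config, reports, dup_idx, rng, outdir)
    else:
        paths = _write_jader(config, reports, dup_idx, rng, outdir)

    ground_truth = {
        "dialect": dialect,
        "seed": config.seed,
        "n_unique_reports": config.n_reports,
        "n_duplicates": len(dup_idx),
        "target_drug": target,
        "injected_signals": [list(s) for s in config.injected_signals],
        "tto_scale": config.tto_scale,
        "tto_shape": config.tto_shape,
        "target_pt_counts": truth_counts,
        "n_target_reports": sum(1 for r in reports if r["ps_drug"] == TARGET_DRUG_FAERS),
    }
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(ground_truth, indent=2, sort_keys=True), encoding="utf-8")
    paths["ground_truth"] = gt_path
    return paths, ground_truth


def _faers_drug_field(rng, name: str) -> str:
    if name == TARGET_DRUG_FAERS:
        return name + _FAERS_SUFFIXES[rng.integers(len(_FAERS_SUFFIXES))]
    return name


def _write_faers(config, reports, dup_idx, rng, outdir: Path) -> dict:
    demo = ["PRIMARYID$CASEID$FDA_DT$EVENT_DT$SEX$AGE$AGE_COD$WT$WT_COD$OCCR_COUNTRY$OCCP_COD"]
    drug = ["PRIMARYID$DRUG_SEQ$ROLE_COD$DRUGNAME"]
    reac = ["PRIMARYID$PT"]
    ther = ["PRIMARYID$DSG_DRUG_SEQ$START_DT$END_DT"]
    outc = ["PRIMARYID$OUTC_COD"]
    countries = ("FR", "US", "GB", "IT", "CA", "JP", "DE")
    outcome_codes = ("HO", "OT", "LT", "DE", "DS")

    def emit(r, primaryid, fda_dt):
        age = "" if np.isnan(r["age"]) else f"{r['age']:.0f}"
        wt = "" if np.isnan(r["weight"]) else f"{r['weight']:.1f}"
        event_dt = _degrade_date(rng, r["event_date"], config.missing_date_rate / 2,
                                 config.date_imprecision_rate)
        demo.append("$".join([
            primaryid, r["case"], fda_dt.strftime("%Y%m%d"), event_dt,
            r["sex"], age, "YR" if age else "", wt, "KG" if wt else "",
            countries[rng.integers(len(countries))],
            "MD" if rng.random() < 0.6 else "CN",
        ]))
        drug.append(f"{primaryid}$1$PS${_faers_drug_field(rng, r['ps_drug'])}")
        start_dt = _degrade_date(rng, r["start"], config.missing_date_rate / 2,
                                 config.date_imprecision_rate)
        ther.append(f"{primaryid}$1${start_dt}$")
        if r["conco"]:
            drug.append(f"{primaryid}$2$C${r['conco']}")
        for pt in r["events"]:
            reac.append(f"{primaryid}${pt}")
        if rng.random() < 0.7:
            outc.append(f"{primaryid}${outcome_codes[rng.integers(len(outcome_codes))]}")

    dup_set = set(dup_idx)
    for i, r in enumerate(reports):
        emit(r, r["primaryid"], r["fda_dt"])
        if i in dup_set:
            # earlier receipt, lower primary id: the dedup rule must drop it
            emit(r, str(int(r["primaryid"]) - 1), r["fda_dt"] - _dt.timedelta(days=30))

    paths = {}
    for key, lines in (("demo", demo), ("drug", drug), ("reac", reac),
                       ("ther", ther), ("outc", outc)):
        p = outdir / f"{key.upper()}.txt"
        p.write_text("\n".join(lines) + "\n", encoding="ascii")
        paths[key] = p
    return paths


def _jader_age_string(age: float) -> str:
    if np.isnan(age):
        return "不明"
    return f"{int(age // 10) * 10}歳代"


def _write_jader(config, reports, dup_idx, rng, outdir: Path) -> dict:
    # JADER has no receipt-date dedup; duplicates are simply not emitted
    demo = ["識別番号,性別,年齢,体重,転帰"]
    drug = ["識別番号,医薬品（一般名）,医薬品の関与,投与開始日"]
    reac = ["識別番号,有害事象,有害事象発現日"]
    outcomes = ("回復", "軽快", "未回復", "死亡")
    for r in reports:
        rid = r["case"]
        sex = {"F": "女性", "M": "男性"}.get(r["sex"], "")
        wt = "" if np.isnan(r["weight"]) else f"{int(r['weight'] // 10) * 10}kg代"
        demo.append(",".join([rid, sex, _jader_age_string(r["age"]), wt,
                              outcomes[rng.integers(len(outcomes))]]))
        name = TARGET_DRUG_JADER if r["ps_drug"] == TARGET_DRUG_FAERS else r["ps_drug"]
        start = _degrade_date(rng, r["start"], config.missing_date_rate / 2,
                              config.date_imprecision_rate)
        drug.append(f"{rid},{name},被疑薬,{start}")
        if r["conco"]:
            drug.append(f"{rid},{r['conco']},併用薬,")
        event_dt = _degrade_date(rng, r["event_date"], config.missing_date_rate / 2,
                                 config.date_imprecision_rate)
        for pt in r["events"]:
            reac.append(f"{rid},{pt},{event_dt}")
    paths = {}
    for key, lines in (("demo", demo), ("drug", drug), ("reac", reac)):
        p = outdir / f"{key}.csv"
        # real JADER exports are Shift-JIS; exercise that decode path
        p.write_text("\n".join(lines) + "\n", encoding="cp932")
        paths[key] = p
    return paths
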