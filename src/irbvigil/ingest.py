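"""Readers and report-level filters for FAERS and JADER raw files.

FAERS quarters ship as ``$``-delimited ASCII tables (DEMO/DRUG/REAC plus
optional THER/INDI/OUTC); JADER ships CSV (DEMO/DRUG/REAC/HIST,
typically Shift-JIS encoded).  Both are normalized into a
:class:`~irbvigil.model.Corpus`.  Deduplication follows the FDA
recommendation: keep the report with the latest receipt date per case
id, breaking ties by the higher primary id.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from ._dates import DAY, MISSING, parse_date
from .model import (
    Corpus,
    DRUG_COLUMNS,
    OUTCOME_CODES,
    REACTION_COLUMNS,
    REPORT_COLUMNS,
    normalize_pt,
)

log = logging.getLogger(__name__)

# FAERS AGE_COD units -> years
_AGE_UNIT_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "WK": 7.0 / 365.25, "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0}

_OCCP_MAP = {"MD": "health_professional", "PH": "health_professional",
             "OT": "health_professional", "HP": "health_professional",
             "RN": "health_professional", "CN": "consumer"}

_JADER_SEX = {"男性": "male", "女性": "female"}
_JADER_ROLE = {"被疑薬": "PS", "併用薬": "C", "相互作用": "I"}


def _read_dollar(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")


def _to_float(s):
    try:
        v = float(s)
    except (TypeError, ValueError):
        return np.nan
    return v if np.isfinite(v) else np.nan


def _faers_age_years(age, age_cod):
    v = _to_float(age)
    if np.isnan(v):
        return np.nan
    unit = (age_cod or "YR").strip().upper() or "YR"
    years = v * _AGE_UNIT_YEARS.get(unit, 1.0)
    return years if years >= 0 else np.nan


def _faers_weight_kg(wt, wt_cod):
    v = _to_float(wt)
    if np.isnan(v) or v < 0:
        return np.nan
    unit = (wt_cod or "KG").strip().upper() or "KG"
    if unit in {"LBS", "LB"}:
        v *= 0.45359237
    return v


def read_faers_quarter(paths: dict) -> Corpus:
    """Read one FAERS quarter from per-table file paths.

    Parameters
    ----------
    paths
        Mapping with keys ``demo``, ``drug``, ``reac`` (required) and
        optionally ``ther``, ``indi``, ``outc``, each a path to the
        ``$``-delimited ASCII file.

    Returns a raw (not yet deduplicated) Corpus.  Malformed rows are
    skipped and counted in ``corpus.audit["skipped_rows"]``.
    """
    for required in ("demo", "drug", "reac"):
        if required not in paths:
            raise FileNotFoundError(f"required FAERS table missing: {required.upper()}")

    skipped = 0
    demo = _read_dollar(paths["demo"])
    reports = []
    for _, row in demo.iterrows():
        rid = str(row.get("PRIMARYID", "")).strip()
        if not rid:
            skipped += 1
            continue
        fda = parse_date(row.get("FDA_DT"))
        evt = parse_date(row.get("EVENT_DT"))
        sex = {"F": "female", "M": "male"}.get(str(row.get("SEX", "")).strip().upper(), "unknown")
        reports.append({
            "report_id": rid,
            "case_id": str(row.get("CASEID", rid)).strip() or rid,
            "receipt_date": fda.date,
            "receipt_precision": fda.precision,
            "event_date": evt.date,
            "event_precision": evt.precision,
            "sex": sex,
            "age_value": _faers_age_years(row.get("AGE"), row.get("AGE_COD")),
            "age_raw": str(row.get("AGE", "")).strip(),
            "weight_kg": _faers_weight_kg(row.get("WT"), row.get("WT_COD")),
            "country": str(row.get("OCCR_COUNTRY", "")).strip() or None,
            "reporter": _OCCP_MAP.get(str(row.get("OCCP_COD", "")).strip().upper(), "unknown"),
            "outcomes": frozenset(),
            "indications": (),
        })
    reports_df = pd.DataFrame(reports, columns=REPORT_COLUMNS)

    drugs = []
    ther = _read_dollar(paths["ther"]) if "ther" in paths else None
    ther_by_key: dict = {}
    if ther is not None:
        for _, row in ther.iterrows():
            key = (str(row.get("PRIMARYID", "")).strip(), str(row.get("DSG_DRUG_SEQ", row.get("DRUG_SEQ", ""))).strip())
            ther_by_key.setdefault(key, row)
    for _, row in _read_dollar(paths["drug"]).iterrows():
        rid = str(row.get("PRIMARYID", "")).strip()
        name = str(row.get("DRUGNAME", "")).strip()
        role = str(row.get("ROLE_COD", "")).strip().upper()
        if not rid or not name or role not in {"PS", "SS", "C", "I"}:
            skipped += 1
            continue
        seq = str(row.get("DRUG_SEQ", "")).strip()
        trow = ther_by_key.get((rid, seq))
        start = parse_date(trow.get("START_DT")) if trow is not None else parse_date(None)
        end = parse_date(trow.get("END_DT")) if trow is not None else parse_date(None)
        drugs.append({
            "report_id": rid, "drug_seq": int(seq) if seq.isdigit() else -1,
            "role": role, "drug_name": name,
            "start_date": start.date, "start_precision": start.precision,
            "end_date": end.date, "end_precision": end.precision,
        })
    drugs_df = pd.DataFrame(drugs, columns=DRUG_COLUMNS)

    reactions = []
    event_by_rid = dict(zip(reports_df["report_id"], zip(reports_df["event_date"], reports_df["event_precision"])))
    for _, row in _read_dollar(paths["reac"]).iterrows():
        rid = str(row.get("PRIMARYID", "")).strip()
        pt = normalize_pt(row.get("PT", ""))
        if not rid or not pt:
            skipped += 1
            continue
        # FAERS carries the event date on DEMO; copy it here so TTO logic
        # is source-agnostic.
        evt_date, evt_prec = event_by_rid.get(rid, (None, MISSING))
        reactions.append({"report_id": rid, "pt": pt,
                          "event_date": evt_date, "event_precision": evt_prec})
    reactions_df = pd.DataFrame(reactions, columns=REACTION_COLUMNS)

    if "outc" in paths:
        outc_sets: dict = {}
        for _, row in _read_dollar(paths["outc"]).iterrows():
            rid = str(row.get("PRIMARYID", "")).strip()
            code = str(row.get("OUTC_COD", "")).strip().upper()
            if rid and code:
                outc_sets.setdefault(rid, set()).add(OUTCOME_CODES.get(code, "unknown"))
        reports_df["outcomes"] = reports_df["report_id"].map(
            lambda r: frozenset(outc_sets.get(r, ())))
    if "indi" in paths:
        indi_lists: dict = {}
        for _, row in _read_dollar(paths["indi"]).iterrows():
            rid = str(row.get("PRIMARYID", "")).strip()
            pt = normalize_pt(row.get("INDI_PT", row.get("PT", "")))
            if rid and pt:
                indi_lists.setdefault(rid, []).append(pt)
        reports_df["indications"] = reports_df["report_id"].map(
            lambda r: tuple(indi_lists.get(r, ())))

    if skipped:
        log.warning("read_faers_quarter: skipped %d malformed rows", skipped)
    corpus = Corpus(reports_df, drugs_df, reactions_df, source="FAERS",
                    audit={"skipped_rows": skipped})
    # child rows whose report is absent from DEMO are dropped, counted
    ids = set(reports_df["report_id"])
    orphan = (~drugs_df["report_id"].isin(ids)).sum() + (~reactions_df["report_id"].isin(ids)).sum()
    if orphan:
        corpus.audit["orphan_rows"] = int(orphan)
        corpus.drugs = drugs_df[drugs_df["report_id"].isin(ids)].reset_index(drop=True)
        corpus.reactions = reactions_df[reactions_df["report_id"].isin(ids)].reset_index(drop=True)
    return corpus


def jader_age_to_years(age_raw: str, midpoint_offset: float = 5.0):
    """Convert a JADER age string to years.

    Decade strings like ``60歳代`` (the 60–69 band) map to the band's
    midpoint, by default lower bound + 5 → 65.  Plain numeric ages
    (``45歳``) parse directly.  Non-numeric categories (neonatal,
    infant, adult, elderly, gestational stages, unknown) map to NaN.
    """
    s = str(age_raw).strip()
    if not s:
        return np.nan
    if s.endswith("歳代"):
        head = s[:-2]
        if head.isdigit():
            return float(head) + midpoint_offset
        return np.nan
    if s.endswith("歳"):
        head = s[:-1]
        if head.isdigit():
            return float(head)
    if s.isdigit():
        return float(s)
    return np.nan


def _read_jader_csv(path, encoding: str):
    encodings = [encoding, "utf-8"] if encoding != "utf-8" else ["utf-8"]
    last_err = None
    for enc in encodings:
        try:
            return pd.read_csv(path, dtype=str, keep_default_na=False, encoding=enc)
        except (UnicodeDecodeError, UnicodeError) as err:
            last_err = err
    raise UnicodeDecodeError(*last_err.args) if isinstance(last_err, UnicodeDecodeError) else last_err


def read_jader(paths: dict, encoding: str = "shift_jis") -> Corpus:
    """Read a JADER file set (CSV: demo, drug, reac; hist optional)."""
    for required in ("demo", "drug", "reac"):
        if required not in paths:
            raise FileNotFoundError(f"required JADER table missing: {required.upper()}")

    demo = _read_jader_csv(paths["demo"], encoding)
    reports = []
    for _, row in demo.iterrows():
        rid = str(row.get("識別番号", "")).strip()
        if not rid:
            continue
        age_raw = str(row.get("年齢", "")).strip()
        wt_raw = str(row.get("体重", "")).strip()
        wt = np.nan
        digits = wt_raw.replace("kg", "").replace("ｋｇ", "").strip()
        # JADER weight comes in 10-kg bands like "60kg代"; use the midpoint
        if digits.endswith("代") and digits[:-1].isdigit():
            wt = float(digits[:-1]) + 5.0
        elif digits.replace(".", "", 1).isdigit():
            wt = float(digits)
        outcome = str(row.get("転帰", "")).strip()
        reports.append({
            "report_id": rid, "case_id": rid,
            "receipt_date": None, "receipt_precision": MISSING,
            "event_date": None, "event_precision": MISSING,
            "sex": _JADER_SEX.get(str(row.get("性別", "")).strip(), "unknown"),
            "age_value": jader_age_to_years(age_raw),
            "age_raw": age_raw,
            "weight_kg": wt,
            "country": "Japan",
            "reporter": "unknown",
            "outcomes": frozenset({outcome}) if outcome else frozenset(),
            "indications": (),
        })
    reports_df = pd.DataFrame(reports, columns=REPORT_COLUMNS)

    drugs = []
    for i, row in _read_jader_csv(paths["drug"], encoding).iterrows():
        rid = str(row.get("識別番号", "")).strip()
        name = str(row.get("医薬品（一般名）", "")).strip()
        role = _JADER_ROLE.get(str(row.get("医薬品の関与", "")).strip())
        if not rid or not name or role is None:
            continue
        start = parse_date(row.get("投与開始日"))
        end = parse_date(row.get("投与終了日"))
        drugs.append({
            "report_id": rid, "drug_seq": i + 1, "role": role, "drug_name": name,
            "start_date": start.date, "start_precision": start.precision,
            "end_date": end.date, "end_precision": end.precision,
        })
    drugs_df = pd.DataFrame(drugs, columns=DRUG_COLUMNS)

    reactions = []
    for _, row in _read_jader_csv(paths["reac"], encoding).iterrows():
        rid = str(row.get("識別番号", "")).strip()
        pt = normalize_pt(row.get("有害事象", ""))
        if not rid or not pt:
            continue
        evt = parse_date(row.get("有害事象発現日"))
        reactions.append({"report_id": rid, "pt": pt,
                          "event_date": evt.date, "event_precision": evt.precision})
    reactions_df = pd.DataFrame(reactions, columns=REACTION_COLUMNS)

    ids = set(reports_df["report_id"])
    drugs_df = drugs_df[drugs_df["report_id"].isin(ids)].reset_index(drop=True)
    reactions_df = reactions_df[reactions_df["report_id"].isin(ids)].reset_index(drop=True)
    return Corpus(reports_df, drugs_df, reactions_df, source="JADER")


def _id_sort_key(report_id: str):
    """PRIMARYID tie-break: numeric when both parse as ints, else lexical."""
    s = str(report_id)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def deduplicate_faers(corpus: Corpus) -> Corpus:
    """FDA deduplication: one report per CASEID.

    Keep the report with the latest receipt date per case id; among
    ties, the higher report id (numeric comparison when both ids are
    integers).  Missing receipt dates sort lowest.  Drug/reaction rows
    of dropped reports are removed.  Idempotent and invariant to input
    row order.
    """
    rep = corpus.reports
    if rep.empty:
        out = corpus.subset([])
        out.audit["dedup_removed"] = 0
        return out

    import datetime as _dtmod
    floor = _dtmod.date.min
    key = pd.DataFrame({
        "report_id": rep["report_id"],
        "case_id": rep["case_id"],
        "_date": [d if d is not None else floor for d in rep["receipt_date"]],
        "_idkey": [_id_sort_key(r) for r in rep["report_id"]],
    })
    keep_ids = (
        key.sort_values(["case_id", "_date", "_idkey"])
        .groupby("case_id", sort=False)
        .tail(1)["report_id"]
    )
    out = corpus.subset(keep_ids)
    out.audit["dedup_removed"] = int(len(rep) - len(keep_ids))
    return out


def select_target_reports(
    corpus: Corpus,
    names,
    role_filter=frozenset({"PS"}),
    match: str = "substring",
) -> Corpus:
    """Keep reports with >=1 drug entry matching a target name and role.

    ``match='substring'`` (default): case-insensitive substring after
    trimming — FAERS free-text drug names carry dose/formulation
    suffixes.  ``match='exact'``: case-insensitive whole-field match.
    """
    if not names:
        raise ValueError("names must be non-empty")
    if match not in {"substring", "exact"}:
        raise ValueError(f"unknown match mode {match!r}")
    targets = [str(n).strip().casefold() for n in names]
    role_filter = set(role_filter)

    field = corpus.drugs["drug_name"].astype(str).str.strip().str.casefold()
    if match == "substring":
        name_hit = pd.Series(False, index=field.index)
        for t in targets:
            name_hit |= field.str.contains(t, regex=False)
    else:
        name_hit = field.isin(targets)
    hit = name_hit & corpus.drugs["role"].isin(role_filter)
    keep = corpus.drugs.loc[hit, "report_id"].unique()
    if len(keep) == 0:
        warnings.warn("select_target_reports: no reports matched", stacklevel=2)
    out = corpus.subset(keep)
    out.audit["target_selected"] = int(len(keep))
    return out


def matches_target(drug_name: str, names, match: str = "substring") -> bool:
    """Whether one drug-name field matches any target name."""
    field = str(drug_name).strip().casefold()
    targets = [str(n).strip().casefold() for n in names]
    if match == "substring":
        return any(t in field for t in targets)
    return field in targets
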