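"""Subgroup and sensitivity scans.

Subgroups: sex (female/male) and age (<65 / ≥65 by default); reports
missing the stratification variable are excluded, never misassigned.
By default the comparator background is restricted to the same stratum
(stratified 2×2), which removes stratum-specific reporting propensity.

Sensitivity: the scan rerun on monotherapy reports only — reports whose
every drug entry matches the target-drug name list — to separate
signals attributable to co-medication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import MeddraMap
from .dispro import ScanConfig, run_signal_scan
from .ingest import matches_target
from .model import Corpus


@dataclass
class StratumSpec:
    """Named disjoint levels over the report table."""

    variable: str
    levels: dict = field(default_factory=dict)  # name -> predicate(reports df) -> bool mask


def sex_strata() -> StratumSpec:
    return StratumSpec("sex", {
        "female": lambda rep: rep["sex"] == "female",
        "male": lambda rep: rep["sex"] == "male",
    })


def age_strata(boundary: float = 65.0) -> StratumSpec:
    return StratumSpec("age", {
        f"<{boundary:g}": lambda rep: rep["age_value"].astype(float) < boundary,
        f">={boundary:g}": lambda rep: rep["age_value"].astype(float) >= boundary,
    })


def subgroup_scan(
    corpus: Corpus,
    meddra: MeddraMap | None,
    target_report_ids,
    spec: StratumSpec,
    level: str = "pt",
    top_k: int = 15,
    config: ScanConfig | None = None,
    background: str = "stratified",
) -> dict:
    """Per-level ranked positive-signal lists.

    Returns ``{level_name: DataFrame}`` where each frame is the full
    within-stratum scan with ``rank`` set on the top_k composite-positive
    terms (by a, descending) and stratum columns attached.
    """
    if background not in {"stratified", "global"}:
        raise ValueError("background must be 'stratified' or 'global'")
    targets = set(target_report_ids)
    results = {}
    for name, predicate in spec.levels.items():
        mask = predicate(corpus.reports).fillna(False).astype(bool)
        level_ids = set(corpus.reports.loc[mask, "report_id"])
        bg = corpus.subset(level_ids) if background == "stratified" else corpus
        level_targets = targets & level_ids
        if not level_targets:
            warnings.warn(f"stratum {spec.variable}={name}: no target reports", stacklevel=2)
            results[name] = pd.DataFrame()
            continue
        scan = run_signal_scan(bg, meddra, level_targets, level=level, config=config)
        scan = scan.copy()
        scan["stratum_variable"] = spec.variable
        scan["stratum_level"] = name
        scan["rank"] = np.nan
        pos = scan.index[scan["all_four_pos"]][:top_k]
        scan.loc[pos, "rank"] = np.arange(1, len(pos) + 1)
        results[name] = scan
    return results


def stratum_specific_terms(results: dict) -> dict:
    """Set-difference report: composite-positive terms unique to each level."""
    positives = {
        name: set(df.loc[df.get("all_four_pos", pd.Series(dtype=bool)).fillna(False), "term"])
        if not df.empty else set()
        for name, df in results.items()
    }
    return {
        name: terms - set().union(*(v for k, v in positives.items() if k != name))
        for name, terms in positives.items()
    }


def monotherapy_report_ids(corpus: Corpus, target_names, match: str = "substring"):
    """Reports whose every drug entry matches a target name."""
    is_target_name = corpus.drugs["drug_name"].map(
        lambda n: matches_target(n, target_names, match=match))
    bad = set(corpus.drugs.loc[~is_target_name, "report_id"])
    return [r for r in corpus.reports["report_id"] if r not in bad]


def sensitivity_scan(
    corpus: Corpus,
    meddra: MeddraMap | None,
    target_report_ids,
    target_names,
    level: str = "pt",
    config: ScanConfig | None = None,
    match: str = "substring",
) -> pd.DataFrame:
    """Rerun the scan after excluding co-medicated target reports."""
    mono = set(monotherapy_report_ids(corpus, target_names, match=match))
    retained = set(target_report_ids) & mono
    scan = run_signal_scan(corpus, meddra, retained, level=level, config=config)
    scan = scan.copy()
    scan["analysis"] = "sensitivity"
    scan.attrs["n_retained"] = len(retained)
    scan.attrs["n_excluded"] = len(set(target_report_ids)) - len(retained)
    return scan
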