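"""PT→SOC mapping and demographic summary tables.

MedDRA itself is proprietary, so the mapping is supplied by the user as
a 4-column tab-delimited file (``pt``, ``pt_code``, ``soc``,
``soc_code``).  PTs absent from the dictionary are routed to a sentinel
``UNMAPPED`` class and counted rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Corpus, normalize_pt

UNMAPPED_SOC = "UNMAPPED"
UNMAPPED_CODE = -1


@dataclass
class MeddraMap:
    """PT → (pt_code, soc, soc_code) lookup, keys normalized like reaction PTs."""

    entries: dict

    @classmethod
    def from_file(cls, path) -> "MeddraMap":
        df = pd.read_csv(path, sep="\t", dtype={"pt": str, "soc": str})
        required = {"pt", "pt_code", "soc", "soc_code"}
        if not required.issubset(df.columns):
            raise ValueError(f"dictionary file needs columns {sorted(required)}")
        entries = {
            normalize_pt(r.pt): (int(r.pt_code), str(r.soc), int(r.soc_code))
            for r in df.itertuples()
        }
        return cls(entries)

    def lookup(self, pt: str):
        return self.entries.get(normalize_pt(pt), (UNMAPPED_CODE, UNMAPPED_SOC, UNMAPPED_CODE))

    def socs(self):
        return sorted({soc for _, soc, _ in self.entries.values()})


def map_pt_to_soc(corpus: Corpus, meddra: MeddraMap):
    """Annotate the reaction table with SOC names/codes.

    Returns ``(annotated reactions DataFrame, n_unmapped)`` where
    ``n_unmapped`` counts distinct unmapped PTs.
    """
    reac = corpus.reactions.copy()
    looked = [meddra.lookup(pt) for pt in reac["pt"]]
    reac["pt_code"] = [t[0] for t in looked]
    reac["soc"] = [t[1] for t in looked]
    reac["soc_code"] = [t[2] for t in looked]
    n_unmapped = reac.loc[reac["soc"] == UNMAPPED_SOC, "pt"].nunique()
    return reac, int(n_unmapped)


# ---------------------------------------------------------------------------
# demographics

FAERS_AGE_BINS = (("<18 years", 0.0, 18.0), ("18-64 years", 18.0, 65.0), (">=65 years", 65.0, np.inf))
JADER_AGE_BINS = (("<65 years", 0.0, 65.0), (">=65 years", 65.0, np.inf))
WEIGHT_BINS = (("<50 kg", 0.0, 50.0), ("50-100 kg", 50.0, 100.0 + 1e-9), (">100 kg", 100.0 + 1e-9, np.inf))


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 1) if total else 0.0


def _bin_counts(values, bins, total):
    """Left-closed binning; values failing every bin go to 'Unknown'."""
    rows = []
    assigned = np.zeros(len(values), dtype=bool)
    arr = np.asarray(values, dtype=float)
    for label, lo, hi in bins:
        inbin = (~np.isnan(arr)) & (arr >= lo) & (arr < hi)
        rows.append((label, int(inbin.sum())))
        assigned |= inbin
    rows.append(("Unknown", int((~assigned).sum())))
    return [(label, n, _pct(n, total)) for label, n in rows]


def summarize_demographics(corpus: Corpus, bin_scheme: str | None = None, top_k: int = 5) -> dict:
    """Per-variable category counts and percentages for a report corpus.

    ``bin_scheme`` is ``"faers"`` (<18 / 18–64 / ≥65) or ``"jader"``
    (<65 / ≥65); defaults to the corpus source.  Percentages are against
    the corpus report count, rounded to one decimal.
    """
    scheme = (bin_scheme or corpus.source).lower()
    age_bins = FAERS_AGE_BINS if scheme == "faers" else JADER_AGE_BINS
    rep = corpus.reports
    total = len(rep)

    summary: dict = {"n_reports": total}

    sex_counts = rep["sex"].value_counts() if total else pd.Series(dtype=int)
    summary["sex"] = [
        (label.capitalize(), int(sex_counts.get(label, 0)), _pct(int(sex_counts.get(label, 0)), total))
        for label in ("female", "male", "unknown")
    ]
    summary["age"] = _bin_counts(rep["age_value"].to_numpy(dtype=float) if total else [], age_bins, total)
    summary["weight"] = _bin_counts(rep["weight_kg"].to_numpy(dtype=float) if total else [], WEIGHT_BINS, total)

    countries = rep["country"].dropna() if total else pd.Series(dtype=str)
    summary["countries_top"] = [
        (c, int(n), _pct(int(n), total)) for c, n in countries.value_counts().head(top_k).items()
    ]
    rep_counts = rep["reporter"].value_counts() if total else pd.Series(dtype=int)
    summary["reporter"] = [
        (label, int(rep_counts.get(label, 0)), _pct(int(rep_counts.get(label, 0)), total))
        for label in ("health_professional", "consumer", "unknown")
    ]
    outc: dict = {}
    if total:
        for s in rep["outcomes"]:
            for o in s:
                outc[o] = outc.get(o, 0) + 1
    summary["outcomes"] = sorted(
        ((o, n, _pct(n, total)) for o, n in outc.items()), key=lambda t: -t[1])
    indi: dict = {}
    if total:
        for lst in rep["indications"]:
            for pt in lst:
                indi[pt] = indi.get(pt, 0) + 1
    summary["indications_top"] = sorted(
        ((p, n, _pct(n, total)) for p, n in indi.items()), key=lambda t: -t[1])[:top_k]
    return summary


def demographics_table(summary: dict) -> pd.DataFrame:
    """Flatten a summary dict into a long table (variable, category, n, pct)."""
    rows = []
    for var in ("sex", "age", "weight", "countries_top", "reporter", "outcomes", "indications_top"):
        for cat, n, pct in summary.get(var, []):
            rows.append({"variable": var, "category": cat, "n": n, "pct": pct})
    return pd.DataFrame(rows, columns=["variable", "category", "n", "pct"])
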