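"""In-memory containers for spontaneous-report corpora.

A :class:`Corpus` holds three aligned pandas DataFrames mirroring the
relational layout of FAERS/JADER: one row per report (demographics and
receipt metadata), one row per drug entry, one row per reaction entry.
Downstream statistics never touch the raw files; they consume a Corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: columns of Corpus.reports
REPORT_COLUMNS = [
    "report_id", "case_id", "receipt_date", "receipt_precision",
    "event_date", "event_precision", "sex", "age_value", "age_raw",
    "weight_kg", "country", "reporter", "outcomes", "indications",
]

#: columns of Corpus.drugs
DRUG_COLUMNS = [
    "report_id", "drug_seq", "role", "drug_name",
    "start_date", "start_precision", "end_date", "end_precision",
]

#: columns of Corpus.reactions
REACTION_COLUMNS = ["report_id", "pt", "event_date", "event_precision"]

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

SEX_VALUES = ("female", "male", "unknown")

OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other_serious",
}


def normalize_pt(pt: str) -> str:
    """Canonical PT form: case-folded, whitespace-trimmed."""
    return str(pt).strip().casefold()


@dataclass
class Corpus:
    """One spontaneous-report corpus (FAERS or JADER dialect)."""

    reports: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    source: str  # "FAERS" | "JADER"
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df, cols in ((self.reports, REPORT_COLUMNS),
                         (self.drugs, DRUG_COLUMNS),
                         (self.reactions, REACTION_COLUMNS)):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"corpus table missing columns {missing}")

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def validate(self) -> None:
        """Referential integrity: child tables resolve to a report."""
        ids = set(self.reports["report_id"])
        for name, df in (("drugs", self.drugs), ("reactions", self.reactions)):
            orphans = set(df["report_id"]) - ids
            if orphans:
                raise ValueError(
                    f"{name} table has {len(orphans)} entries with unknown report_id"
                )
        if self.reports["report_id"].duplicated().any():
            raise ValueError("duplicate report_id in reports table")

    def subset(self, report_ids) -> "Corpus":
        """Restrict all three tables to the given report ids."""
        keep = set(report_ids)
        return Corpus(
            reports=self.reports[self.reports["report_id"].isin(keep)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["report_id"].isin(keep)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["report_id"].isin(keep)].reset_index(drop=True),
            source=self.source,
            audit=dict(self.audit),
        )


def empty_corpus(source: str = "FAERS") -> Corpus:
    return Corpus(
        reports=pd.DataFrame(columns=REPORT_COLUMNS),
        drugs=pd.DataFrame(columns=DRUG_COLUMNS),
        reactions=pd.DataFrame(columns=REACTION_COLUMNS),
        source=source,
    )
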