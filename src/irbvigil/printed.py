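"""Published SOC-level signal tables for the irbesartan scans.

The package ships, as plain TSV data, the SOC-level disproportionality
statistics published for irbesartan in FAERS and JADER.  Re-applying
the positivity rules to those printed statistics checks the threshold
logic against the published SOC-level calls without access to the raw
databases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dispro import evaluate_thresholds


def load_soc_table(database: str) -> pd.DataFrame:
    """Published SOC-level statistics; ``database`` is 'faers' or 'jader'."""
    name = {"faers": "faers_soc_signals.tsv", "jader": "jader_soc_signals.tsv"}.get(database.lower())
    if name is None:
        raise ValueError("database must be 'faers' or 'jader'")
    with resources.files("irbvigil.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def apply_thresholds(table: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Attach the four positivity flags to a printed statistics table."""
    out = table.copy()
    flags = [
        evaluate_thresholds(r.n, r.ror_lo95, r.prr, r.chi2, r.ic025, r.ebgm05,
                            min_count=min_count)
        for r in table.itertuples()
    ]
    for key in ("ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "all_four_pos"):
        out[key] = [f[key] for f in flags]
    return out
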