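#!/usr/bin/env python
"""Ingest the simulated FAERS set, deduplicate, and run the full scan.

Reads the file set written by 01_simulate.py, applies the FDA
case-level deduplication rule, selects primary-suspect target-drug
reports, and computes all four disproportionality statistics (ROR,
PRR+chi2, BCPNN IC, MGPS EBGM) with the four-way positivity rule at
both PT and SOC level.  Writes the signal tables and the demographic
summary under results/scan/.
"""

import argparse
from pathlib import Path

from irbvigil.cohort import MeddraMap, demographics_table, summarize_demographics
from irbvigil.dispro import run_signal_scan
from irbvigil.ingest import deduplicate_faers, read_faers_quarter, select_target_reports


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/scan"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    paths = {k: args.sim / "faers" / f"{k.upper()}.txt"
             for k in ("demo", "drug", "reac", "ther", "outc")}
    corpus = deduplicate_faers(read_faers_quarter(paths))
    print(f"ingested {corpus.n_reports} reports after removing "
          f"{corpus.audit['dedup_removed']} duplicates")

    target = select_target_reports(corpus, ["IRBESARTAN"])
    print(f"{target.n_reports} reports name the target drug as primary suspect")

    demographics_table(summarize_demographics(target)).to_csv(
        args.out / "demographics.tsv", sep="\t", index=False)

    meddra = MeddraMap.from_file(args.sim / "meddra.tsv")
    target_ids = set(target.reports["report_id"])
    for level in ("pt", "soc"):
        scan = run_signal_scan(corpus, meddra, target_ids, level=level)
        scan.to_csv(args.out / f"signals_{level}.tsv", sep="\t", index=False)
        pos = scan.loc[scan["all_four_pos"], "term"].tolist()
        print(f"{level.upper()} level: {len(scan)} terms scanned, "
              f"{len(pos)} composite-positive: {pos}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
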