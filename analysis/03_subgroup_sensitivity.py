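#!/usr/bin/env python
"""Subgroup scans by sex and age, and the monotherapy sensitivity scan.

Reruns the disproportionality scan inside each stratum (comparator
background restricted to the stratum) and after excluding reports with
any non-target drug entry.  Writes the per-stratum ranked signal lists
and the sensitivity table under results/strata/.
"""

import argparse
from pathlib import Path

from irbvigil.cohort import MeddraMap
from irbvigil.ingest import deduplicate_faers, read_faers_quarter, select_target_reports
from irbvigil.strata import (
    age_strata,
    sensitivity_scan,
    sex_strata,
    stratum_specific_terms,
    subgroup_scan,
)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/strata"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    paths = {k: args.sim / "faers" / f"{k.upper()}.txt"
             for k in ("demo", "drug", "reac", "ther")}
    corpus = deduplicate_faers(read_faers_quarter(paths))
    target = select_target_reports(corpus, ["IRBESARTAN"])
    target_ids = set(target.reports["report_id"])
    meddra = MeddraMap.from_file(args.sim / "meddra.tsv")

    for spec in (sex_strata(), age_strata()):
        results = subgroup_scan(corpus, meddra, target_ids, spec, top_k=15)
        specific = stratum_specific_terms(results)
        for name, df in results.items():
            safe = name.replace("<", "lt").replace(">=", "ge")
            df.to_csv(args.out / f"subgroup_{spec.variable}_{safe}.tsv",
                      sep="\t", index=False)
            n_pos = int(df["all_four_pos"].sum()) if not df.empty else 0
            print(f"{spec.variable}={name}: {len(df)} terms, {n_pos} positive, "
                  f"stratum-specific: {sorted(specific[name])}")

    sens = sensitivity_scan(corpus, meddra, target_ids, ["IRBESARTAN"])
    sens.to_csv(args.out / "sensitivity_pt.tsv", sep="\t", index=False)
    persistent = sens.loc[sens["all_four_pos"], "term"].tolist()
    print(f"sensitivity (monotherapy only): kept {sens.attrs['n_retained']} of "
          f"{sens.attrs['n_retained'] + sens.attrs['n_excluded']} target reports; "
          f"persistent positives: {persistent}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
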