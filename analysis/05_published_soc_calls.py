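#!/usr/bin/env python
"""Re-apply the positivity rules to the published SOC-level tables.

The package ships the SOC-level statistics published for irbesartan in
FAERS and JADER.  This driver re-derives every SOC-level call from
those printed numbers: which SOCs pass the ROR threshold in each
database, which pass it in both, and which pass all four methods at
once.  Writes the flagged tables under results/published/.
"""

import argparse
from pathlib import Path

from irbvigil.printed import apply_thresholds, load_soc_table


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/published"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    flagged = {}
    for db in ("faers", "jader"):
        table = apply_thresholds(load_soc_table(db))
        table.to_csv(args.out / f"{db}_soc_flags.tsv", sep="\t", index=False)
        flagged[db] = table
        ror_pos = table.loc[table["ror_pos"], "soc"].tolist()
        all4 = table.loc[table["all_four_pos"], "soc"].tolist()
        print(f"{db.upper()}: {len(table)} SOCs, {len(ror_pos)} ROR-positive "
              f"({', '.join(ror_pos)}); all-four-positive: {all4}")

    both = (set(flagged["faers"].loc[flagged["faers"]["ror_pos"], "soc"])
            & set(flagged["jader"].loc[flagged["jader"]["ror_pos"], "soc"]))
    print(f"ROR-positive in both databases ({len(both)}): {sorted(both)}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
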