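#!/usr/bin/env python
"""Generate the synthetic FAERS-like and JADER-like study file sets.

Writes two raw file sets with known ground truth under results/sim/:
a FAERS dialect set with one strong injected drug-event association
(relative risk 10) plus duplicate case ids to exercise deduplication,
and a JADER dialect set with Japanese role labels and decade age
strings.  A synthetic PT->SOC dictionary accompanies them.
"""

import argparse
import json
from pathlib import Path

from irbvigil.synthdata import SimConfig, generate_corpus, generate_meddra_fixture


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-reports", type=int, default=4000)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    faers_cfg = SimConfig(
        n_reports=args.n_reports, seed=args.seed, target_share=0.15,
        duplicate_rate=0.08,
        injected_signals=(("IRBESARTAN", "pt_005", 10.0),),
    )
    paths_f, truth_f = generate_corpus(faers_cfg, args.out / "faers", dialect="faers")
    print(f"FAERS dialect: {faers_cfg.n_reports} reports "
          f"(+{truth_f['n_duplicates']} duplicate case ids), "
          f"{truth_f['n_target_reports']} exposed to the target drug; "
          f"injected pt_005 at RR 10 -> {truth_f['target_pt_counts'].get('pt_005', 0)} "
          "target reports carry it")

    jader_cfg = SimConfig(
        n_reports=max(args.n_reports // 10, 300), seed=args.seed + 1,
        target_share=0.15, duplicate_rate=0.0,
        injected_signals=(("IRBESARTAN", "pt_003", 8.0),),
    )
    paths_j, truth_j = generate_corpus(jader_cfg, args.out / "jader", dialect="jader")
    print(f"JADER dialect: {jader_cfg.n_reports} reports, "
          f"{truth_j['n_target_reports']} exposed")

    meddra = generate_meddra_fixture(200, 27, args.seed, args.out / "meddra.tsv")
    print(f"synthetic dictionary: 200 PTs over 27 SOCs -> {meddra}")

    manifest = {
        "seed": args.seed,
        "faers": {k: str(v) for k, v in paths_f.items()},
        "jader": {k: str(v) for k, v in paths_j.items()},
        "meddra": str(meddra),
    }
    (args.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
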