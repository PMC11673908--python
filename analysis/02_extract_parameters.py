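#!/usr/bin/env python
"""Extract the 15 cyclogram parameters for every dataset of the study.

Each dataset's ten marker clusters yield the geometry parameters (gait line
AE, single-support line BD, marker positions, distances AB/BC/CD/DE, ratios
Ra and Rp) and the raw Balance Index. The demo recordings additionally run
the full event-detection -> cyclogram -> marker pipeline.

Reads results/study/; writes results/parameters.csv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cyclogait.cli import run_extract  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    out, failures = run_extract(args.results / "study" / "manifest.csv", args.results / "parameters.csv")
    table = pd.read_csv(out)
    print(f"parameter table: {len(table)} datasets, {failures} failures -> {out}")
    med = table.groupby("cohort")[["AB", "BC", "Ra", "BI"]].median().round(4)
    print("cohort medians:\n", med)

    rec_manifest = args.results / "study_recordings" / "manifest.csv"
    if rec_manifest.exists():
        out2, f2 = run_extract(rec_manifest, args.results / "parameters_recordings.csv")
        print(f"full-pipeline demo recordings -> {out2} ({f2} failures)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
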