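#!/usr/bin/env python
"""Evaluate the 15 parameters as diabetic-neuropathy classifiers.

For every parameter: cohort medians, Mann-Whitney U and p, separation S,
rank effect size r = 1 - 2S with its label, AUC = 1 - S, and — for large
effects only (r > 0.37) — the optimal threshold at max sqrt(TPR*TNR) with
the confusion percentages. The Balance Index is first rescaled so its
optimal threshold sits at 100.

Reads results/parameters.csv; writes results/comparison.json/.csv.
"""

import argparse
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cyclogait.cli import RunConfig, run_compare  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_compare(
            args.results / "parameters.csv",
            args.results / "comparison.json",
            RunConfig(calibrate_bi=True),
        )
    comp = pd.DataFrame(report["comparison"]).set_index("parameter")
    print(f"BI scale constant: {report['bi_scale']:.1f} (optimal BI threshold -> 100)")
    cols = ["median_D", "median_H", "r", "effect", "AUC", "THR", "FN_pct", "FP_pct"]
    print(comp[cols].to_string())
    best = comp.sort_values("AUC", ascending=False).head(3)
    print("\nbest classifiers by AUC:", ", ".join(best.index))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
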