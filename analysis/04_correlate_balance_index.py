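#!/usr/bin/env python
"""Correlate the geometry parameters with the (log) Balance Index.

The geometry parameters describe walking style; the BI, built from marker
scatter, describes balance. Their shared variance measures how much of the
geometric collapse travels with imbalance. Each of the 14 geometry
parameters is regressed against log10(BI) (Ra itself log-transformed, as a
ratio spanning an order of magnitude).

Reads results/parameters.csv; writes results/bi_correlations.csv.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cyclogait import correlate_with_bi  # noqa: E402
from cyclogait.parameters import PARAM_NAMES  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = pd.read_csv(args.results / "parameters.csv")
    bi = table["BI"].to_numpy()
    rows = []
    for name in PARAM_NAMES[:-1]:
        vals = table[name].to_numpy()
        tx = "log10" if name == "Ra" and np.all(vals > 0) else "identity"
        try:
            res = correlate_with_bi(vals, bi, transform=(tx, "log10"))
        except ValueError as exc:
            print(f"{name}: skipped ({exc})")
            continue
        rows.append({"parameter": name, "transform": tx, "R2": res.r_squared,
                     "slope": res.slope, "p": res.p})
    out = pd.DataFrame(rows).sort_values("R2", ascending=False)
    path = args.results / "bi_correlations.csv"
    out.to_csv(path, index=False, float_format="%.4g")
    print(out.head(5).to_string(index=False))
    print(f"\ntop correlates of log10(BI): {', '.join(out.head(3)['parameter'])} -> {path}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
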