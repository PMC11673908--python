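#!/usr/bin/env python
"""Generate the synthetic two-cohort insole study.

Emulates the study conditions: 56 diabetic-neuropathy and 70 healthy
datasets (126 total) over 14/15 participants, 12 consecutive steps per
dataset at 50 Hz. Marker-level data (fast mode) drive the cohort analysis;
two full time-series recordings are also written for illustration and QC.

Writes results/study/ (marker manifest) and results/study_recordings/.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cyclogait import StudySpec  # noqa: E402
from cyclogait.cli import run_simulate  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    spec = StudySpec()
    manifest = run_simulate(args.out / "study", spec=spec, seed=args.seed, mode="markers")
    print(f"marker-level study: {spec.n_diabetic} D + {spec.n_healthy} H datasets -> {manifest}")

    demo_spec = StudySpec(n_diabetic=1, n_healthy=1, participants_diabetic=1, participants_healthy=1)
    rec_manifest = run_simulate(
        args.out / "study_recordings", spec=demo_spec, seed=args.seed, mode="recordings"
    )
    print(f"demo 50 Hz recordings (one per cohort)  -> {rec_manifest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
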