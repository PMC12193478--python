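#!/usr/bin/env python
"""Simulate the study-scale cohort: 19 older adults, two walks each.

Writes the cohort table to results/tables/cohort.csv and the bulky
per-trial keypoint JSON streams to scratch/study_data/keypoints/ (runtime
data, not part of the deliverable tree).  Downstream drivers start from
these files, mirroring an analysis that would start from camera exports.
"""

import argparse
from pathlib import Path

from gaitvar import CohortSimConfig, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--subjects", type=int, default=19)
    args = parser.parse_args()

    config = CohortSimConfig(n_subjects=args.subjects, seed=args.seed)
    result = simulate_cohort(config)

    data_dir = ROOT / "scratch" / "study_data"
    write_cohort(result, data_dir)
    tables = ROOT / "results" / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(tables / "cohort.csv", index=False)

    durations = result.cohort[["duration1", "duration2", "duration"]].mean()
    print(f"simulated {len(result.cohort)} subjects (seed {args.seed})")
    print(f"keypoint JSON trials -> {data_dir / 'keypoints'}")
    print(f"cohort table        -> {tables / 'cohort.csv'}")
    print("mean durations (s): "
          f"trial 2.1 = {durations['duration1']:.2f}, "
          f"trial 2.2 = {durations['duration2']:.2f}, "
          f"total = {durations['duration']:.2f}")
    print("trial 1 runs longer than trial 2, as expected from the "
          "adaptation offset built into the generator.")


if __name__ == "__main__":
    main()
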