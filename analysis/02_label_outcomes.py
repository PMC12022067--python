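#!/usr/bin/env python
"""Label cognitive decline and trajectory categories.

Applies the >= 3-point MoCA drop rule (year 2 and/or year 4) to the
simulated cohort, classifies the four longitudinal trajectory patterns, and
writes the labeled cohort plus a category frequency table (the pie-chart
style summary) under results/.
"""

import json
from pathlib import Path

from cogdecline import label_cohort
from cogdecline.io import read_cohort, schema_for_config, write_cohort
from cogdecline.outcomes import category_frequencies
from cogdecline.synthetic import load_config

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = load_config(RESULTS / "cohort_config.yaml")
    cohort = read_cohort(RESULTS / "cohort.csv",
                         schema=schema_for_config(config))
    labeled = label_cohort(cohort)
    write_cohort(labeled, RESULTS / "cohort_labeled.csv")
    freq = category_frequencies(labeled)
    with open(RESULTS / "trajectory_frequencies.json", "w") as fh:
        json.dump(freq, fh, indent=2)
    rate = labeled["decline"].mean()
    print(f"{int(labeled['decline'].sum())}/{len(labeled)} subjects "
          f"({100 * rate:.0f}%) show cognitive decline")
    for cat, pct in freq["percent"].items():
        print(f"  {cat:<14s} {freq['counts'][cat]:>4d}  ({pct:.0f}%)")
    agree = (labeled["decline"] == labeled["sim_decline"]).mean()
    print(f"label consistency vs generator ground truth: {100 * agree:.1f}%")


if __name__ == "__main__":
    main()
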