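#!/usr/bin/env python
"""Fit the prognostic model on the labeled cohort.

Runs the full pipeline — LR estimation, qualification, Jaccard redundancy
filtering, LRTS backward elimination, age-bracket prior estimation — and
writes the fitted model JSON plus the elimination trace.  For comparison,
prints the packaged published model's likelihood ratios side by side.
"""

from pathlib import Path

from cogdecline import fit_model, published_model
from cogdecline.io import read_cohort, schema_for_config
from cogdecline.synthetic import load_config

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = load_config(RESULTS / "cohort_config.yaml")
    labeled = read_cohort(RESULTS / "cohort_labeled.csv",
                          schema=schema_for_config(config))
    model, trace = fit_model(labeled, config.feature_definitions())
    model.save(RESULTS / "fitted_model.json")
    trace["elimination"].to_csv(RESULTS / "elimination_trace.csv", index=False)
    trace["features"].to_csv(RESULTS / "qualification_table.csv", index=False)

    print("qualification table:")
    print(trace["features"].round(3).to_string(index=False))
    if trace["jaccard_dropped"]:
        print(f"redundancy filter dropped: {trace['jaccard_dropped']}")
    print("\nelimination trace:")
    print(trace["elimination"].round(3).to_string(index=False))

    print(f"\nfinal model features: {model.feature_names}")
    reference = {f.name: f for f in published_model().features}
    for f in model.features:
        ref = reference.get(f.name)
        ref_lr = f"(published LR+ {ref.lr_pos:.2f})" if ref else ""
        print(f"  {f.name:<18s} LR+ {f.lr_pos:>6.2f}  LR- {f.lr_neg:.2f}  "
              f"role {f.role} {ref_lr}")
    print(f"wrote {RESULTS / 'fitted_model.json'}")


if __name__ == "__main__":
    main()
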