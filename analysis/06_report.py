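"""Summarize the fitted solution: class groups and reliable change.

Aggregates fitted class weights into remission / improvement / chronic
groups, computes reliable-and-clinically-significant change rates on both
scales, and writes the summary JSON.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from symtraj.mixture import MixtureModel
from symtraj.report import (ClassGrouping, _change_summary,
                            summarize_class_groups)
from symtraj.simulate import PanelDataset

# canonical (descending baseline PHQ-9) order of the default 6-class
# solution: elevated chronic, acute recovery, chronic, depression
# improvement, anxiety improvement, recovery
DEFAULT_GROUPING = ClassGrouping({
    "remission": (1, 5),
    "improvement": (3, 4),
    "chronic": (0, 2),
})


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    with open(args.cohort / "model.json") as fh:
        raw = json.load(fh)
    model = MixtureModel.from_dict(raw)
    panel = PanelDataset(visits=pd.read_csv(args.cohort / "visits.csv"),
                         covariates=pd.read_csv(args.cohort
                                                / "covariates.csv"))

    summary = {"class_weights_pct":
               [round(100 * w, 1) for w in model.weights]}
    if model.n_classes == 6:
        groups = summarize_class_groups(model.weights, DEFAULT_GROUPING)
        summary["group_pct"] = groups
        print("class-group percentages:")
        for name, pct in groups.items():
            print(f"  {name:<12s} {pct:5.1f}%")
    change = _change_summary(panel)
    summary["reliable_change"] = change.to_dict(orient="records")
    print(change.to_string(index=False))

    with open(args.cohort / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"wrote {args.cohort}/summary.json")


if __name__ == "__main__":
    main()
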