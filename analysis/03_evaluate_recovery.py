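#!/usr/bin/env python
"""Compare pipeline calls to the planted truth and report recovery.

Joins results/scan/calls.tsv to results/cohort/truth.tsv, prints the
confusion table, verifies the 24-bp inter-box conservation on every
classified call, and writes the confusion table to
results/scan/confusion.tsv.
"""

from pathlib import Path

import pandas as pd


def main() -> None:
    root = Path(__file__).resolve().parents[1] / "results"
    truth = pd.read_csv(root / "cohort" / "truth.tsv", sep="\t")
    calls = pd.read_csv(root / "scan" / "calls.tsv", sep="\t")
    merged = truth.merge(calls, on="genome_id", suffixes=("_truth", "_called"))
    confusion = pd.crosstab(merged["group_truth"], merged["group_called"])
    confusion.to_csv(root / "scan" / "confusion.tsv", sep="\t")
    correct = int((merged["group_truth"] == merged["group_called"]).sum())
    print(confusion.to_string())
    print(f"recovered {correct}/{len(merged)} planted groups")

    classified = merged[merged["group_called"].isin(["I", "II", "III"])]
    law = classified["g_up"] + 6 + classified["g_down"]
    assert (law == classified["interbox_gap"]).all()
    assert (classified["interbox_gap"] == 24).all()
    print(f"inter-box distance is 24 bp on all {len(classified)} classified calls")
    spacers = sorted(int(s) for s in classified["spacer"].unique())
    print(f"spacer is {spacers} bp on all promoter-bearing calls")


if __name__ == "__main__":
    main()
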