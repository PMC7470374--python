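#!/usr/bin/env python
"""Stage 4 — evaluate both methods against vendor truth.

Signature-like scores are compared on the full cohort; signature-trained
regressions use the held-out validation half only (cross-tabs use all
samples).  Writes a summary table and the full report JSON, and prints the
headline comparison: training should tighten slope/intercept toward the
identity and raise concordance.

    python analysis/04_evaluate.py
"""

import json
from pathlib import Path

import pandas as pd

from multisig import evaluation, io, training

cohort_dir = Path("results/cohort")
truth = io.scores_from_frame(io.read_scores(cohort_dir / "true_scores.csv"))
like = io.scores_from_frame(io.read_scores(cohort_dir / "scores_like.csv"))
trained = io.scores_from_frame(
    io.read_scores(cohort_dir / "scores_trained.csv"))
split_d = json.loads((cohort_dir / "split.json").read_text())
split = training.SplitSpec(tuple(split_d["train_ids"]),
                           tuple(split_d["validation_ids"]),
                           split_d["seed"])

reports = evaluation.build_report(like, trained, truth, split)
summary = pd.DataFrame([r.summary_row() for r in reports])
summary.to_csv(cohort_dir / "report_summary.csv", index=False,
               float_format=io.FLOAT_FMT)
(cohort_dir / "report.json").write_text(json.dumps(
    [io.report_to_jsonable(r) for r in reports], indent=1))

cols = ["comparison", "n", "pearson_r", "slope", "intercept",
        "concordance_ternary", "concordance_binary"]
with pd.option_context("display.width", 120, "display.precision", 3):
    print(summary[cols].to_string(index=False))
print(f"\nwrote {cohort_dir / 'report_summary.csv'} and report.json")
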