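#!/usr/bin/env python
"""Stage 2 — Method 1, signature-like scores.

Applies the published algorithms after one global normalization (no
calibration to true results) to the cohort from stage 1, writes the scores,
and prints their regression against the vendor truth.  The point of
interest: correlation is high but slope/intercept drift off the identity —
the scaling artefact of running a published algorithm on another platform's
normalized data.

    python analysis/02_score_like.py
"""

from pathlib import Path

from multisig import evaluation, io

cohort_dir = Path("results/cohort")
x = io.read_expression(cohort_dir / "expression.tsv")
cov = io.read_covariates(cohort_dir / "covariates.csv")
truth = io.scores_from_frame(io.read_scores(cohort_dir / "true_scores.csv"))

like = io.compute_like_scores(x, cov, ("prosigna", "oncotype", "mammaprint"))
io.write_scores(like, cohort_dir / "scores_like.csv")

print("signature-like vs true (all samples):")
for key in ("ROR_P", "ROR_PT", "RS"):
    r, slope, intercept = evaluation.regression_metrics(
        like[key].continuous, truth[key].continuous)
    print(f"  {key:7s} r={r:.3f}  like = {intercept:+.2f} + {slope:.2f} x true")
_, conc, lo, hi = evaluation.concordance_table(
    like["MAMMAPRINT"].category, truth["MAMMAPRINT"].category, "binary")
print(f"  MammaPrint binary concordance {conc:.1%} "
      f"(scored lower {lo:.1%}, higher {hi:.1%})")
print(f"wrote {cohort_dir / 'scores_like.csv'}")
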