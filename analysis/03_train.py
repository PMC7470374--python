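#!/usr/bin/env python
"""Stage 3 — Method 2, signature-trained scores.

Splits the cohort 50:50, calibrates each surrogate on the training half
(Prosigna: alternating centering/scaling optimization with 5-fold
cross-validated early stopping; Oncotype DX: metagene-weight refit;
MammaPrint: cross-validated ridge), freezes the models, and scores the full
cohort.  Writes frozen models, iteration traces and trained scores.

    python analysis/03_train.py [--split-seed 1 --cv-seed 2]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from multisig import io, training
from multisig.engines import ExpressionMatrix

ap = argparse.ArgumentParser()
ap.add_argument("--split-seed", type=int, default=1)
ap.add_argument("--cv-seed", type=int, default=2)
args = ap.parse_args()

cohort_dir = Path("results/cohort")
x = io.read_expression(cohort_dir / "expression.tsv")
cov = io.read_covariates(cohort_dir / "covariates.csv")
truth = io.scores_from_frame(io.read_scores(cohort_dir / "true_scores.csv"))

split = training.split_cohort(x.sample_ids, args.split_seed)
(cohort_dir / "split.json").write_text(json.dumps(
    {"seed": split.seed, "train_ids": list(split.train_ids),
     "validation_ids": list(split.validation_ids)}, indent=1))
print(f"50:50 split: {len(split.train_ids)} train / "
      f"{len(split.validation_ids)} validation (seed {args.split_seed})")

import pandas as pd

tr = list(split.train_ids)
x_tr = ExpressionMatrix(x.data.loc[tr], "raw_positive")

yp = pd.Series(truth["ROR_P"].continuous, index=truth["ROR_P"].sample_ids)
ypt = pd.Series(truth["ROR_PT"].continuous, index=truth["ROR_PT"].sample_ids)
model_pro = training.train_prosigna(x_tr, cov.loc[tr], yp.loc[tr],
                                    ypt.loc[tr], cv_seed=args.cv_seed)
full_trace = model_pro.iteration_trace.query("fold == 'full'")
print(f"prosigna: CV chose {model_pro.chosen_iteration} alternating "
      f"iterations; final train MSE {full_trace['train_mse'].iloc[-1]:.2f}")

rs = pd.Series(truth["RS"].continuous, index=truth["RS"].sample_ids)
model_onc = training.train_oncotype(x_tr, rs.loc[tr])
deltas = model_onc.metagene_fit["weight_deltas"]
biggest = max(deltas, key=lambda k: abs(deltas[k]))
print(f"oncotype: refit weight deltas vs published, largest on "
      f"'{biggest}' ({deltas[biggest]:+.3f})")

labels = pd.Series(truth["MAMMAPRINT"].category,
                   index=truth["MAMMAPRINT"].sample_ids)
from multisig import panels
x70 = training.center_log2_per_sample(
    x_tr, panels.load_gene70_template().genes)
model_mp = training.train_mammaprint(x70, labels.loc[tr], seed=args.cv_seed)
print(f"mammaprint: ridge penalty {model_mp.ridge_fit['penalty']:.3g} "
      f"chosen by 5-fold CV")

models = {"prosigna": model_pro, "oncotype": model_onc,
          "mammaprint": model_mp}
for assay, model in models.items():
    io.save_model(model, cohort_dir / f"model_{assay}.yaml")
    if model.iteration_trace is not None:
        model.iteration_trace.to_csv(cohort_dir / f"trace_{assay}.csv",
                                     index=False, float_format=io.FLOAT_FMT)
trained = io.apply_all(models, x, cov)
io.write_scores(trained, cohort_dir / "scores_trained.csv")
print(f"wrote frozen models and {cohort_dir / 'scores_trained.csv'}")
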