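#!/usr/bin/env python
"""Stage 1 — simulate the study cohort.

Generates the default-condition synthetic NanoString-style cohort (n=200:
subtype-structured expression over the three assay panels, hidden per-gene
centering/scaling distortions, tumour sizes, and vendor-true ROR/RS/
MammaPrint results with measurement noise) and writes it under
results/cohort/.  Run from the repository root:

    python analysis/01_simulate.py [--seed 0]
"""

import argparse
from pathlib import Path

import numpy as np

from multisig import io
from multisig.synth import SimulationConfig, generate_cohort

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

out = Path("results/cohort")
out.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(seed=args.seed)
cohort = generate_cohort(cfg)
io.write_expression(cohort.expression, out / "expression.tsv")
io.write_covariates(cohort.covariates, out / "covariates.csv")
io.write_scores(cohort.true_scores, out / "true_scores.csv")

sizes = cohort.covariates["tumour_size_cm"]
print(f"cohort: {cfg.n_samples} samples x "
      f"{cohort.expression.values.shape[1]} genes (seed {cfg.seed})")
print(f"tumour size > 2 cm: {(sizes > 2).mean():.0%} of samples")
for key in ("ROR_PT", "RS"):
    s = cohort.true_scores[key].continuous
    print(f"true {key}: median {np.median(s):.1f}, "
          f"IQR {np.percentile(s, 25):.1f}-{np.percentile(s, 75):.1f}")
frac_low = (cohort.true_scores["MAMMAPRINT"].category == "low").mean()
print(f"true MammaPrint: {frac_low:.0%} low risk")
print(f"wrote expression/covariates/true scores to {out}/")
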