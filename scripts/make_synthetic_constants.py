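"""One-off construction of the synthetic stand-in constant files.

The centroid matrix, ROR weights and gene70 template are labelled synthetic
reconstructions: they have the documented structure (role-driven subtype
profiles, realistic signs/magnitudes) but are not the proprietary values.
Run from repo root: python scripts/make_synthetic_constants.py
"""
import numpy as np
import yaml
from pathlib import Path

DATA = Path("src/multisig/data")

panels = yaml.safe_load((DATA / "panels.yaml").read_text())

# ---- Prosigna centroids: 46 genes x 4 subtypes, role-structured + jitter ----
role_profiles = {
    # (LumA, LumB, Her2, Basal) on the row-scaled scale
    "proliferation": (-1.00, 0.70, 0.60, 0.90),
    "luminal": (0.90, 0.60, -0.60, -0.90),
    "her2": (-0.30, 0.00, 1.20, -0.40),
    "basal": (-0.70, -0.60, -0.30, 1.10),
    "other": (0.00, 0.20, 0.10, 0.20),
}
subtypes = ["LumA", "LumB", "Her2", "Basal"]
rng = np.random.default_rng(20200903)
genes = list(panels["prosigna"]["reporters"])
rows = []
for g in genes:
    role = panels["prosigna"]["reporters"][g]
    base = np.array(role_profiles[role])
    vals = base + rng.normal(0.0, 0.25, size=4)
    rows.append((g, vals))

with open(DATA / "prosigna_centroids.synthetic.tsv", "w") as fh:
    fh.write(
        "# Synthetic stand-in for the published Prosigna/PAM50 subtype centroids\n"
        "# (Parker et al. 2009 / patent US20130337444A1). Role-structured values\n"
        "# on the row-scaled scale; NOT the proprietary centroid values.\n"
    )
    fh.write("gene\t" + "\t".join(subtypes) + "\n")
    for g, vals in rows:
        fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in vals) + "\n")

# ---- gene70 template: 70 values, centered, plus published-style cutoff ----
mp_genes = list(panels["mammaprint"]["reporters"])
t = rng.normal(0.0, 0.5, size=len(mp_genes))
t -= t.mean()
with open(DATA / "gene70_template.synthetic.tsv", "w") as fh:
    fh.write(
        "# Synthetic stand-in for the MammaPrint good-prognosis average profile\n"
        "# (van 't Veer 2002 / van de Vijver 2002). The 0.4 correlation cutoff is\n"
        "# the published value; the per-gene template values are synthetic.\n"
        "# correlation_cutoff\t0.4\n"
    )
    fh.write("gene\ttemplate\n")
    for g, v in zip(mp_genes, t):
        fh.write(f"{g}\t{v:.4f}\n")

print("wrote centroids + template")
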