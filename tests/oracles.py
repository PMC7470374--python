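"""Independent brute-force oracles used by the test suite.

These are deliberately written as single, flat expressions over plain Python
loops / textbook formulas, sharing no code with the package's vectorized
engines.
"""

import math

import numpy as np


def pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / (n - 1)
    va = sum((x - ma) ** 2 for x in a) / (n - 1)
    vb = sum((y - mb) ** 2 for y in b) / (n - 1)
    return cov / math.sqrt(va * vb)


def ror_chain_brute_force(raw_intensities, hk_intensities, centering, scaling,
                          centroid_columns, subtype_weights, prolif_weight,
                          size_weight, prolif_flags, size_cm, offset, slope,
                          variant):
    """Steps 1-8 for ONE sample as a single pass: housekeeping log-ratio,
    row-scaling, centroid correlations, proliferation mean, the ROR linear
    combination, affine rescale and truncation."""
    log_hk = [math.log2(v) for v in hk_intensities]
    geo = sum(log_hk) / len(log_hk)
    normalized = [math.log2(v) - geo for v in raw_intensities]
    row_scaled = [(v - c) / s for v, c, s in zip(normalized, centering, scaling)]
    raw = 0.0
    for w, col in zip(subtype_weights, centroid_columns):
        raw += w * pearson(row_scaled, col)
    if variant in ("ROR_P", "ROR_PT"):
        prolif_vals = [v for v, flag in zip(row_scaled, prolif_flags) if flag]
        raw += prolif_weight * (sum(prolif_vals) / len(prolif_vals))
    if variant == "ROR_PT":
        raw += size_weight * (1.0 if size_cm > 2.0 else 0.0)
    return min(max(offset + slope * raw, 0.0), 100.0)


def ols(x, y):
    """Normal-equations least squares of y on x: (intercept, slope)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    return float(coef[0]), float(coef[1])
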