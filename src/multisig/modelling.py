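"""Method 1 — "signature-like" scores.

One global normalization of the raw intensity matrix followed by the
published scoring algorithms applied verbatim, with no calibration against
true assay results (they are deliberately not parameters of anything here).
The base assumption being probed is that a published algorithm can be
applied to normalized data from a different platform without correction;
the evaluation stage quantifies how far that assumption bends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engines, panels
from .engines import ExpressionMatrix, RiskScoreSet, ScalingFactors, SD_FLOOR


@dataclass(frozen=True)
class RangeTransform:
    """Affine "measurement range" transform: maps the cohort's 2.5th-97.5th
    percentile band of normalized log2 values onto a configured target range
    (defaults emulate the 0-15 reference-normalized scale the published
    Recurrence Score constants assume)."""

    target_low: float = 0.0
    target_high: float = 15.0

    def fit_apply(self, x: ExpressionMatrix, genes) -> ExpressionMatrix:
        sub = x.subset_genes(genes)
        lo, hi = np.percentile(sub.values, [2.5, 97.5])
        span = max(hi - lo, SD_FLOOR)
        slope = (self.target_high - self.target_low) / span
        data = self.target_low + slope * (sub.data - lo)
        return ExpressionMatrix(data, "log2")


def global_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample's intensities to the cohort median total intensity,
    then log2-transform."""
    if x.scale_tag != "raw_positive":
        raise engines.EngineError(f"expected raw_positive input, got {x.scale_tag}")
    if x.data.empty:
        raise engines.EngineError("empty expression matrix")
    totals = x.values.sum(axis=1)
    factors = np.median(totals) / totals
    data = np.log2(x.data.mul(factors, axis=0))
    return ExpressionMatrix(data, "log2")


def cohort_mean_sd_factors(x: ExpressionMatrix, genes) -> ScalingFactors:
    """Row-scaling factors taken from the cohort itself: per-gene mean and
    (floored) SD.  Degenerates gracefully on single-sample input."""
    sub = x.subset_genes(genes)
    if sub.values.shape[0] < 2:
        # cohort statistics are undefined for a single sample; identity
        # factors keep the downstream correlations defined
        n = len(sub.gene_ids)
        return ScalingFactors(tuple(genes), np.zeros(n), np.ones(n))
    mean = sub.values.mean(axis=0)
    sd = np.maximum(sub.values.std(axis=0, ddof=1), SD_FLOOR)
    return ScalingFactors(tuple(genes), mean, sd)


def minmax_rescale(raw: pd.Series) -> tuple[float, float]:
    """Offset/slope mapping the cohort's raw score range onto [0, 100]; the
    published final-rescale constants are not public, so the untrained
    pipeline maps by cohort min-max (a single score maps to 50)."""
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi - lo < SD_FLOOR:
        return 50.0 - float(lo), 1.0
    slope = 100.0 / (hi - lo)
    return -lo * slope, slope


def prosigna_like(x: ExpressionMatrix, tumour_size_cm: pd.Series,
                  variant: str = "ROR_PT") -> RiskScoreSet:
    panel = panels.load_panel("prosigna")
    centroids, weights = panels.load_constants("prosigna")
    norm = global_normalize(x)
    f = cohort_mean_sd_factors(norm, panel.reporter_genes)
    rs = engines.row_scale(norm, f)
    corr = engines.subtype_correlations(rs, centroids)
    prolif = engines.proliferation_score(rs, panel)
    raw = engines.ror_scores(corr, prolif, tumour_size_cm, weights, variant)
    offset, slope = minmax_rescale(raw)
    scores = engines.rescale_truncate(raw, offset, slope)
    out = RiskScoreSet(list(raw.index), "prosigna", variant, continuous=scores)
    return engines.classify_risk(out) if variant == "ROR_PT" else out


def oncotype_like(x: ExpressionMatrix,
                  gstm1_background: float | None = None,
                  range_transform: RangeTransform | None = RangeTransform(),
                  ) -> RiskScoreSet:
    panel = panels.load_panel("oncotype")
    model = panels.load_metagene_model()
    norm = global_normalize(x)
    genes = [g for g in panel.reporter_genes if g in norm.data.columns]
    if range_transform is not None:
        norm = range_transform.fit_apply(norm, genes)
    if gstm1_background is None:
        # GSTM1 is bimodal with about half of samples below background, so
        # the cohort median sits near the background boundary
        gstm1_background = float(np.median(norm.subset_genes(["GSTM1"]).values))
    mg = engines.metagene_scores(norm, model,
                                 background={"GSTM1": gstm1_background})
    rs = engines.recurrence_score(mg, model)
    out = RiskScoreSet(list(rs.index), "oncotype", "RS",
                       continuous=rs.to_numpy())
    return engines.classify_risk(out)


def mammaprint_like(x: ExpressionMatrix) -> RiskScoreSet:
    template = panels.load_gene70_template()
    norm = global_normalize(x)
    return engines.gene70_index(norm, template)


def signature_like(x: ExpressionMatrix, covariates: pd.DataFrame | None,
                   assay: str) -> RiskScoreSet:
    """Method-1 surrogate score for one assay; ``covariates`` must carry a
    ``tumour_size_cm`` column for the Prosigna ROR-PT variant."""
    if assay == "prosigna":
        if covariates is None or "tumour_size_cm" not in covariates:
            raise engines.EngineError("prosigna-like ROR-PT needs tumour sizes")
        return prosigna_like(x, covariates["tumour_size_cm"])
    if assay == "oncotype":
        return oncotype_like(x)
    if assay == "mammaprint":
        return mammaprint_like(x)
    raise engines.EngineError(f"unknown assay {assay!r}")
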