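"""Pure, deterministic scoring engines for the three assays.

The Prosigna risk-of-recurrence (ROR) chain: housekeeping normalization,
per-gene row-scaling, Pearson correlation with the four subtype centroids,
the 18-gene proliferation average, the ROR linear combination and the 0-100
rescale/truncation.  The Oncotype DX chain: metagene averages (with the
GSTM1 background-threshold and Cathepsin-L2 exclusion rules) and the
Recurrence Score.  The MammaPrint chain: gene70 template correlation with a
fixed cutoff.  Risk-category assignment for all assays lives in
:func:`classify_risk`, the single source of truth for cutoff conventions.

No randomness anywhere: same input, bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panels import (GenePanel, Gene70Template, MetageneModel, RorWeights,
                     SubtypeCentroids)

#: floor applied to per-gene standard deviations so row-scaling stays defined
#: on degenerate (e.g. single-sample or constant-gene) cohorts
SD_FLOOR = 1e-8

ROR_VARIANTS = ("ROR", "ROR_P", "ROR_PT")


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes expression with an explicit scale tag.

    ``raw_positive`` holds strictly positive intensities (NanoString-style
    counts); ``log2`` holds log2 (usually reference-normalized) values;
    ``row_scaled`` holds per-gene centered/scaled values.
    """

    data: pd.DataFrame  # index = sample ids, columns = gene symbols
    scale_tag: str = "raw_positive"

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise EngineError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise EngineError(f"duplicate gene columns: {dup}")
        values = self.data.to_numpy(float)
        if np.isnan(values).any():
            raise EngineError("missing values in expression matrix")
        if self.scale_tag == "raw_positive" and not (values > 0).all():
            raise EngineError("raw expression must be strictly positive")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise EngineError(f"missing genes: {missing}")
        return replace(self, data=self.data.loc[:, list(genes)])


@dataclass(frozen=True)
class ScalingFactors:
    """Per-gene centering/scaling used for row-scaling (the quantities the
    training stage estimates; the vendor values are not published)."""

    gene_ids: tuple[str, ...]
    centering: np.ndarray
    scaling: np.ndarray

    def __post_init__(self):
        if not (len(self.gene_ids) == len(self.centering) == len(self.scaling)):
            raise EngineError("scaling-factor arrays misaligned")
        if not (np.asarray(self.scaling) > 0).all():
            raise EngineError("scaling factors must be strictly positive")


@dataclass(frozen=True)
class RiskScoreSet:
    """Per-sample continuous score (absent for binary-only MammaPrint truth)
    plus low/intermediate/high or low/high categories for one assay."""

    sample_ids: list
    assay_name: str
    score_kind: str  # ROR | ROR_P | ROR_PT | RS | GENE70_INDEX
    continuous: np.ndarray | None = None
    category: np.ndarray | None = None  # dtype object, values low/intermediate/high

    def as_frame(self) -> pd.DataFrame:
        d: dict = {"sample_id": list(self.sample_ids), "assay": self.assay_name,
                   "score_kind": self.score_kind}
        d["score"] = self.continuous if self.continuous is not None else np.nan
        d["category"] = self.category if self.category is not None else ""
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Prosigna chain


def normalize_housekeeping(x: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """log2 of each gene relative to the geometric mean of the panel's
    housekeeping genes, per sample.  Housekeeping columns are retained."""
    if x.scale_tag != "raw_positive":
        raise EngineError(f"expected raw_positive input, got {x.scale_tag}")
    hk = list(panel.housekeeping_genes)
    if not hk:
        raise EngineError(f"{panel.assay_name} panel has no housekeeping genes")
    missing = [g for g in hk if g not in x.data.columns]
    if missing:
        raise EngineError(f"missing housekeeping genes: {missing}")
    log2 = np.log2(x.values)
    hk_idx = [x.gene_ids.index(g) for g in hk]
    geo = log2[:, hk_idx].mean(axis=1, keepdims=True)  # log2 geometric mean
    out = pd.DataFrame(log2 - geo, index=x.data.index, columns=x.data.columns)
    return ExpressionMatrix(out, scale_tag="log2")


def row_scale(x: ExpressionMatrix, f: ScalingFactors) -> ExpressionMatrix:
    """(value - centering) / scaling per gene, restricted to ``f.gene_ids``."""
    if x.scale_tag != "log2":
        raise EngineError(f"expected log2 input, got {x.scale_tag}")
    sub = x.subset_genes(f.gene_ids)
    z = (sub.values - np.asarray(f.centering)) / np.asarray(f.scaling)
    out = pd.DataFrame(z, index=sub.data.index, columns=list(f.gene_ids))
    return ExpressionMatrix(out, scale_tag="row_scaled")


def pearson_rows(profiles: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``profiles`` (n x p) with each
    column of ``targets`` (p x k); returns n x k."""
    p = profiles - profiles.mean(axis=1, keepdims=True)
    t = targets - targets.mean(axis=0, keepdims=True)
    pn = np.sqrt((p ** 2).sum(axis=1))
    tn = np.sqrt((t ** 2).sum(axis=0))
    if (pn == 0).any():
        raise EngineError("zero-variance sample profile: correlation undefined")
    if (tn == 0).any():
        raise EngineError("zero-variance target profile")
    return (p @ t) / pn[:, None] / tn[None, :]


def subtype_correlations(x: ExpressionMatrix, c: SubtypeCentroids) -> pd.DataFrame:
    """Per-sample Pearson correlation (across the 46 genes) with each of the
    four subtype centroids."""
    if x.scale_tag != "row_scaled":
        raise EngineError(f"expected row_scaled input, got {x.scale_tag}")
    sub = x.subset_genes(c.genes)
    r = pearson_rows(sub.values, c.values)
    return pd.DataFrame(r, index=sub.data.index, columns=list(c.subtypes))


def proliferation_score(x: ExpressionMatrix, panel: GenePanel) -> pd.Series:
    """Unweighted mean of the 18 proliferation genes' row-scaled values."""
    if x.scale_tag != "row_scaled":
        raise EngineError(f"expected row_scaled input, got {x.scale_tag}")
    genes = panel.genes_with_role("proliferation")
    sub = x.subset_genes(genes)
    return pd.Series(sub.values.mean(axis=1), index=sub.data.index)


def ror_scores(correlations: pd.DataFrame, proliferation: pd.Series,
               tumour_size_cm: pd.Series | None, w: RorWeights,
               variant: str = "ROR_PT") -> pd.Series:
    """Raw (un-rescaled) ROR linear combination.

    ROR uses the four subtype-correlation terms only; ROR_P adds the weighted
    proliferation score; ROR_PT further adds the tumour-size term, an
    indicator of size strictly greater than 2 cm.
    """
    if variant not in ROR_VARIANTS:
        raise EngineError(f"unknown ROR variant {variant!r}")
    wvec = np.array([w.subtype_weights[s] for s in correlations.columns])
    raw = correlations.to_numpy(float) @ wvec
    if variant in ("ROR_P", "ROR_PT"):
        raw = raw + w.proliferation_weight * proliferation.loc[correlations.index].to_numpy(float)
    if variant == "ROR_PT":
        if tumour_size_cm is None:
            raise EngineError("ROR_PT requires tumour sizes")
        size = tumour_size_cm.loc[correlations.index].to_numpy(float)
        raw = raw + w.size_weight * (size > 2.0).astype(float)
    return pd.Series(raw, index=correlations.index)


def rescale_truncate(raw, offset: float, slope: float) -> np.ndarray:
    """Affine map onto the reported scale, truncated to [0, 100]."""
    if slope <= 0:
        raise EngineError("rescale slope must be positive")
    return np.clip(offset + slope * np.asarray(raw, float), 0.0, 100.0)


# ---------------------------------------------------------------------------
# Oncotype DX chain


def metagene_scores(x: ExpressionMatrix, m: MetageneModel,
                    background: dict[str, float] | None = None) -> pd.DataFrame:
    """Weighted-average metagene values on the log2 normalized scale.

    When ``m.gstm1_threshold_rule`` is on, GSTM1 values below the supplied
    background level are raised to background before averaging (GSTM1 is
    bimodal, with roughly half of samples below background).  When
    ``m.ctsl2_excluded`` is on, Cathepsin-L2 (CTSV) is dropped and the
    invasion metagene averages only its remaining member.
    """
    if x.scale_tag != "log2":
        raise EngineError(f"expected log2 input, got {x.scale_tag}")
    out = {}
    for mg, members in m.metagene_definitions.items():
        use = [(g, w) for g, w in members
               if not (m.ctsl2_excluded and g == "CTSV")]
        if not use:
            raise EngineError(f"metagene {mg} has no usable member genes")
        genes = [g for g, _ in use]
        sub = x.subset_genes(genes)
        vals = sub.values.copy()
        if m.gstm1_threshold_rule and "GSTM1" in genes:
            if background is None or "GSTM1" not in background:
                raise EngineError("GSTM1 thresholding enabled but no background "
                                  "level supplied")
            j = genes.index("GSTM1")
            vals[:, j] = np.maximum(vals[:, j], background["GSTM1"])
        wts = np.array([w for _, w in use])
        out[mg] = vals @ wts / wts.sum()
    return pd.DataFrame(out, index=x.data.index)


def recurrence_score(metagenes: pd.DataFrame, m: MetageneModel) -> pd.Series:
    """Reported Recurrence Score: weighted metagene sum, affinely rescaled to
    0-100 and truncated."""
    missing = [mg for mg in m.metagene_weights if mg not in metagenes.columns]
    if missing:
        raise EngineError(f"missing metagene columns: {missing}")
    unscaled = sum(m.metagene_weights[mg] * metagenes[mg].to_numpy(float)
                   for mg in m.metagene_weights)
    rs = rescale_truncate(unscaled, m.rs_rescale_offset, m.rs_rescale_slope)
    return pd.Series(rs, index=metagenes.index)


# ---------------------------------------------------------------------------
# MammaPrint chain


def gene70_index(x: ExpressionMatrix, t: Gene70Template) -> RiskScoreSet:
    """Pearson correlation of each sample's 70-gene profile with the
    good-prognosis template; low risk iff index >= cutoff."""
    if x.scale_tag != "log2":
        raise EngineError(f"expected log2 input, got {x.scale_tag}")
    sub = x.subset_genes(t.genes)
    idx = pearson_rows(sub.values, t.template_profile[:, None])[:, 0]
    cat = np.where(idx >= t.correlation_cutoff, "low", "high").astype(object)
    return RiskScoreSet(sample_ids=sub.sample_ids, assay_name="mammaprint",
                        score_kind="GENE70_INDEX", continuous=idx, category=cat)


# ---------------------------------------------------------------------------
# Risk categories

#: (low upper, intermediate upper) cutoffs on the 0-100 scale; low is
#: [0, lo), intermediate [lo, hi], high (hi, 100].  The binary grouping
#: collapses low+intermediate, i.e. cuts at ``hi``.
CATEGORY_CUTOFFS = {"ROR_PT": (40.0, 60.0), "RS": (18.0, 25.0)}


def categorize(scores: np.ndarray, low_upper: float, high_lower: float,
               scheme: str = "ternary") -> np.ndarray:
    s = np.asarray(scores, float)
    if ((s < 0) | (s > 100)).any():
        raise EngineError("scores outside [0, 100]")
    if scheme == "binary":
        return np.where(s > high_lower, "high", "low").astype(object)
    if scheme != "ternary":
        raise EngineError(f"unknown scheme {scheme!r}")
    out = np.full(s.shape, "intermediate", dtype=object)
    out[s < low_upper] = "low"
    out[s > high_lower] = "high"
    return out


def classify_risk(scores: RiskScoreSet, scheme: str = "ternary") -> RiskScoreSet:
    """Attach risk categories using the documented cutoff conventions:
    ROR-PT low [0,40) / intermediate [40,60] / high (60,100]; RS low [0,18) /
    intermediate [18,25] / high (25,100]; binary collapses low+intermediate
    (so the Oncotype binary cut sits at 25 and the Prosigna one at 60);
    gene70 categories come from the template cutoff and are scheme-free."""
    if scores.continuous is None:
        raise EngineError("classify_risk requires continuous scores")
    kind = "ROR_PT" if scores.score_kind in ROR_VARIANTS else scores.score_kind
    if kind not in CATEGORY_CUTOFFS:
        raise EngineError(f"no category scheme for score kind {scores.score_kind}")
    lo, hi = CATEGORY_CUTOFFS[kind]
    cat = categorize(scores.continuous, lo, hi, scheme)
    return replace(scores, category=cat)
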