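"""Agreement metrics between two score sets.

Pearson correlation and the OLS regression of the *estimated* score on the
*true* score (slope/intercept are direction-dependent; the estimated-on-true
direction matches the way surrogate-vs-assay regression equations are
conventionally printed), plus ternary/binary risk-category cross-tabs with
overall concordance (diagonal fraction) and the directional discordance
fractions (scored lower / scored higher than truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engines import RiskScoreSet, classify_risk
from .training import SplitSpec

_ORDER = {"low": 0, "intermediate": 1, "high": 2}


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationReport:
    assay_name: str
    comparison: str  # e.g. like-vs-true, trained-vs-true
    n: int
    pearson_r: float | None
    slope: float | None
    intercept: float | None
    crosstab_ternary: pd.DataFrame | None = field(default=None, hash=False)
    crosstab_binary: pd.DataFrame | None = field(default=None, hash=False)
    concordance_ternary: float | None = None
    concordance_binary: float | None = None
    frac_scored_lower: float | None = None
    frac_scored_higher: float | None = None

    def summary_row(self) -> dict:
        return {
            "assay": self.assay_name, "comparison": self.comparison,
            "n": self.n, "pearson_r": self.pearson_r, "slope": self.slope,
            "intercept": self.intercept,
            "concordance_ternary": self.concordance_ternary,
            "concordance_binary": self.concordance_binary,
            "frac_scored_lower": self.frac_scored_lower,
            "frac_scored_higher": self.frac_scored_higher,
        }


def regression_metrics(estimated, true) -> tuple[float, float, float]:
    """Pearson r and the OLS slope/intercept of estimated = a + b*true."""
    est = np.asarray(estimated, float)
    tru = np.asarray(true, float)
    if est.size != tru.size:
        raise EvaluationError("length mismatch")
    if est.size < 3:
        raise EvaluationError("need at least 3 samples")
    if est.var() == 0 or tru.var() == 0:
        raise EvaluationError("zero variance input")
    r = float(np.corrcoef(est, tru)[0, 1])
    slope = float(np.cov(tru, est, ddof=0)[0, 1] / tru.var(ddof=0))
    intercept = float(est.mean() - slope * tru.mean())
    return r, slope, intercept


def concordance_table(labels_a, labels_b, scheme: str = "ternary"):
    """Cross-tab of a (rows) vs b (columns) with concordance = diagonal/n
    and the fractions where a's ordinal category is below/above b's."""
    cats = ["low", "high"] if scheme == "binary" else ["low", "intermediate",
                                                       "high"]
    a = np.asarray(labels_a, object)
    b = np.asarray(labels_b, object)
    if a.size != b.size:
        raise EvaluationError("length mismatch")
    bad = set(a) | set(b)
    if not bad <= set(cats):
        raise EvaluationError(f"labels outside {scheme} scheme: "
                              f"{sorted(bad - set(cats))}")
    tab = pd.DataFrame(0, index=cats, columns=cats)
    for la, lb in zip(a, b):
        tab.loc[la, lb] += 1
    n = a.size
    conc = float(np.trace(tab.to_numpy())) / n
    ra = np.array([_ORDER[v] for v in a])
    rb = np.array([_ORDER[v] for v in b])
    frac_lower = float(np.mean(ra < rb))
    frac_higher = float(np.mean(ra > rb))
    return tab, conc, frac_lower, frac_higher


def _align(est: RiskScoreSet, true: RiskScoreSet, ids) -> tuple:
    est_f = est.as_frame().set_index("sample_id")
    true_f = true.as_frame().set_index("sample_id")
    missing = [i for i in ids if i not in est_f.index or i not in true_f.index]
    if missing:
        raise EvaluationError(f"sample ids missing from a score set: "
                              f"{missing[:5]}")
    return est_f.loc[list(ids)], true_f.loc[list(ids)]


def compare_scores(estimated: RiskScoreSet, true: RiskScoreSet,
                   assay: str, comparison: str,
                   regression_ids=None, crosstab_ids=None) -> EvaluationReport:
    """One report: regression on ``regression_ids`` (or all samples),
    cross-tabs on ``crosstab_ids`` (or all samples); regression is skipped
    for binary-only score sets (MammaPrint)."""
    all_ids = list(true.sample_ids)
    regression_ids = list(regression_ids) if regression_ids is not None else all_ids
    crosstab_ids = list(crosstab_ids) if crosstab_ids is not None else all_ids

    has_continuous = (estimated.continuous is not None
                      and true.continuous is not None)
    has_categories = (estimated.category is not None
                      and true.category is not None)
    binary_only = not has_continuous
    r = slope = intercept = None
    if has_continuous:
        est_f, true_f = _align(estimated, true, regression_ids)
        r, slope, intercept = regression_metrics(est_f["score"], true_f["score"])

    report = dict(assay_name=assay, comparison=comparison,
                  n=len(regression_ids), pearson_r=r, slope=slope,
                  intercept=intercept)
    if not has_categories:
        return EvaluationReport(**report)
    est_f, true_f = _align(estimated, true, crosstab_ids)
    if binary_only:
        tab, conc, lo, hi = concordance_table(est_f["category"],
                                              true_f["category"], "binary")
        return EvaluationReport(**report, crosstab_binary=tab,
                                concordance_binary=conc, frac_scored_lower=lo,
                                frac_scored_higher=hi)
    tab3, conc3, lo3, hi3 = concordance_table(est_f["category"],
                                              true_f["category"], "ternary")
    est_b = classify_risk(estimated, "binary")
    true_b = classify_risk(true, "binary")
    est_bf, true_bf = _align(est_b, true_b, crosstab_ids)
    tab2, conc2, _, _ = concordance_table(est_bf["category"],
                                          true_bf["category"], "binary")
    return EvaluationReport(**report, crosstab_ternary=tab3,
                            crosstab_binary=tab2, concordance_ternary=conc3,
                            concordance_binary=conc2, frac_scored_lower=lo3,
                            frac_scored_higher=hi3)


def build_report(like: dict[str, RiskScoreSet], trained: dict[str, RiskScoreSet],
                 true: dict[str, RiskScoreSet],
                 split: SplitSpec) -> list[EvaluationReport]:
    """Reports for every assay/comparison: like-vs-true on all samples;
    trained-vs-true regression on the validation split only, cross-tabs on
    all samples."""
    reports = []
    key_to_assay = {"ROR_P": "prosigna", "ROR_PT": "prosigna",
                    "RS": "oncotype", "MAMMAPRINT": "mammaprint"}
    for key, truth in true.items():
        assay = key_to_assay.get(key, key.lower())
        if key in like:
            reports.append(compare_scores(like[key], truth, assay,
                                          f"like-vs-true ({key})"))
        if key in trained:
            reports.append(compare_scores(
                trained[key], truth, assay, f"trained-vs-true ({key})",
                regression_ids=split.validation_ids))
    return reports
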