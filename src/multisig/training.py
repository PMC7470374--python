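"""Method 2 — "signature-trained" scores.

Each surrogate is calibrated against true assay results on a training split
and then frozen:

* Prosigna ROR: starting from the untrained factors (each gene's mean and SD
  in the training data), alternate between optimizing the 46 scaling factors
  (on the log scale, positivity by construction) and the 46 centering
  factors with a derivative-free simplex, minimizing the mean squared error
  of the rescaled surrogate against true scores; inside every objective
  evaluation an ordinary-least-squares rescale maps the raw score to 0-100.
  The number of alternating iterations is a tuning parameter chosen by
  5-fold cross-validation (up to 20 iterations; the held-out curve typically
  falls, flattens, then rises as the factors start fitting noise).
* Oncotype DX RS: the metagene design (with the GSTM1/CTSL2 rules) is
  refitted to true Recurrence Scores by least squares with intercept.
* MammaPrint: an L2-penalized (ridge) linear classifier on the standardized
  70-gene block, penalty chosen by 5-fold cross-validation.

Training functions only ever see the training split; applying a frozen model
re-estimates nothing from the data it scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import Ridge

from . import engines, panels
from .engines import ExpressionMatrix, RiskScoreSet, ScalingFactors, SD_FLOOR

MAX_ITERATIONS = 20
CV_FOLDS = 5
#: simplex budget per half-iteration, as a multiple of the block dimension;
#: the alternating schedule revisits each block every iteration, so descent
#: saturates well below the point where a larger per-block budget helps
MAXFEV_FACTOR = 60
DEFAULT_PENALTY_GRID = tuple(np.logspace(-2.0, 4.0, 13))


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """Seeded 50:50 train/validation partition of a cohort."""

    train_ids: tuple
    validation_ids: tuple
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.validation_ids):
            raise TrainingError("train/validation overlap")
        if abs(len(self.train_ids) - len(self.validation_ids)) > 1:
            raise TrainingError("split sizes differ by more than 1")


def split_cohort(sample_ids, seed: int) -> SplitSpec:
    ids = list(sample_ids)
    if len(ids) < 2:
        raise TrainingError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    train = tuple(ids[i] for i in sorted(perm[:half]))
    valid = tuple(ids[i] for i in sorted(perm[half:]))
    return SplitSpec(train_ids=train, validation_ids=valid, seed=seed)


@dataclass(frozen=True)
class TrainingResult:
    """Frozen calibrated surrogate for one assay.

    ``factors``/``rescales`` are set for Prosigna; ``metagene_fit`` for
    Oncotype; ``ridge_fit`` for MammaPrint.  ``iteration_trace`` records the
    training objective per iteration (and per-fold held-out MSE for CV
    runs); applying the model never mutates it.
    """

    assay_name: str
    factors: ScalingFactors | None = None
    rescales: dict[str, tuple[float, float]] | None = field(default=None, hash=False)
    metagene_fit: dict | None = field(default=None, hash=False)
    ridge_fit: dict | None = field(default=None, hash=False)
    iteration_trace: pd.DataFrame | None = field(default=None, hash=False)
    chosen_iteration: int | None = None
    objective_mode: str | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Prosigna: alternating centering/scaling optimization


def untrained_init(x: ExpressionMatrix) -> ScalingFactors:
    """Untrained factors: each gene's centering factor is its mean in the
    data, each gene's scaling factor its SD (floored)."""
    panel = panels.load_panel("prosigna")
    sub = x.subset_genes(panel.reporter_genes)
    if sub.values.shape[0] < 2:
        raise TrainingError("untrained_init needs at least 2 samples")
    mean = sub.values.mean(axis=0)
    sd = np.maximum(sub.values.std(axis=0, ddof=1), SD_FLOOR)
    return ScalingFactors(panel.reporter_genes, mean, sd)


def fit_rescale(raw, true) -> tuple[float, float]:
    """OLS of true on raw: the offset/slope mapping raw surrogate scores to
    the 0-100 scale with least squared error."""
    raw = np.asarray(raw, float)
    true = np.asarray(true, float)
    if raw.size < 3:
        raise TrainingError("fit_rescale needs at least 3 samples")
    vr = raw.var()
    if vr < SD_FLOOR ** 2:
        raise TrainingError("raw scores have zero variance")
    slope = np.cov(raw, true, ddof=0)[0, 1] / raw.var(ddof=0)
    offset = true.mean() - slope * raw.mean()
    return float(offset), float(slope)


class ProsignaObjective:
    """Fast evaluator of the training objective for candidate factors.

    Holds the housekeeping-normalized 46-gene block, pre-normalized
    centroids, the tumour-size indicator and the true scores; evaluates the
    MSE of the OLS-rescaled, truncated surrogate (ROR-P and ROR-PT, averaged
    under the default objective mode) in a few vectorized operations.
    """

    def __init__(self, x_log2: ExpressionMatrix, tumour_size_cm: pd.Series,
                 true_ror_p, true_ror_pt, objective_mode: str = "average"):
        if objective_mode not in ("average", "ror_pt"):
            raise TrainingError(f"unknown objective mode {objective_mode!r}")
        panel = panels.load_panel("prosigna")
        centroids, weights = panels.load_constants("prosigna")
        sub = x_log2.subset_genes(panel.reporter_genes)
        self.sample_ids = sub.sample_ids
        self.X = np.ascontiguousarray(sub.values)
        c = centroids.values - centroids.values.mean(axis=0, keepdims=True)
        self.C = c / np.sqrt((c ** 2).sum(axis=0, keepdims=True))
        self.wsub = np.array([weights.subtype_weights[s] for s in centroids.subtypes])
        self.wprol = weights.proliferation_weight
        prolif = panel.genes_with_role("proliferation")
        self.prolif_mask = np.array([g in prolif for g in panel.reporter_genes])
        size = tumour_size_cm.loc[self.sample_ids].to_numpy(float)
        self.size_term = weights.size_weight * (size > 2.0).astype(float)
        self.y_p = np.asarray(true_ror_p, float)
        self.y_pt = np.asarray(true_ror_pt, float)
        self.mode = objective_mode

    def raw_scores(self, centering, scaling):
        z = (self.X - centering) / scaling
        zc = z - z.mean(axis=1, keepdims=True)
        den = np.sqrt(np.einsum("ij,ij->i", zc, zc))
        corr = (zc @ self.C) / den[:, None]
        prolif = z[:, self.prolif_mask].mean(axis=1)
        raw_p = corr @ self.wsub + self.wprol * prolif
        return raw_p, raw_p + self.size_term

    @staticmethod
    def _rescaled_mse(raw, y):
        vr = raw.var()
        if not np.isfinite(vr) or vr < SD_FLOOR ** 2:
            return np.inf, (0.0, 0.0)
        slope = ((raw * y).mean() - raw.mean() * y.mean()) / vr
        offset = y.mean() - slope * raw.mean()
        pred = np.clip(offset + slope * raw, 0.0, 100.0)
        return float(np.mean((pred - y) ** 2)), (float(offset), float(slope))

    def mse(self, centering, scaling) -> float:
        raw_p, raw_pt = self.raw_scores(centering, scaling)
        mse_pt, _ = self._rescaled_mse(raw_pt, self.y_pt)
        if self.mode == "ror_pt":
            return mse_pt
        mse_p, _ = self._rescaled_mse(raw_p, self.y_p)
        return 0.5 * (mse_p + mse_pt)

    def rescales(self, centering, scaling) -> dict[str, tuple[float, float]]:
        """OLS rescale per score kind at the given factors."""
        raw_p, raw_pt = self.raw_scores(centering, scaling)
        return {"ROR_P": self._rescaled_mse(raw_p, self.y_p)[1],
                "ROR_PT": self._rescaled_mse(raw_pt, self.y_pt)[1]}

    def holdout_mse(self, centering, scaling,
                    rescales: dict[str, tuple[float, float]]) -> float:
        """MSE under externally fitted (training-set) rescales."""
        raw_p, raw_pt = self.raw_scores(centering, scaling)
        off, slo = rescales["ROR_PT"]
        mse_pt = np.mean((np.clip(off + slo * raw_pt, 0, 100) - self.y_pt) ** 2)
        if self.mode == "ror_pt":
            return float(mse_pt)
        off, slo = rescales["ROR_P"]
        mse_p = np.mean((np.clip(off + slo * raw_p, 0, 100) - self.y_p) ** 2)
        return float(0.5 * (mse_p + mse_pt))


def _iterate_factors(obj: ProsignaObjective, init: ScalingFactors,
                     n_iterations: int, maxfev_factor: int = MAXFEV_FACTOR):
    """Yield ``(iteration, factors, train_mse)`` for iterations 0..n.

    One iteration optimizes the scaling block (holding centering) and then
    the centering block (holding scaling); the simplex never returns a point
    worse than its start, so the trace is non-increasing.
    """
    centering = np.asarray(init.centering, float).copy()
    log_scaling = np.log(np.asarray(init.scaling, float))
    p = len(centering)
    maxfev = maxfev_factor * p
    yield 0, ScalingFactors(init.gene_ids, centering.copy(),
                            np.exp(log_scaling)), obj.mse(centering,
                                                          np.exp(log_scaling))
    opts = dict(maxfev=maxfev, xatol=1e-6, fatol=1e-8, adaptive=True)

    def _exp(ls):  # clipped so wild simplex proposals cannot overflow
        return np.exp(np.clip(ls, -20.0, 20.0))

    for it in range(1, n_iterations + 1):
        res = minimize(lambda ls: obj.mse(centering, _exp(ls)), log_scaling,
                       method="Nelder-Mead", options=opts)
        log_scaling = np.clip(res.x, -20.0, 20.0)
        res = minimize(lambda c: obj.mse(c, _exp(log_scaling)), centering,
                       method="Nelder-Mead", options=opts)
        centering = res.x
        if not np.isfinite(res.fun):
            raise TrainingError("non-finite training objective")
        yield it, ScalingFactors(init.gene_ids, centering.copy(),
                                 np.exp(log_scaling)), float(res.fun)


def alternating_optimization(x_log2: ExpressionMatrix, tumour_size_cm: pd.Series,
                             true_ror_p, true_ror_pt, init: ScalingFactors,
                             n_iterations: int,
                             objective_mode: str = "average",
                             maxfev_factor: int = MAXFEV_FACTOR) -> TrainingResult:
    """Run the alternating centering/scaling optimization for a fixed number
    of iterations on one training set (iteration 0 = init + fitted rescale)."""
    if n_iterations < 0:
        raise TrainingError("n_iterations must be nonnegative")
    obj = ProsignaObjective(x_log2, tumour_size_cm, true_ror_p, true_ror_pt,
                            objective_mode)
    rows, factors = [], init
    for it, f, mse in _iterate_factors(obj, init, n_iterations, maxfev_factor):
        rows.append({"iteration": it, "train_mse": mse})
        factors = f
    trace = pd.DataFrame(rows)
    rescales = obj.rescales(factors.centering, factors.scaling)
    return TrainingResult(assay_name="prosigna", factors=factors,
                          rescales=rescales, iteration_trace=trace,
                          chosen_iteration=n_iterations,
                          objective_mode=objective_mode)


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    if k > n:
        raise TrainingError(f"k={k} folds but only {n} samples")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def select_iterations_cv(x_log2: ExpressionMatrix, tumour_size_cm: pd.Series,
                         true_ror_p: pd.Series, true_ror_pt: pd.Series,
                         k: int = CV_FOLDS, max_iterations: int = MAX_ITERATIONS,
                         seed: int = 0, objective_mode: str = "average",
                         maxfev_factor: int = MAXFEV_FACTOR,
                         ) -> tuple[int, pd.DataFrame]:
    """Choose the number of alternating iterations by seeded k-fold CV.

    Each fold trains on its 4/5 complement, recording held-out MSE (with the
    complement-fitted rescales) after every iteration 0..max; the chosen
    iteration minimizes the mean held-out MSE, ties going to the smallest
    iteration.  Returns ``(chosen_iteration, fold_traces)``.
    """
    ids = np.array(x_log2.sample_ids, dtype=object)
    folds = _kfold_indices(len(ids), k, seed)
    rows = []
    for fold_no, test_idx in enumerate(folds):
        test_mask = np.zeros(len(ids), bool)
        test_mask[test_idx] = True
        tr_ids, te_ids = list(ids[~test_mask]), list(ids[test_mask])
        if len(te_ids) < 3 or len(tr_ids) < 3:
            raise TrainingError("degenerate CV fold")
        xtr = ExpressionMatrix(x_log2.data.loc[tr_ids], "log2")
        xte = ExpressionMatrix(x_log2.data.loc[te_ids], "log2")
        obj_tr = ProsignaObjective(xtr, tumour_size_cm, true_ror_p.loc[tr_ids],
                                   true_ror_pt.loc[tr_ids], objective_mode)
        obj_te = ProsignaObjective(xte, tumour_size_cm, true_ror_p.loc[te_ids],
                                   true_ror_pt.loc[te_ids], objective_mode)
        init = untrained_init(xtr)
        for it, f, train_mse in _iterate_factors(obj_tr, init, max_iterations,
                                                 maxfev_factor):
            rescales = obj_tr.rescales(f.centering, f.scaling)
            test_mse = obj_te.holdout_mse(f.centering, f.scaling, rescales)
            rows.append({"fold": fold_no, "iteration": it,
                         "train_mse": train_mse, "test_mse": test_mse})
    traces = pd.DataFrame(rows)
    mean_curve = traces.groupby("iteration")["test_mse"].mean()
    chosen = int(mean_curve.index[np.argmin(mean_curve.to_numpy())])
    return chosen, traces


def train_prosigna(x_raw: ExpressionMatrix, covariates: pd.DataFrame,
                   true_ror_p: pd.Series, true_ror_pt: pd.Series,
                   cv_seed: int = 0, k: int = CV_FOLDS,
                   max_iterations: int = MAX_ITERATIONS,
                   objective_mode: str = "average",
                   maxfev_factor: int = MAXFEV_FACTOR) -> TrainingResult:
    """Full Prosigna calibration: CV over the training set to pick the
    iteration count, then the alternating optimization on the complete
    training set stopping there; factors and rescales are frozen."""
    panel = panels.load_panel("prosigna")
    x_log2 = engines.normalize_housekeeping(x_raw, panel)
    size = covariates["tumour_size_cm"]
    chosen, traces = select_iterations_cv(
        x_log2, size, true_ror_p, true_ror_pt, k=k,
        max_iterations=max_iterations, seed=cv_seed,
        objective_mode=objective_mode, maxfev_factor=maxfev_factor)
    result = alternating_optimization(
        x_log2, size, true_ror_p, true_ror_pt, untrained_init(x_log2),
        chosen, objective_mode, maxfev_factor)
    trace = result.iteration_trace.assign(fold="full")
    return TrainingResult(assay_name="prosigna", factors=result.factors,
                          rescales=result.rescales,
                          iteration_trace=pd.concat([traces, trace],
                                                    ignore_index=True),
                          chosen_iteration=chosen,
                          objective_mode=objective_mode, seed=cv_seed)


# ---------------------------------------------------------------------------
# Oncotype DX: metagene-weight refit


def train_oncotype(x_raw: ExpressionMatrix, true_rs: pd.Series,
                   model0: panels.MetageneModel | None = None,
                   gstm1_background: float = None) -> TrainingResult:
    """Refit the metagene coefficients to true Recurrence Scores by least
    squares with intercept; reports the fitted weights both on the RS scale
    and divided by the published rescale slope for comparison with the
    published coefficients."""
    from .synth import GSTM1_BACKGROUND
    if model0 is None:
        model0 = panels.load_metagene_model()
    if gstm1_background is None:
        gstm1_background = GSTM1_BACKGROUND
    panel = panels.load_panel("oncotype")
    norm = engines.normalize_housekeeping(x_raw, panel)
    mg = engines.metagene_scores(norm, model0,
                                 background={"GSTM1": gstm1_background})
    names = list(model0.metagene_weights)
    A = mg[names].to_numpy(float)
    y = true_rs.loc[mg.index].to_numpy(float)
    # scores sitting exactly on the truncation boundary are censored values,
    # not linear responses; the refit uses interior samples only
    interior = (y > 0.0) & (y < 100.0)
    A, y = A[interior], y[interior]
    if A.shape[0] < A.shape[1] + 2:
        raise TrainingError("too few samples for the metagene refit")
    design = np.column_stack([np.ones(len(y)), A])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise TrainingError("collinear metagene design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept, coefs = float(beta[0]), beta[1:]
    published = np.array([model0.metagene_weights[n] for n in names])
    fit = {
        "metagenes": names,
        "intercept": intercept,
        "coefficients": dict(zip(names, coefs.astype(float))),
        "weights_on_published_scale": dict(
            zip(names, (coefs / model0.rs_rescale_slope).astype(float))),
        "weight_deltas": dict(
            zip(names, (coefs / model0.rs_rescale_slope - published)
                .astype(float))),
        "gstm1_background": float(gstm1_background),
    }
    return TrainingResult(assay_name="oncotype", metagene_fit=fit)


# ---------------------------------------------------------------------------
# MammaPrint: cross-validated ridge classifier


def center_log2_per_sample(x_raw: ExpressionMatrix, genes) -> ExpressionMatrix:
    """log2 intensities centered per sample over ``genes`` — a per-sample
    normalization with no cohort statistics, so it is apply-safe."""
    sub = x_raw.subset_genes(genes)
    log2 = np.log2(sub.values)
    data = pd.DataFrame(log2 - log2.mean(axis=1, keepdims=True),
                        index=sub.data.index, columns=list(genes))
    return ExpressionMatrix(data, "log2")


def train_mammaprint(x_log2: ExpressionMatrix, labels: pd.Series,
                     k: int = CV_FOLDS,
                     penalty_grid=DEFAULT_PENALTY_GRID,
                     seed: int = 0) -> TrainingResult:
    """Ridge (L2-penalized linear) classifier of the binary risk label from
    the standardized 70-gene block; the penalty minimizes 5-fold held-out
    misclassification, ties going to the larger (more regularized) penalty."""
    template = panels.load_gene70_template()
    sub = x_log2.subset_genes(template.genes)
    y = (labels.loc[sub.data.index].to_numpy(object) == "high").astype(float)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    X = sub.values
    mean = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0, ddof=1), SD_FLOOR)
    Xs = (X - mean) / sd
    folds = _kfold_indices(len(y), k, seed)
    grid = np.asarray(sorted(penalty_grid), float)
    errors = np.zeros(len(grid))
    for test_idx in folds:
        mask = np.zeros(len(y), bool)
        mask[test_idx] = True
        for gi, alpha in enumerate(grid):
            clf = Ridge(alpha=alpha)
            clf.fit(Xs[~mask], y[~mask])
            pred = clf.predict(Xs[mask]) > 0.5
            errors[gi] += np.sum(pred != (y[mask] > 0.5))
    # ties -> larger penalty: scan from the large end
    best = len(grid) - 1 - int(np.argmin(errors[::-1]))
    clf = Ridge(alpha=grid[best])
    clf.fit(Xs, y)
    fit = {
        "genes": list(template.genes),
        "standardize_mean": mean,
        "standardize_sd": sd,
        "coefficients": clf.coef_.copy(),
        "intercept": float(clf.intercept_),
        "penalty": float(grid[best]),
        "penalty_grid": grid,
        "cv_errors": errors,
        "threshold": 0.5,
    }
    return TrainingResult(assay_name="mammaprint", ridge_fit=fit, seed=seed)


# ---------------------------------------------------------------------------
# Applying frozen models


def apply_trained(model: TrainingResult, x_raw: ExpressionMatrix,
                  covariates: pd.DataFrame | None = None,
                  ) -> dict[str, RiskScoreSet]:
    """Score samples with a frozen model; never re-estimates anything from
    ``x_raw``.  Returns score sets keyed by score kind."""
    if model.assay_name == "prosigna":
        if covariates is None:
            raise TrainingError("prosigna scoring needs tumour sizes")
        panel = panels.load_panel("prosigna")
        centroids, weights = panels.load_constants("prosigna")
        norm = engines.normalize_housekeeping(x_raw, panel)
        rs = engines.row_scale(norm, model.factors)
        corr = engines.subtype_correlations(rs, centroids)
        prolif = engines.proliferation_score(rs, panel)
        out = {}
        for variant in ("ROR_P", "ROR_PT"):
            raw = engines.ror_scores(corr, prolif, covariates["tumour_size_cm"],
                                     weights, variant)
            offset, slope = model.rescales[variant]
            scores = np.clip(offset + slope * raw.to_numpy(), 0.0, 100.0)
            sset = RiskScoreSet(list(raw.index), "prosigna", variant,
                                continuous=scores)
            out[variant] = engines.classify_risk(sset)
        return out
    if model.assay_name == "oncotype":
        fit = model.metagene_fit
        panel = panels.load_panel("oncotype")
        model0 = panels.load_metagene_model()
        norm = engines.normalize_housekeeping(x_raw, panel)
        mg = engines.metagene_scores(
            norm, model0, background={"GSTM1": fit["gstm1_background"]})
        rs = fit["intercept"] + sum(fit["coefficients"][n] * mg[n].to_numpy()
                                    for n in fit["metagenes"])
        sset = RiskScoreSet(list(mg.index), "oncotype", "RS",
                            continuous=np.clip(rs, 0.0, 100.0))
        return {"RS": engines.classify_risk(sset)}
    if model.assay_name == "mammaprint":
        fit = model.ridge_fit
        x_log2 = center_log2_per_sample(x_raw, fit["genes"])
        Xs = (x_log2.values - fit["standardize_mean"]) / fit["standardize_sd"]
        score = Xs @ fit["coefficients"] + fit["intercept"]
        cat = np.where(score > fit["threshold"], "high", "low").astype(object)
        return {"MAMMAPRINT": RiskScoreSet(x_log2.sample_ids, "mammaprint",
                                           "GENE70_INDEX", continuous=None,
                                           category=cat)}
    raise TrainingError(f"unknown assay {model.assay_name!r}")
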