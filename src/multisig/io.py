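"""File formats, run configuration and the end-to-end study driver.

One format per role: expression matrices as TSV (first column ``sample_id``,
remaining columns gene symbols), covariates and scores as CSV, configs and
frozen models as YAML, evaluation reports as JSON.  Every artifact a run
writes is a deterministic function of its config and seeds; the output
directory always contains the config, the seeds and checksums of the
packaged constant files, so a run can be reproduced from its artifacts
alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engines, evaluation, modelling, panels, training
from .engines import ExpressionMatrix, RiskScoreSet
from .synth import SimulationConfig, SyntheticCohort, generate_cohort
from .training import SplitSpec, TrainingResult

FLOAT_FMT = "%.10g"


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tabular formats


def write_expression(x: ExpressionMatrix, path) -> None:
    df = x.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression(path, scale_tag: str = "raw_positive") -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = header[1:]
    dup = sorted({g for g in genes if genes.count(g) > 1})
    if dup:
        raise IOError_(f"duplicate gene columns: {dup[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "sample_id":
        raise IOError_("expression TSV must have a sample_id first column")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise IOError_(f"duplicate sample ids: {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].tolist()
        raise IOError_(f"duplicate gene columns: {dup[:5]}")
    values = df.to_numpy(float)
    if scale_tag == "raw_positive" and not (values > 0).all():
        bad = df.columns[(values <= 0).any(axis=0)].tolist()
        raise IOError_(f"nonpositive intensities in genes: {bad[:5]}")
    return ExpressionMatrix(df, scale_tag)


def missing_panel_genes(x: ExpressionMatrix) -> dict[str, list[str]]:
    """Report which panel genes each assay is missing from a matrix."""
    out = {}
    for assay in panels.ASSAYS:
        panel = panels.load_panel(assay)
        out[assay] = [g for g in panel.all_genes if g not in x.data.columns]
    return out


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov = cov.copy()
    cov.index.name = "sample_id"
    cov.to_csv(path, float_format=FLOAT_FMT)


def read_covariates(path) -> pd.DataFrame:
    cov = pd.read_csv(path, index_col=0)
    if "tumour_size_cm" in cov and (cov["tumour_size_cm"] <= 0).any():
        raise IOError_("tumour sizes must be positive")
    return cov


def scores_frame(scores: dict[str, RiskScoreSet]) -> pd.DataFrame:
    """Long-format scores table with both category schemes where defined."""
    rows = []
    for key, s in scores.items():
        f = s.as_frame()
        if s.continuous is not None and s.score_kind in ("ROR_PT", "RS"):
            tern = engines.classify_risk(s, "ternary").category
            bina = engines.classify_risk(s, "binary").category
        elif s.continuous is not None and s.score_kind == "ROR_P":
            tern = np.full(len(f), "", object)
            bina = np.full(len(f), "", object)
        else:
            tern = np.full(len(f), "", object)
            bina = s.category if s.category is not None else np.full(len(f), "",
                                                                     object)
        f["category_ternary"] = tern
        f["category_binary"] = bina
        f = f.drop(columns=["category"])
        rows.append(f)
    return pd.concat(rows, ignore_index=True)


def write_scores(scores: dict[str, RiskScoreSet], path) -> None:
    scores_frame(scores).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path)


def scores_from_frame(df: pd.DataFrame) -> dict[str, RiskScoreSet]:
    out = {}
    for kind, grp in df.groupby("score_kind", sort=False):
        key = "MAMMAPRINT" if kind == "GENE70_INDEX" else kind
        cont = grp["score"].to_numpy(float)
        if np.isnan(cont).all():
            cont = None
        cat = grp["category_binary"].astype(object).to_numpy()
        if (pd.isna(cat) | (cat == "")).all():
            cat = None
        s = RiskScoreSet(list(grp["sample_id"]), grp["assay"].iloc[0],
                         kind, continuous=cont, category=cat)
        if cont is not None and kind in ("ROR_PT", "RS"):
            # rebuild ternary categories from the continuous scores (the CSV
            # stores both schemes; the ternary one is the canonical label)
            s = engines.classify_risk(s, "ternary")
        out[key] = s
    return out


# ---------------------------------------------------------------------------
# Frozen models as YAML


def _tolist(a):
    return np.asarray(a).tolist()


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def model_to_dict(m: TrainingResult) -> dict:
    d: dict = {"assay_name": m.assay_name, "chosen_iteration": m.chosen_iteration,
               "objective_mode": m.objective_mode, "seed": m.seed}
    if m.factors is not None:
        d["factors"] = {"gene_ids": list(m.factors.gene_ids),
                        "centering": _tolist(m.factors.centering),
                        "scaling": _tolist(m.factors.scaling)}
    if m.rescales is not None:
        d["rescales"] = {k: list(v) for k, v in m.rescales.items()}
    if m.metagene_fit is not None:
        d["metagene_fit"] = _plain(m.metagene_fit)
    if m.ridge_fit is not None:
        d["ridge_fit"] = _plain(m.ridge_fit)
    return _plain(d)


def model_from_dict(d: dict) -> TrainingResult:
    factors = None
    if "factors" in d:
        f = d["factors"]
        factors = engines.ScalingFactors(tuple(f["gene_ids"]),
                                         np.asarray(f["centering"], float),
                                         np.asarray(f["scaling"], float))
    rescales = ({k: tuple(v) for k, v in d["rescales"].items()}
                if "rescales" in d else None)
    ridge = d.get("ridge_fit")
    if ridge is not None:
        ridge = dict(ridge)
        for k in ("standardize_mean", "standardize_sd", "coefficients",
                  "penalty_grid", "cv_errors"):
            if k in ridge:
                ridge[k] = np.asarray(ridge[k], float)
    return TrainingResult(assay_name=d["assay_name"], factors=factors,
                          rescales=rescales, metagene_fit=d.get("metagene_fit"),
                          ridge_fit=ridge,
                          chosen_iteration=d.get("chosen_iteration"),
                          objective_mode=d.get("objective_mode"),
                          seed=d.get("seed"))


def save_model(m: TrainingResult, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(m), sort_keys=True))


def load_model(path) -> TrainingResult:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration and the end-to-end driver


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs; all seeds explicit."""

    output_dir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    assays: tuple[str, ...] = ("prosigna", "oncotype", "mammaprint")
    method: str = "both"  # like | trained | both
    split_seed: int = 1
    cv_seed: int = 2
    objective_mode: str = "average"
    max_iterations: int = training.MAX_ITERATIONS
    maxfev_factor: int = training.MAXFEV_FACTOR

    def validate(self) -> None:
        if self.method not in ("like", "trained", "both"):
            raise IOError_(f"unknown method {self.method!r}")
        unknown = set(self.assays) - set(panels.ASSAYS)
        if unknown:
            raise IOError_(f"unknown assays: {sorted(unknown)}")
        self.simulation.validate()


def data_checksums() -> dict[str, str]:
    """SHA-256 of every packaged constant file (recorded in run provenance)."""
    out = {}
    data_dir = resources.files("multisig") / "data"
    for entry in sorted(data_dir.iterdir(), key=lambda e: e.name):
        if entry.name.endswith((".tsv", ".yaml")):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out


def compute_like_scores(x: ExpressionMatrix, covariates: pd.DataFrame,
                        assays) -> dict[str, RiskScoreSet]:
    out = {}
    for assay in assays:
        if assay == "prosigna":
            out["ROR_P"] = modelling.prosigna_like(
                x, covariates["tumour_size_cm"], "ROR_P")
            out["ROR_PT"] = modelling.prosigna_like(
                x, covariates["tumour_size_cm"], "ROR_PT")
        elif assay == "oncotype":
            out["RS"] = modelling.signature_like(x, covariates, assay)
        else:
            out["MAMMAPRINT"] = modelling.signature_like(x, covariates, assay)
    return out


def train_all(cohort: SyntheticCohort, split: SplitSpec, config: RunConfig,
              ) -> dict[str, TrainingResult]:
    """Fit every requested assay's trained model on the training split."""
    tr = list(split.train_ids)
    x_tr = ExpressionMatrix(cohort.expression.data.loc[tr], "raw_positive")
    cov_tr = cohort.covariates.loc[tr]
    models: dict[str, TrainingResult] = {}
    truth = {k: pd.Series(v.continuous, index=cohort.sample_ids)
             for k, v in cohort.true_scores.items() if v.continuous is not None}
    if "prosigna" in config.assays:
        models["prosigna"] = training.train_prosigna(
            x_tr, cov_tr, truth["ROR_P"].loc[tr], truth["ROR_PT"].loc[tr],
            cv_seed=config.cv_seed, max_iterations=config.max_iterations,
            objective_mode=config.objective_mode,
            maxfev_factor=config.maxfev_factor)
    if "oncotype" in config.assays:
        models["oncotype"] = training.train_oncotype(
            x_tr, truth["RS"].loc[tr])
    if "mammaprint" in config.assays:
        labels = pd.Series(cohort.true_scores["MAMMAPRINT"].category,
                           index=cohort.sample_ids)
        x70 = training.center_log2_per_sample(
            x_tr, panels.load_gene70_template().genes)
        models["mammaprint"] = training.train_mammaprint(
            x70, labels.loc[tr], seed=config.cv_seed)
    return models


def apply_all(models: dict[str, TrainingResult], x: ExpressionMatrix,
              covariates: pd.DataFrame) -> dict[str, RiskScoreSet]:
    out: dict[str, RiskScoreSet] = {}
    for model in models.values():
        out.update(training.apply_trained(model, x, covariates))
    return out


def report_to_jsonable(r: evaluation.EvaluationReport) -> dict:
    d = r.summary_row()
    for name in ("crosstab_ternary", "crosstab_binary"):
        tab = getattr(r, name)
        if tab is not None:
            d[name] = {str(row): {str(col): int(tab.loc[row, col])
                                  for col in tab.columns}
                       for row in tab.index}
    return d


def run(config: RunConfig) -> list[evaluation.EvaluationReport]:
    """Execute simulate -> score-like -> train -> apply -> evaluate as
    requested, writing all artifacts (scores, models, traces, report,
    provenance) under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(
        {"run": asdict(config), "data_checksums": data_checksums()},
        sort_keys=True))

    cohort = generate_cohort(config.simulation)
    write_expression(cohort.expression, out / "expression.tsv")
    write_covariates(cohort.covariates, out / "covariates.csv")
    write_scores(cohort.true_scores, out / "true_scores.csv")

    like: dict[str, RiskScoreSet] = {}
    trained: dict[str, RiskScoreSet] = {}
    split = training.split_cohort(cohort.sample_ids, config.split_seed)
    (out / "split.json").write_text(json.dumps(
        {"seed": split.seed, "train_ids": list(split.train_ids),
         "validation_ids": list(split.validation_ids)}, indent=1))

    if config.method in ("like", "both"):
        like = compute_like_scores(cohort.expression, cohort.covariates,
                                   config.assays)
        write_scores(like, out / "scores_like.csv")
    if config.method in ("trained", "both"):
        models = train_all(cohort, split, config)
        for assay, model in models.items():
            save_model(model, out / f"model_{assay}.yaml")
            if model.iteration_trace is not None:
                model.iteration_trace.to_csv(out / f"trace_{assay}.csv",
                                             index=False,
                                             float_format=FLOAT_FMT)
        trained = apply_all(models, cohort.expression, cohort.covariates)
        write_scores(trained, out / "scores_trained.csv")

    reports = evaluation.build_report(like, trained, cohort.true_scores, split)
    (out / "report.json").write_text(json.dumps(
        [report_to_jsonable(r) for r in reports], indent=1))
    summary = pd.DataFrame([r.summary_row() for r in reports])
    summary.to_csv(out / "report_summary.csv", index=False,
                   float_format=FLOAT_FMT)
    return reports
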