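"""Synthetic NanoString-style cohort generator.

Emulates the statistical structure the analysis assumes, so that training,
validation, parameter recovery and concordance evaluation run end-to-end
without the (non-public) clinical cohort:

* subtype-structured expression for the Prosigna 46-gene panel anchored on
  the packaged subtype centroids, pushed through hidden per-gene
  location/scale factors (the unpublished "vendor" centering/scaling) and
  exponentiated onto the positive intensity scale;
* housekeeping genes with low between-sample variance;
* Oncotype-only and MammaPrint genes with subtype-correlated latent
  structure on scales chosen so the published Recurrence Score constants and
  the gene70 cutoff produce realistic score distributions;
* log-normal tumour sizes centred on 2 cm so both values of the ">2 cm"
  indicator occur;
* ground-truth ROR/ROR-P/ROR-PT, Recurrence Score and binary MammaPrint
  labels obtained by running the scoring engines with the hidden factors,
  plus additive measurement noise (a small label-flip probability for
  MammaPrint).

All randomness flows from ``SimulationConfig.seed`` through named
sub-streams; regeneration with the same config is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engines, panels
from .engines import ExpressionMatrix, RiskScoreSet, ScalingFactors

#: GSTM1 background level on the housekeeping-normalized log2 scale; GSTM1 is
#: generated bimodal with roughly half of samples below this level.
GSTM1_BACKGROUND = 5.0

#: log2 ratio of reporter genes to the housekeeping geometric mean under the
#: unperturbed (base) factors; chosen so reference-normalized values sit on
#: the 0-15 scale the published Recurrence Score constants assume.
BASE_CENTERING = 7.0
BASE_SCALING = 1.0

#: per-subtype latent traits (LumA, LumB, Her2, Basal) driving the genes that
#: are not part of the Prosigna centroid model
_TRAITS = {
    "er": np.array([1.0, 0.6, -0.8, -1.0]),
    "her2": np.array([-0.3, 0.0, 1.4, -0.4]),
    "prolif": np.array([-1.0, 0.7, 0.6, 0.9]),
}

#: structural constants of the MammaPrint block (fixed, not per-cohort)
_MP_BASE_SEED = 988997
_MP_TEMPLATE_GAIN = 2.2
_MP_GOOD_FRACTION = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_samples: int = 200
    subtype_proportions: tuple[float, float, float, float] = (0.45, 0.25, 0.15, 0.15)
    expression_noise_sd: float = 0.30
    factor_perturbation: tuple[float, tuple[float, float]] = (0.5, (0.8, 1.25))
    score_noise_sd: float = 1.0
    mammaprint_flip_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be at least 20")
        props = np.asarray(self.subtype_proportions, float)
        if len(props) != 4 or not np.isclose(props.sum(), 1.0):
            raise ValueError("subtype_proportions must be 4 values summing to 1")
        if (props < 0).any():
            raise ValueError("negative subtype proportion")
        shift, (lo, hi) = self.factor_perturbation
        if shift < 0 or lo <= 0 or hi < lo:
            raise ValueError("invalid factor perturbation")
        if self.expression_noise_sd < 0 or self.score_noise_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0 <= self.mammaprint_flip_prob < 1:
            raise ValueError("flip probability must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticCohort:
    expression: ExpressionMatrix  # raw positive intensities, all panels + hk
    covariates: pd.DataFrame  # index sample_id, column tumour_size_cm
    true_scores: dict[str, RiskScoreSet]  # ROR, ROR_P, ROR_PT, RS, MAMMAPRINT
    hidden: dict = field(hash=False)  # factors, subtypes, seeds, noise levels

    @property
    def sample_ids(self) -> list:
        return self.expression.sample_ids


def base_factors() -> ScalingFactors:
    """Unperturbed hidden factors: every Prosigna reporter centred
    ``BASE_CENTERING`` log2 units above housekeeping with unit scale."""
    panel = panels.load_panel("prosigna")
    n = len(panel.reporter_genes)
    return ScalingFactors(
        gene_ids=panel.reporter_genes,
        centering=np.full(n, BASE_CENTERING),
        scaling=np.full(n, BASE_SCALING),
    )


def perturb_factors(base: ScalingFactors, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> ScalingFactors:
    """Shift centering by N(0, shift_scale) and multiply scaling by
    U[lo, hi] per gene; the perturbed factors are the hidden quantities the
    training stage must recover."""
    config.validate()
    shift, (lo, hi) = config.factor_perturbation
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    centering = np.asarray(base.centering) + rng.normal(0.0, shift, len(base.gene_ids))
    scaling = np.asarray(base.scaling) * rng.uniform(lo, hi, len(base.gene_ids))
    return ScalingFactors(gene_ids=base.gene_ids, centering=centering,
                          scaling=scaling)


def _mammaprint_base_profile(n_genes: int) -> np.ndarray:
    rng = np.random.default_rng(_MP_BASE_SEED)
    return rng.normal(7.0, 0.8, n_genes)


def generate_expression(config: SimulationConfig,
                        factors: ScalingFactors | None = None,
                        rng: np.random.Generator | None = None):
    """Generate the raw intensity matrix over the union of all panels.

    Returns ``(ExpressionMatrix raw_positive, subtype labels, factors)``.
    When ``factors`` is None the hidden factors are drawn by perturbing the
    base factors under ``config.factor_perturbation``.
    """
    config.validate()
    # children 0-5 belong to expression generation; 6-7 to generate_cohort
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(8)]
    rng_factors, rng_subtype, rng_expr, rng_traits, rng_mp = streams[:5]
    if rng is not None:  # explicit stream overrides the derived ones
        rng_factors = rng_subtype = rng_expr = rng_traits = rng_mp = rng

    prosigna = panels.load_panel("prosigna")
    oncotype = panels.load_panel("oncotype")
    mamma = panels.load_panel("mammaprint")
    centroids = panels.load_centroids()

    if factors is None:
        factors = perturb_factors(base_factors(), config, rng_factors)

    n = config.n_samples
    props = np.asarray(config.subtype_proportions, float)
    k = rng_subtype.choice(4, size=n, p=props)
    subtype_labels = np.array(panels.SUBTYPES, dtype=object)[k]

    sd = config.expression_noise_sd
    # Prosigna reporters: row-scaled latent anchored on the subtype centroid,
    # mapped through the hidden per-gene affine onto the log2-ratio scale.
    z = centroids.values.T[k] + rng_expr.normal(0.0, sd, (n, 46))
    y46 = np.asarray(factors.centering) + np.asarray(factors.scaling) * z

    # housekeeping / reference genes: low between-sample variance
    hk_genes = list(dict.fromkeys(prosigna.housekeeping_genes
                                  + oncotype.housekeeping_genes))
    hk_offsets = np.linspace(-0.6, 0.6, len(hk_genes))
    h = rng_expr.normal(10.0, 0.5, n)  # per-sample housekeeping level
    y_hk = hk_offsets[None, :] + rng_expr.normal(0.0, 0.05, (n, len(hk_genes)))

    # Oncotype genes outside the Prosigna panel: trait-driven
    traits = {name: _TRAITS[name][k] + rng_traits.normal(0.0, 0.3, n)
              for name in _TRAITS}
    extras = {
        "AURKA": BASE_CENTERING + 1.0 * traits["prolif"] + rng_traits.normal(0, sd, n),
        "SCUBE2": BASE_CENTERING + 1.2 * traits["er"] + rng_traits.normal(0, sd, n),
        "CTSV": 3.5 + rng_traits.normal(0.0, 0.4, n),  # below background
        "CD68": BASE_CENTERING + rng_traits.normal(0.0, 0.5, n),
        "GSTM1": np.where(
            rng_traits.random(n) < 0.5,
            6.5 + rng_traits.normal(0.0, 0.5, n),
            3.8 + rng_traits.normal(0.0, 0.4, n),  # below background half
        ),
    }

    # MammaPrint block: bimodal prognosis latent times the packaged template
    template = panels.load_gene70_template()
    mp_base = _mammaprint_base_profile(len(mamma.reporter_genes))
    good = rng_mp.random(n) < _MP_GOOD_FRACTION
    v = np.where(good, rng_mp.normal(0.9, 0.25, n), rng_mp.normal(-0.1, 0.3, n))
    y_mp = (mp_base[None, :]
            + _MP_TEMPLATE_GAIN * v[:, None] * template.template_profile[None, :]
            + rng_mp.normal(0.0, sd, (n, len(mamma.reporter_genes))))

    cols: dict[str, np.ndarray] = {}
    for j, g in enumerate(prosigna.reporter_genes):
        cols[g] = y46[:, j]
    for j, g in enumerate(hk_genes):
        cols[g] = y_hk[:, j]
    for g, vals in extras.items():
        cols[g] = vals
    for j, g in enumerate(mamma.reporter_genes):
        cols[g] = y_mp[:, j]

    gene_order = (list(prosigna.reporter_genes) + hk_genes + list(extras)
                  + list(mamma.reporter_genes))
    log2_ratio = np.column_stack([cols[g] for g in gene_order])
    intensities = 2.0 ** (h[:, None] + log2_ratio)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    data = pd.DataFrame(intensities, index=sample_ids, columns=gene_order)
    return ExpressionMatrix(data, "raw_positive"), subtype_labels, factors


def true_prosigna_scores(x: ExpressionMatrix, factors: ScalingFactors,
                         tumour_size_cm: pd.Series) -> dict[str, pd.Series]:
    """Reference ROR family computed with the hidden factors and the
    packaged vendor rescale (noise-free)."""
    panel = panels.load_panel("prosigna")
    centroids, weights = panels.load_constants("prosigna")
    norm = engines.normalize_housekeeping(x, panel)
    rs = engines.row_scale(norm, factors)
    corr = engines.subtype_correlations(rs, centroids)
    prolif = engines.proliferation_score(rs, panel)
    out = {}
    for variant in engines.ROR_VARIANTS:
        raw = engines.ror_scores(corr, prolif, tumour_size_cm, weights, variant)
        out[variant] = pd.Series(
            engines.rescale_truncate(raw, weights.rescale_offset,
                                     weights.rescale_slope),
            index=raw.index)
    return out


def true_oncotype_scores(x: ExpressionMatrix) -> pd.Series:
    """Reference Recurrence Score from the published metagene constants
    (noise-free)."""
    panel = panels.load_panel("oncotype")
    model = panels.load_metagene_model()
    norm = engines.normalize_housekeeping(x, panel)
    mg = engines.metagene_scores(norm, model,
                                 background={"GSTM1": GSTM1_BACKGROUND})
    return engines.recurrence_score(mg, model)


def true_mammaprint_index(x: ExpressionMatrix) -> RiskScoreSet:
    """Reference gene70 index/category from log2 intensities (flip-free)."""
    template = panels.load_gene70_template()
    log2 = ExpressionMatrix(np.log2(x.data), "log2")
    return engines.gene70_index(log2, template)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full synthetic cohort: expression, tumour sizes, and noisy vendor-true
    scores for all three assays, with every hidden parameter recorded."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(8)
    rng_size = np.random.default_rng(children[6])
    rng_noise = np.random.default_rng(children[7])

    x, subtypes, factors = generate_expression(config)
    sizes = pd.Series(np.exp(rng_size.normal(np.log(2.0), 0.45, config.n_samples)),
                      index=x.data.index, name="tumour_size_cm")

    noise = config.score_noise_sd
    true_scores: dict[str, RiskScoreSet] = {}
    for variant, clean in true_prosigna_scores(x, factors, sizes).items():
        noisy = np.clip(clean.to_numpy()
                        + rng_noise.normal(0.0, noise, config.n_samples), 0, 100)
        true_scores[variant] = engines.classify_risk(
            RiskScoreSet(x.sample_ids, "prosigna", variant, continuous=noisy))

    rs_clean = true_oncotype_scores(x)
    rs_noisy = np.clip(rs_clean.to_numpy()
                       + rng_noise.normal(0.0, noise, config.n_samples), 0, 100)
    true_scores["RS"] = engines.classify_risk(
        RiskScoreSet(x.sample_ids, "oncotype", "RS", continuous=rs_noisy))

    mp = true_mammaprint_index(x)
    flips = rng_noise.random(config.n_samples) < config.mammaprint_flip_prob
    labels = mp.category.copy()
    labels[flips] = np.where(labels[flips] == "low", "high", "low")
    true_scores["MAMMAPRINT"] = RiskScoreSet(
        x.sample_ids, "mammaprint", "GENE70_INDEX", continuous=None,
        category=labels)

    covariates = sizes.to_frame()
    hidden = {
        "factors": factors,
        "subtypes": subtypes,
        "gene70_index": mp.continuous,
        "mammaprint_flips": flips,
        "expression_noise_sd": config.expression_noise_sd,
        "score_noise_sd": noise,
        "seed": config.seed,
    }
    return SyntheticCohort(expression=x, covariates=covariates,
                           true_scores=true_scores, hidden=hidden)
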