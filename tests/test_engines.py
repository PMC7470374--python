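"""Scoring-engine correctness against hand and textbook oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multisig import engines, panels
from multisig.engines import ExpressionMatrix, RiskScoreSet, ScalingFactors

from .conftest import make_matrix
from . import oracles


# ---------------------------------------------------------------------------
# housekeeping normalization


def test_normalize_housekeeping_hand_oracle(prosigna_panel):
    genes = list(prosigna_panel.reporter_genes) + list(
        prosigna_panel.housekeeping_genes)
    vals = np.full(len(genes), 4.0)
    vals[:2] = [16.0, 2.0]  # reporters; housekeeping {2,8} below
    hk = dict.fromkeys(prosigna_panel.housekeeping_genes, 4.0)
    hk[prosigna_panel.housekeeping_genes[0]] = 2.0
    hk[prosigna_panel.housekeeping_genes[1]] = 8.0
    for g, v in hk.items():
        vals[genes.index(g)] = v
    # geometric mean of {2, 8, 4, 4, 4, 4, 4, 4} = 4
    x = make_matrix(vals, genes)
    out = engines.normalize_housekeeping(x, prosigna_panel)
    assert out.scale_tag == "log2"
    assert out.data.iloc[0][genes[0]] == pytest.approx(np.log2(16 / 4))
    assert out.data.iloc[0][genes[1]] == pytest.approx(np.log2(2 / 4))


def test_normalize_housekeeping_scale_invariance(prosigna_panel):
    rng = np.random.default_rng(1)
    genes = list(prosigna_panel.all_genes)
    vals = rng.uniform(10, 1000, (3, len(genes)))
    a = engines.normalize_housekeeping(make_matrix(vals, genes), prosigna_panel)
    b = engines.normalize_housekeeping(make_matrix(vals * [[1], [2], [7]], genes),
                                       prosigna_panel)
    np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def test_normalize_reporter_at_geomean_is_zero(prosigna_panel):
    genes = list(prosigna_panel.all_genes)
    x = make_matrix(np.full(len(genes), 9.5), genes)
    out = engines.normalize_housekeeping(x, prosigna_panel)
    np.testing.assert_allclose(out.values, 0.0, atol=1e-12)


def test_normalize_missing_housekeeping_gene_errors(prosigna_panel):
    x = make_matrix([[1.0, 2.0]], ["ESR1", "ACTB"])
    with pytest.raises(engines.EngineError, match="housekeeping"):
        engines.normalize_housekeeping(x, prosigna_panel)


# ---------------------------------------------------------------------------
# row scaling


def test_row_scale_hand_oracle():
    x = make_matrix([[5.0, 1.0]], ["A", "B"], scale_tag="log2")
    f = ScalingFactors(("A", "B"), np.array([1.0, 1.0]), np.array([2.0, 4.0]))
    out = engines.row_scale(x, f)
    assert out.scale_tag == "row_scaled"
    np.testing.assert_allclose(out.values, [[2.0, 0.0]])


def test_row_scale_standardization_property():
    rng = np.random.default_rng(2)
    vals = rng.normal(5, 2, (30, 4))
    genes = list("ABCD")
    x = make_matrix(vals, genes, scale_tag="log2")
    f = ScalingFactors(tuple(genes), vals.mean(0), vals.std(0, ddof=1))
    out = engines.row_scale(x, f)
    np.testing.assert_allclose(out.values.mean(0), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.values.std(0, ddof=1), 1.0, atol=1e-12)


def test_row_scale_rejects_nonpositive_scaling():
    with pytest.raises(engines.EngineError):
        ScalingFactors(("A",), np.array([0.0]), np.array([0.0]))


# ---------------------------------------------------------------------------
# centroid correlations and proliferation


def test_subtype_correlation_of_centroid_is_one(centroids):
    x = make_matrix(centroids.values[:, 0], centroids.genes,
                    scale_tag="row_scaled")
    corr = engines.subtype_correlations(x, centroids)
    assert corr.iloc[0]["LumA"] == pytest.approx(1.0)
    x = make_matrix(-centroids.values[:, 3], centroids.genes,
                    scale_tag="row_scaled")
    corr = engines.subtype_correlations(x, centroids)
    assert corr.iloc[0]["Basal"] == pytest.approx(-1.0)


def test_subtype_correlations_match_scipy(centroids):
    rng = np.random.default_rng(3)
    profile = rng.normal(0, 1, 46)
    x = make_matrix(profile, centroids.genes, scale_tag="row_scaled")
    corr = engines.subtype_correlations(x, centroids)
    for j, s in enumerate(centroids.subtypes):
        expected = stats.pearsonr(profile, centroids.values[:, j]).statistic
        assert corr.iloc[0][s] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_profile_errors(centroids):
    x = make_matrix(np.zeros(46), centroids.genes, scale_tag="row_scaled")
    with pytest.raises(engines.EngineError, match="zero-variance"):
        engines.subtype_correlations(x, centroids)


def test_proliferation_score_is_plain_mean(prosigna_panel):
    rng = np.random.default_rng(4)
    vals = rng.normal(0, 1, 46)
    x = make_matrix(vals, prosigna_panel.reporter_genes,
                    scale_tag="row_scaled")
    score = engines.proliferation_score(x, prosigna_panel)
    idx = [prosigna_panel.reporter_genes.index(g)
           for g in prosigna_panel.genes_with_role("proliferation")]
    assert score.iloc[0] == pytest.approx(np.mean(vals[idx]), abs=1e-12)
    x2 = make_matrix(np.full(46, 1.7), prosigna_panel.reporter_genes,
                     scale_tag="row_scaled")
    assert engines.proliferation_score(x2, prosigna_panel).iloc[0] == \
        pytest.approx(1.7)


# ---------------------------------------------------------------------------
# the ROR combination and rescale


def _dummy_inputs():
    corr = pd.DataFrame([[0.1, -0.2, 0.3, 0.4]], index=["s0"],
                        columns=list(panels.SUBTYPES))
    prolif = pd.Series([0.5], index=["s0"])
    size = pd.Series([2.5], index=["s0"])
    return corr, prolif, size


def test_ror_scores_linear_combination(ror_weights):
    corr, prolif, size = _dummy_inputs()
    got = engines.ror_scores(corr, prolif, size, ror_weights, "ROR_PT")
    expected = sum(ror_weights.subtype_weights[s] * corr.iloc[0][s]
                   for s in panels.SUBTYPES)
    expected += ror_weights.proliferation_weight * 0.5 + ror_weights.size_weight
    assert got.iloc[0] == pytest.approx(expected, abs=1e-12)


def test_ror_variant_nesting(ror_weights):
    corr, prolif, size = _dummy_inputs()
    r = engines.ror_scores(corr, prolif, size, ror_weights, "ROR").iloc[0]
    rp = engines.ror_scores(corr, prolif, size, ror_weights, "ROR_P").iloc[0]
    rpt = engines.ror_scores(corr, prolif, size, ror_weights, "ROR_PT").iloc[0]
    assert rp == pytest.approx(r + ror_weights.proliferation_weight * 0.5)
    assert rpt == pytest.approx(rp + ror_weights.size_weight)


@pytest.mark.parametrize("size,adds_term", [(2.5, True), (1.5, False),
                                            (2.0, False)])
def test_size_indicator_is_strictly_greater_than_2cm(ror_weights, size,
                                                     adds_term):
    corr, prolif, _ = _dummy_inputs()
    base = engines.ror_scores(corr, prolif, pd.Series([size], index=["s0"]),
                              ror_weights, "ROR_PT").iloc[0]
    rp = engines.ror_scores(corr, prolif, None, ror_weights, "ROR_P").iloc[0]
    assert base - rp == pytest.approx(
        ror_weights.size_weight if adds_term else 0.0, abs=1e-12)


def test_ror_pt_requires_sizes(ror_weights):
    corr, prolif, _ = _dummy_inputs()
    with pytest.raises(engines.EngineError, match="tumour"):
        engines.ror_scores(corr, prolif, None, ror_weights, "ROR_PT")


@pytest.mark.parametrize("raw,expected", [(55.0, 55.0), (105.0, 100.0),
                                          (-3.0, 0.0)])
def test_rescale_truncate(raw, expected):
    assert engines.rescale_truncate([raw], 0.0, 1.0)[0] == expected


def test_rescale_rejects_nonpositive_slope():
    with pytest.raises(engines.EngineError):
        engines.rescale_truncate([1.0], 0.0, -1.0)


# ---------------------------------------------------------------------------
# Oncotype metagenes and RS


def _onco_matrix(value_map, default=7.0):
    panel = panels.load_panel("oncotype")
    genes = list(panel.reporter_genes)
    vals = np.full(len(genes), default)
    for g, v in value_map.items():
        vals[genes.index(g)] = v
    return make_matrix(vals, genes, scale_tag="log2")


def test_er_metagene_weighted_average():
    model = panels.load_metagene_model()
    x = _onco_matrix({"ESR1": 3.0, "PGR": 3.0, "BCL2": 3.0, "SCUBE2": 3.0})
    mg = engines.metagene_scores(x, model, background={"GSTM1": 5.0})
    assert mg.iloc[0]["er"] == pytest.approx(3.0)
    # uneven members: weighted average with weights 0.8/1.2/1/1
    x = _onco_matrix({"ESR1": 1.0, "PGR": 2.0, "BCL2": 3.0, "SCUBE2": 4.0})
    mg = engines.metagene_scores(x, model, background={"GSTM1": 5.0})
    assert mg.iloc[0]["er"] == pytest.approx(
        (0.8 * 1 + 1.2 * 2 + 3 + 4) / 4.0)


def test_gstm1_thresholded_at_background():
    model = panels.load_metagene_model()
    x = _onco_matrix({"GSTM1": 4.0})
    mg = engines.metagene_scores(x, model, background={"GSTM1": 5.0})
    assert mg.iloc[0]["gstm1"] == pytest.approx(5.0)
    x = _onco_matrix({"GSTM1": 6.0})
    mg = engines.metagene_scores(x, model, background={"GSTM1": 5.0})
    assert mg.iloc[0]["gstm1"] == pytest.approx(6.0)


def test_gstm1_threshold_requires_background():
    model = panels.load_metagene_model()
    with pytest.raises(engines.EngineError, match="background"):
        engines.metagene_scores(_onco_matrix({}), model)


def test_ctsl2_exclusion_leaves_single_invasion_gene():
    model = panels.load_metagene_model()
    x = _onco_matrix({"MMP11": 2.5, "CTSV": 9.9})
    mg = engines.metagene_scores(x, model, background={"GSTM1": 5.0})
    assert mg.iloc[0]["invasion"] == pytest.approx(2.5)
    model_incl = panels.load_metagene_model(ctsl2_excluded=False)
    mg = engines.metagene_scores(x, model_incl, background={"GSTM1": 5.0})
    assert mg.iloc[0]["invasion"] == pytest.approx((2.5 + 9.9) / 2)


def test_recurrence_score_weighted_sum_oracle():
    model = panels.load_metagene_model()
    rng = np.random.default_rng(5)
    mg = pd.DataFrame([rng.uniform(4, 10, len(model.metagenes))],
                      index=["s0"], columns=list(model.metagenes))
    rs = engines.recurrence_score(mg, model)
    unscaled = sum(model.metagene_weights[m] * mg.iloc[0][m]
                   for m in model.metagenes)
    expected = np.clip(model.rs_rescale_offset
                       + model.rs_rescale_slope * unscaled, 0, 100)
    assert rs.iloc[0] == pytest.approx(expected, abs=1e-12)


def test_recurrence_score_zero_metagenes():
    model = panels.load_metagene_model()
    mg = pd.DataFrame([np.zeros(len(model.metagenes))], index=["s0"],
                      columns=list(model.metagenes))
    assert engines.recurrence_score(mg, model).iloc[0] == \
        np.clip(model.rs_rescale_offset, 0, 100)


# ---------------------------------------------------------------------------
# gene70


def test_gene70_template_self_correlation():
    tpl = panels.load_gene70_template()
    x = make_matrix(tpl.template_profile + 5.0, tpl.genes, scale_tag="log2")
    out = engines.gene70_index(x, tpl)
    assert out.continuous[0] == pytest.approx(1.0)
    assert out.category[0] == "low"
    x = make_matrix(-tpl.template_profile, tpl.genes, scale_tag="log2")
    out = engines.gene70_index(x, tpl)
    assert out.continuous[0] == pytest.approx(-1.0)
    assert out.category[0] == "high"


def test_gene70_index_matches_scipy():
    tpl = panels.load_gene70_template()
    rng = np.random.default_rng(6)
    profile = rng.normal(7, 1, 70)
    out = engines.gene70_index(make_matrix(profile, tpl.genes,
                                           scale_tag="log2"), tpl)
    expected = stats.pearsonr(profile, tpl.template_profile).statistic
    assert out.continuous[0] == pytest.approx(expected, abs=1e-12)
    assert out.category[0] == ("low" if expected >= tpl.correlation_cutoff
                               else "high")


# ---------------------------------------------------------------------------
# categories


@pytest.mark.parametrize("score,expected", [
    (0.0, "low"), (35.0, "low"), (39.999, "low"),
    (40.0, "intermediate"), (50.0, "intermediate"), (60.0, "intermediate"),
    (60.001, "high"), (100.0, "high"),
])
def test_ror_pt_ternary_boundaries(score, expected):
    s = RiskScoreSet(["a"], "prosigna", "ROR_PT",
                     continuous=np.array([score]))
    assert engines.classify_risk(s, "ternary").category[0] == expected


@pytest.mark.parametrize("score,expected", [
    (0.0, "low"), (17.999, "low"), (18.0, "intermediate"),
    (25.0, "intermediate"), (25.001, "high"), (30.0, "high"), (100.0, "high"),
])
def test_rs_ternary_boundaries(score, expected):
    s = RiskScoreSet(["a"], "oncotype", "RS", continuous=np.array([score]))
    assert engines.classify_risk(s, "ternary").category[0] == expected


@pytest.mark.parametrize("kind,score,expected", [
    ("RS", 25.0, "low"), ("RS", 25.001, "high"),
    ("ROR_PT", 60.0, "low"), ("ROR_PT", 60.001, "high"),
])
def test_binary_collapse(kind, score, expected):
    assay = "oncotype" if kind == "RS" else "prosigna"
    s = RiskScoreSet(["a"], assay, kind, continuous=np.array([score]))
    assert engines.classify_risk(s, "binary").category[0] == expected


def test_categories_exhaustive_and_exclusive_over_scale():
    scores = np.linspace(0, 100, 2001)
    s = RiskScoreSet(list(range(len(scores))), "prosigna", "ROR_PT",
                     continuous=scores)
    tern = engines.classify_risk(s, "ternary").category
    assert set(tern) == {"low", "intermediate", "high"}
    bina = engines.classify_risk(s, "binary").category
    assert set(bina) == {"low", "high"}
    # binary is exactly the ternary collapse
    np.testing.assert_array_equal(
        bina, np.where(tern == "high", "high", "low"))


def test_out_of_range_scores_rejected():
    s = RiskScoreSet(["a"], "oncotype", "RS", continuous=np.array([101.0]))
    with pytest.raises(engines.EngineError):
        engines.classify_risk(s)


# ---------------------------------------------------------------------------
# purity and the full-chain oracle


def test_engines_are_pure(prosigna_panel, centroids):
    rng = np.random.default_rng(8)
    genes = list(prosigna_panel.all_genes)
    x = make_matrix(rng.uniform(50, 5000, (5, len(genes))), genes)
    a = engines.normalize_housekeeping(x, prosigna_panel)
    b = engines.normalize_housekeeping(x, prosigna_panel)
    np.testing.assert_array_equal(a.values, b.values)


def test_full_chain_matches_brute_force_oracle(prosigna_panel, centroids,
                                               ror_weights):
    """Composed engine steps equal an independent single-expression oracle."""
    rng = np.random.default_rng(9)
    n = 5
    genes = list(prosigna_panel.reporter_genes)
    hk = list(prosigna_panel.housekeeping_genes)
    raw = rng.uniform(100, 10000, (n, len(genes)))
    raw_hk = rng.uniform(200, 2000, (n, len(hk)))
    centering = rng.normal(7, 0.5, 46)
    scaling = rng.uniform(0.8, 1.3, 46)
    sizes = rng.uniform(0.8, 4.5, n)
    x = make_matrix(np.hstack([raw, raw_hk]), genes + hk)
    f = ScalingFactors(tuple(genes), centering, scaling)
    norm = engines.normalize_housekeeping(x, prosigna_panel)
    z = engines.row_scale(norm, f)
    corr = engines.subtype_correlations(z, centroids)
    prolif = engines.proliferation_score(z, prosigna_panel)
    size_s = pd.Series(sizes, index=x.sample_ids)
    prolif_flags = [g in prosigna_panel.genes_with_role("proliferation")
                    for g in genes]
    for variant in engines.ROR_VARIANTS:
        raw_scores = engines.ror_scores(corr, prolif, size_s, ror_weights,
                                        variant)
        got = engines.rescale_truncate(raw_scores, ror_weights.rescale_offset,
                                       ror_weights.rescale_slope)
        for i in range(n):
            expected = oracles.ror_chain_brute_force(
                raw[i], raw_hk[i], centering, scaling,
                [centroids.values[:, j] for j in range(4)],
                [ror_weights.subtype_weights[s] for s in centroids.subtypes],
                ror_weights.proliferation_weight, ror_weights.size_weight,
                prolif_flags, sizes[i], ror_weights.rescale_offset,
                ror_weights.rescale_slope, variant)
            assert got[i] == pytest.approx(expected, abs=1e-9)
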