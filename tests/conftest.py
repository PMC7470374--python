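import numpy as np
import pandas as pd
import pytest

from multisig import panels, synth
from multisig.engines import ExpressionMatrix


@pytest.fixture(scope="session")
def prosigna_panel():
    return panels.load_panel("prosigna")


@pytest.fixture(scope="session")
def centroids():
    return panels.load_centroids()


@pytest.fixture(scope="session")
def ror_weights():
    return panels.load_ror_weights()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared by read-only tests."""
    return synth.generate_cohort(synth.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero factor perturbation, zero score noise: the closed-loop regime."""
    cfg = synth.SimulationConfig(seed=7, factor_perturbation=(0.0, (1.0, 1.0)),
                                 score_noise_sd=0.0)
    return synth.generate_cohort(cfg)


def make_matrix(values, genes, sample_ids=None, scale_tag="raw_positive"):
    values = np.atleast_2d(np.asarray(values, float))
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=sample_ids,
                                         columns=list(genes)), scale_tag)


@pytest.fixture
def matrix_factory():
    return make_matrix
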