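"""Shared fixtures: the synthetic suite, fitted joint models, and fusion fits.

The three N=9 joint-model fits and the 4x2000 fusion fit are session-scoped
because several test modules (fidelity, sparsity, conditional probes) assert
different properties of the same fitted objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from perfcast.config import RunConfig
from perfcast.effects import OUTCOMES, default_matrix
from perfcast.fixtures import default_fusion_truth, gen_fusion_sources, gen_marginal_suite
from perfcast.fusion import fit_ml, init_fusion
from perfcast.pipeline import build_outcome_model

SUITE_SEED = 20240
FUSION_SEED = 7


@pytest.fixture(scope="session")
def marginal_suite():
    suite, desc = gen_marginal_suite(SUITE_SEED)
    return suite, desc


@pytest.fixture(scope="session")
def effect_matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def test_config():
    return RunConfig.test_profile(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def outcome_models(marginal_suite, effect_matrix, test_config):
    """The three fitted N=9 joint models with their fidelity reports."""
    suite, _ = marginal_suite
    out = {}
    for outcome in OUTCOMES:
        out[outcome] = build_outcome_model(outcome, suite, effect_matrix,
                                           test_config)
    return out


@pytest.fixture(scope="session")
def fusion_recovery():
    """Truth model, generated sources (4 x 2000), initialization, and ML fit."""
    truth = default_fusion_truth(4)
    sources = gen_fusion_sources(truth, [2000] * 4, seed=FUSION_SEED)
    init = init_fusion(sources, n_components=6)
    fitted = fit_ml(sources, init)
    return truth, sources, init, fitted
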