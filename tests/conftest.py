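import warnings

import numpy as np
import pytest

from floranet.config import PipelineConfig, SimulationConfig
from floranet import coexpression as cx
from floranet import ppi
from floranet import simulate as sim
from floranet.pipeline import _derive_seed


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def default_expression():
    """Planted 3-module expression matrix at the default study conditions."""
    expr, truth = sim.generate_expression(SimulationConfig(seed=11))
    return expr, truth


@pytest.fixture(scope="session")
def analyzed(default_expression):
    expr, truth = default_expression
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        partition, beta, fit_table, adj = cx.analyze(expr)
    return expr, truth, partition, beta, fit_table, adj


@pytest.fixture(scope="session")
def corpus():
    """Synthetic PPI corpus plus ground truth at default conditions."""
    cfg = SimulationConfig(seed=5)
    proteins, positives, truth = sim.generate_ppi_corpus(cfg)
    return cfg, proteins, positives, truth


@pytest.fixture(scope="session")
def trained_model(corpus):
    """Classifier trained on the session corpus (positives + sampled negatives)."""
    cfg, proteins, positives, truth = corpus
    curated, _ = ppi.curate_positives(positives, proteins, identity_threshold=None)
    negatives = ppi.build_negative_set(
        proteins, [(a, b) for a, b, _ in curated.pairs], n=len(curated.pairs),
        seed=_derive_seed(cfg.seed, 21),
    )
    dataset = ppi.PPIDataset(pairs=curated.pairs + negatives.pairs)
    model = ppi.train_classifier(dataset, proteins, seed=0)
    return dataset, model


@pytest.fixture()
def pipeline_config():
    return PipelineConfig(seed=0)
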