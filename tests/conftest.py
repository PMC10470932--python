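import numpy as np
import pytest

from circnea.core_io import DiseaseDAG
from circnea.fusion import fuse, pair_features
from circnea.similarity import build_bundle
from circnea.synthetic import (
    SyntheticConfig,
    sample_negatives,
    simulate_associations,
    simulate_dag,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted synthetic dataset (80x30, 4 blocks)."""
    cfg = SyntheticConfig()
    am = simulate_associations(cfg)
    dag = simulate_dag(cfg)
    expr = simulate_expression(cfg)
    return cfg, am, dag, expr


@pytest.fixture(scope="session")
def default_fv(default_dataset):
    """Fused pair-feature matrix for the default dataset's labeled pairs."""
    _, am, dag, expr = default_dataset
    pairs = sample_negatives(am, int(am.AM.sum()), 11)
    fused = fuse(build_bundle(am, dag, expr))
    return pair_features(fused.CM, fused.DM, pairs), pairs


@pytest.fixture(scope="session")
def small_dataset():
    """A small dataset for fast cross-validation plumbing tests."""
    cfg = SyntheticConfig(m=36, n=12, blocks=3, density_in=0.4, density_out=0.03, seed=7)
    am = simulate_associations(cfg)
    dag = simulate_dag(cfg)
    expr = simulate_expression(cfg)
    pairs = sample_negatives(am, int(am.AM.sum()), 13)
    return cfg, am, dag, expr, pairs


@pytest.fixture()
def diamond_dag():
    """d -> a, d -> b, a -> r, b -> r (edges child -> parent)."""
    return DiseaseDAG(["d", "a", "b", "r"], [("d", "a"), ("d", "b"), ("a", "r"), ("b", "r")])
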