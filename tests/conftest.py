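import numpy as np
import pandas as pd
import pytest

from malignet import coexpnet, synthio


@pytest.fixture(scope="session")
def default_cohort():
    """Reference synthetic cohort: 60 samples, 3 planted 50-gene modules."""
    cfg = synthio.SimulationConfig(seed=1)
    expr, truth = synthio.generate_cohort(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def default_tom(default_cohort):
    _, expr, _ = default_cohort
    adj = coexpnet.adjacency_matrix(expr, 6)  # pipeline default soft power
    return coexpnet.topological_overlap(adj)


@pytest.fixture(scope="session")
def default_assignment(default_cohort, default_tom):
    _, expr, _ = default_cohort
    assignment = coexpnet.detect_modules(default_tom)
    return coexpnet.module_eigengene_and_membership(expr, assignment)


@pytest.fixture(scope="session")
def truth_assignment(default_cohort):
    """Assignment built from the planted labels (no detection step)."""
    _, expr, truth = default_cohort
    assignment = coexpnet.ModuleAssignment(labels=truth.module_labels)
    return coexpnet.module_eigengene_and_membership(expr, assignment)


def random_correlation_data(n_genes: int, n_samples: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    return pd.DataFrame(values, index=[f"g{i:03d}" for i in range(n_genes)])
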