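import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from consensome import (
    CistromeSimulationConfig,
    ExperimentTable,
    SimulationConfig,
    simulate_cistromic_corpus,
    simulate_transcriptomic_corpus,
)


def make_table(experiment_id, rows):
    """rows: iterable of (probeset_id, gene_id, fold_change, p_value)."""
    df = pd.DataFrame(rows, columns=["probeset_id", "gene_id", "fold_change", "p_value"])
    return ExperimentTable(experiment_id, df)


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic study: 1000 genes, 10 true targets, 20 experiments."""
    return simulate_transcriptomic_corpus(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_cistrome():
    return simulate_cistromic_corpus(CistromeSimulationConfig(seed=7))
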