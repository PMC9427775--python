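import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from icfuse.config import AnalysisConfig
from icfuse.simulate import SimulationConfig, simulate_cohort
from icfuse.types import Layer, OmicsMatrix


@pytest.fixture(scope="session")
def default_bundle():
    """One default (complementary-design) cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def full_design_bundle():
    """Cohort with per-cluster markers in both layers (full design)."""
    return simulate_cohort(SimulationConfig(seed=5, complementary_design=False))


@pytest.fixture()
def analysis_config():
    cfg = AnalysisConfig()
    cfg.consensus.reps = 100
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(values, layer=Layer.EXPRESSION_LOG, features=None, samples=None):
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr, index=features, columns=samples), layer)
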