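import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from colicord.io_core import AnalysisConfig, ExpressionMatrix, SampleDesign
from colicord.synthetic_data import SimConfig, simulate_experiment


@pytest.fixture
def analysis_config():
    return AnalysisConfig()


@pytest.fixture
def small_log2_matrix():
    """4 genes x 4 samples log2 matrix with a fully crossed 2-subject design."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(4, 4)),
        index=[f"g{i}" for i in range(4)],
        columns=["s1_T0", "s1_T3", "s2_T0", "s2_T3"],
    )
    return ExpressionMatrix(values=values, scale="log2")


@pytest.fixture
def small_design():
    rows = []
    for subj in ("s1", "s2"):
        for cond in ("T0", "T3"):
            rows.append(
                {
                    "sample_id": f"{subj}_{cond}",
                    "subject_id": subj,
                    "condition": cond,
                    "species": "rat",
                }
            )
    return SampleDesign(table=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_study():
    """One moderately sized simulated study shared across test modules."""
    return simulate_experiment(SimConfig(n_genes=600, rng_seed=101))
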