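import numpy as np
import pandas as pd
import pytest

from immunomet.cytometry import EventTable
from immunomet.simulate import SyntheticCohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230921)


@pytest.fixture
def small_events():
    """Tiny hand-built event table: 4 cells, oligomycin condition."""
    data = pd.DataFrame(
        {
            "puromycin": [1.0, 10.0, 1.0, 10.0],
            "CD14": [1.0, 10.0, 1.0, 10.0],
            "sample_id": "s1",
            "population": "mDC",
            "condition": "O",
            "viability_pass": True,
        }
    )
    return EventTable(data, ("puromycin", "CD14"))


@pytest.fixture
def tiny_cohort_config():
    """Small, fast synthetic cohort used by integration-style tests."""
    return SyntheticCohortConfig(
        seed=11,
        n_patients={"good": 6, "bad": 6},
        cells_per_condition=300,
    )
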