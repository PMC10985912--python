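import logging

import numpy as np
import pandas as pd
import pytest

from snownet.synthetic import SimConfig, generate_dataset
from snownet.tables import (
    BACTERIA,
    FUNGI,
    SNOW_COVERED,
    SNOW_FREE,
    AsvTable,
    SampleMetadata,
)

logging.getLogger("snownet").setLevel(logging.ERROR)


@pytest.fixture
def toy_table():
    """3 samples × 4 ASVs with easily-enumerable occurrences (2, 3, 1, 3)."""
    counts = pd.DataFrame(
        {
            "a1": [5, 0, 2],
            "a2": [1, 1, 7],
            "a3": [0, 0, 3],
            "a4": [2, 2, 2],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return AsvTable(counts, FUNGI)


@pytest.fixture
def toy_meta():
    return SampleMetadata(
        pd.DataFrame(
            {
                "location": ["L1", "L2", "L3"],
                "condition": [SNOW_FREE, SNOW_COVERED, SNOW_FREE],
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Scaled-down synthetic study used where full size is unnecessary."""
    defaults = dict(
        n_fungi=30,
        n_bacteria=60,
        n_core_fungi=8,
        n_core_bacteria=15,
        fungal_depth=(2000.0, 500.0),
        bacterial_depth=(8000.0, 2000.0),
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic dataset shared across the session."""
    return generate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_sim_config(seed=5))
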