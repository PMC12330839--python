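import numpy as np
import pandas as pd
import pytest

from langasym.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared across tests (moderate noise)."""
    spec = CohortSpec(
        n_subjects=40,
        n_regions=32,
        n_pairs_of_interest=8,
        n_timepoints=120,
        noise_sd=0.5,
        seed=123,
    )
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_atlas():
    from langasym.atlas import make_atlas

    return make_atlas(8, 2)


@pytest.fixture(scope="session")
def tiny_g1(tiny_atlas):
    """Deterministic gradient table for 3 subjects over the tiny atlas."""
    rng = np.random.default_rng(7)
    g = rng.uniform(0, 100, size=(3, len(tiny_atlas)))
    return pd.DataFrame(
        g,
        index=pd.Index([f"sub{i}" for i in range(3)], name="subject_id"),
        columns=list(tiny_atlas["region_id"]),
    )
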