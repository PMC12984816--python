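import numpy as np
import pandas as pd
import pytest

from abaqg import (
    DesignSpec,
    MissingnessSpec,
    pedigree_from_frame,
    simulate_population,
)


def trio_frame():
    return pd.DataFrame(
        {
            "id": ["X", "S", "D"],
            "sire": ["S", "0", "0"],
            "dam": ["D", "0", "0"],
            "sex": ["F", "M", "F"],
        }
    )


@pytest.fixture
def trio_pedigree():
    return pedigree_from_frame(trio_frame())


@pytest.fixture(scope="session")
def small_design():
    """A 30-family design, fully observed, all traits, no subsample."""
    spec = DesignSpec(
        n_sires=18, n_dams=27, n_families=30, offspring_per_family=10, seed=9
    )
    return simulate_population(
        spec,
        seed=9,
        miss=MissingnessSpec(
            survival_rate=0.95,
            tag_retention=1.0,
            trait_retention={},
            meat_subsample=None,
        ),
    )


@pytest.fixture(scope="session")
def sl30_population():
    """Moderate single-trait population for REML recovery checks."""
    spec = DesignSpec(
        n_sires=24, n_dams=36, n_families=42, offspring_per_family=14, seed=21
    )
    return simulate_population(
        spec,
        traits=["SL_30"],
        seed=21,
        miss=MissingnessSpec(
            survival_rate=1.0, tag_retention=1.0, trait_retention={},
            meat_subsample=None,
        ),
    )


def fully_observed(survival_rate=1.0):
    return MissingnessSpec(
        survival_rate=survival_rate,
        tag_retention=1.0,
        trait_retention={},
        meat_subsample=None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
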