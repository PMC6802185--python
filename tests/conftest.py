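import numpy as np
import pandas as pd
import pytest

from colcomp.data import SeedDataset
from colcomp.kernels import KernelSpec
from colcomp.synthetic import (
    CommunityConfig,
    SpeciesConfig,
    generate_community,
)


def single_species_config(
    kernel: KernelSpec,
    beta: float = 5.0,
    n_stems: int = 300,
    n_traps: int = 149,
    **overrides,
) -> CommunityConfig:
    """One canopy-like species on the default 20-ha plot."""
    sp = SpeciesConfig(
        code="SP",
        n_stems=n_stems,
        dbh_meanlog=np.log(10.0),
        dbh_sdlog=0.6,
        dbh_r=5.0,
        beta=beta,
        kernel=kernel,
        intercept=3.0,
        coef_dbh=0.03,
        coef_nc=-0.3,
    )
    return CommunityConfig(species=(sp,), n_traps=n_traps, **overrides)


@pytest.fixture(scope="session")
def exp_kernel():
    return KernelSpec("negative_exponential", (15.0,))


@pytest.fixture(scope="session")
def small_community():
    """A single-species synthetic community reused across read-only tests."""
    return generate_community(single_species_config(KernelSpec("negative_exponential", (15.0,))), seed=42)


@pytest.fixture()
def toy_dataset():
    """A hand-sized dataset (5 trees, 3 traps) for brute-force likelihood checks."""
    trees = pd.DataFrame(
        {
            "id": [f"t{i}" for i in range(5)],
            "species": ["AA"] * 5,
            "x": [10.0, 30.0, 55.0, 70.0, 90.0],
            "y": [20.0, 40.0, 35.0, 60.0, 15.0],
            "dbh": [12.0, 8.0, 4.0, 20.0, 15.0],
            "survived": [True, True, False, True, False],
        }
    )
    traps = pd.DataFrame(
        {"id": ["T1", "T2", "T3"], "x": [25.0, 50.0, 80.0], "y": [25.0, 50.0, 30.0], "area": [0.5] * 3}
    )
    counts = pd.DataFrame(
        {"trap_id": ["T1", "T2", "T3"], "species": ["AA"] * 3, "count": [4, 1, 2]}
    )
    species = pd.DataFrame(
        {"code": ["AA"], "dbh_r": [5.0], "dbh_m": [20.0], "growth_form": ["canopy"]}
    )
    return SeedDataset(
        trees=trees, traps=traps, counts=counts, species=species, years=10.0, plot=(100.0, 80.0)
    )
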