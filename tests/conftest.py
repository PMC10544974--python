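import numpy as np
import pandas as pd
import pytest

import phenospectra as ps


@pytest.fixture(scope="session")
def vegetation_spectrum():
    """A healthy mid-canopy spectrum used across spectral tests."""
    return ps.simulate_canopy_spectrum(0.0, 0.5)


@pytest.fixture(scope="session")
def balanced_trial():
    """Balanced alpha-lattice trial (60 genotypes x 2 envs x 2 reps)."""
    design = ps.generate_trial_design(
        "alpha_lattice", 60, r=2, x=2, block_size=60, seed=101
    )
    table, truth = ps.simulate_genetic_values(
        design, sigma_G2=2.0, sigma_GE2=0.5, sigma_eps2=1.0, seed=202
    )
    return design, table, truth


@pytest.fixture()
def small_band_table():
    """Five plots with all five index bands."""
    rng = np.random.default_rng(7)
    n = 5
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(n)],
            "R550": rng.uniform(0.05, 0.15, n),
            "R680": rng.uniform(0.05, 0.15, n),
            "R700": rng.uniform(0.1, 0.25, n),
            "R800": rng.uniform(0.35, 0.55, n),
            "R970": rng.uniform(0.25, 0.45, n),
        }
    )
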