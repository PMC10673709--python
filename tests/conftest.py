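import numpy as np
import pandas as pd
import pytest

from droughtflux import synthetic


@pytest.fixture(scope="session")
def default_design() -> pd.DataFrame:
    return synthetic.generate_design(synthetic.default_sites())


@pytest.fixture(scope="session")
def noiseless_config() -> synthetic.EffectConfig:
    """All noise off: downstream stages must round-trip the ground truth."""
    return synthetic.EffectConfig(
        unit_sd_log10=0.0,
        microcosm_sd_log10=0.0,
        cq_noise_sd=0.0,
        flux_sd={"CO2": 0.0, "CH4": 0.0, "N2O": 0.0},
        conc_noise_ppm={"CO2": 0.0, "CH4": 0.0, "N2O": 0.0},
    )


@pytest.fixture(scope="session")
def small_sim() -> dict:
    """One-site, two-replicate simulation with default noise (seeded)."""
    site = synthetic.SiteConfig(
        site_id="mini", vegetation_types=("veg_a", "veg_b"), replicates_per_cell=2, pwp=9.17
    )
    return synthetic.simulate_experiment([site], synthetic.EffectConfig(), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
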