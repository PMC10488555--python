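import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scarspls.synthetic_data as sd
from scarspls.spectra_io import WavenumberGrid

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_small_dataset(seed: int = 0, n_samples: int = 24, scatter: sd.ScatterNoiseModel | None = None):
    """Compact two-analyte dataset on a 120-point grid for fast tests."""
    grid = WavenumberGrid.from_range(7600.0, 7600.0 - 8 * 119, 8.0)
    config = sd.FermentationSimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    profiles = sd.simulate_profiles(config, rng=rng)
    idx = np.round(np.linspace(0, len(profiles) - 1, n_samples)).astype(int)
    profiles = profiles.iloc[idx].reset_index(drop=True)
    bands = {
        "acetic_acid": [sd.PureComponentBand(7192.0, 25.0, 0.012)],
        "ethanol": [sd.PureComponentBand(6744.0, 25.0, 0.008)],
    }
    water = [sd.PureComponentBand(6900.0, 190.0, 0.95)]
    ds = sd.simulate_dataset(
        profiles[["time_days", "batch", "acetic_acid", "ethanol"]],
        bands,
        water,
        scatter if scatter is not None else sd.ScatterNoiseModel(),
        grid,
        seed=seed + 1,
    )
    # last third of the samples become the prediction set
    role = ds.role.copy()
    role[2 * n_samples // 3 :] = "prediction"
    ds.role = role
    return ds


@pytest.fixture(scope="session")
def small_dataset():
    return build_small_dataset(seed=0)


@pytest.fixture(scope="session")
def paper_dataset():
    return sd.make_paper_scale_splits(seed=1)
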