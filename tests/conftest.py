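import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from ramanct import SpectralDataset, SyntheticConfig, generate_dataset


def make_dataset(axis, intensities, groups=None, batches=None, mice=None):
    """Hand-rolled tiny dataset helper for unit tests."""
    intensities = np.atleast_2d(intensities)
    n = intensities.shape[0]
    groups = groups or ["sham"] * n
    batches = batches or ["batch1"] * n
    mice = mice or [f"m{i}" for i in range(n)]
    meta = pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(n)],
        "batch_id": batches,
        "mouse_id": mice,
        "group": groups,
        "model": ["PCI"] * n,
        "cell_id": [f"c{i}" for i in range(n)],
    })
    return SpectralDataset(axis, intensities, meta)


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structured experiment: 2 batches x 2 mice/group x 15 cells."""
    return SyntheticConfig(n_batches=2, mice_per_group_per_batch=2,
                           cells_per_mouse=15, seed=42)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_dataset(small_cfg)
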