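import numpy as np
import pytest

from angioquant import synthetic as syn


@pytest.fixture(scope="session")
def tube_phantom():
    """Noise-free vascular phantom with exact ground truth (shared)."""
    return syn.generate_vascular_phantom(shape=(48, 48, 48), n_segments=18,
                                         radius_range_um=(18.0, 36.0),
                                         noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def histology_field():
    """Default Ki67/lectin phantom field with ground truth (shared)."""
    return syn.generate_histology_field(seed=21)


@pytest.fixture(scope="session")
def spectra_cohort():
    """Default two-class spectral cohort (n = 6 + 6)."""
    return syn.generate_spectra_cohort(seed=31)


def random_vessel_mask(shape, rng, n_tubes=3):
    """Sparse random tube-and-blob mask for oracle-equivalence tests."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_tubes):
        p0 = rng.uniform(2, np.array(shape) - 3)
        p1 = rng.uniform(2, np.array(shape) - 3)
        syn.rasterize_tube(mask, p0, p1, rng.uniform(1.0, 2.5))
    return mask
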