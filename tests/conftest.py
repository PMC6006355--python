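import numpy as np
import pytest

import nodulex as nx


@pytest.fixture(scope="session")
def sphere_phantom():
    """One 64x64x24 scan with a single exact (spiculation-free) sphere."""
    spec = nx.PhantomSpec(
        "P-sphere",
        nodules=(nx.NoduleTruth(center=(32.0, 32.0, 12.0), radius_mm=5.0),),
        rng_seed=42,
    )
    volume, masks = nx.generate_scan(spec)
    return spec, volume, masks[0]


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient two-class cohort with 4 jittered readers."""
    readers = nx.SimulatedReaderSet(
        n_readers=4, contour_jitter_mm=0.5, rating_noise=0.2, rng_seed=3
    )
    return nx.generate_cohort(
        40,
        {nx.BENIGN_LIKE: 0.5, nx.MALIGNANT_LIKE: 0.5},
        readers,
        seed=202,
    )


def random_mask(rng: np.random.Generator, shape=(8, 8, 4), p=0.3) -> np.ndarray:
    return rng.random(shape) < p
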