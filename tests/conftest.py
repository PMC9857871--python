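import numpy as np
import pytest

from spectraqc import (
    SimulationConfig,
    SpectralLibrary,
    default_tissue_suite,
    preprocess_library,
    sample_library,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_library():
    """3 spectra, 2 tissues, 2 patients, 5 bands."""
    wavelengths = [500, 505, 510, 515, 520]
    reflectance = [
        [0.2, 0.3, 0.4, 0.5, 0.6],
        [0.25, 0.35, 0.45, 0.55, 0.65],
        [0.9, 0.7, 0.5, 0.3, 0.1],
    ]
    return SpectralLibrary(
        wavelengths, reflectance, ["mucosa", "mucosa", "serosa"], ["p1", "p2", "p1"]
    )


@pytest.fixture(scope="session")
def suite_library():
    """One seeded draw from the shipped tissue suite, preprocessed, with truth."""
    cfg = SimulationConfig(
        models=default_tissue_suite()[:8],
        n_patients=10,
        spectra_per_tissue_per_patient=5,
        seed=11,
        mislabel_fraction=0.05,
    )
    lib, truth = sample_library(cfg)
    return preprocess_library(lib), truth


def random_positive_spectra(rng, n_pairs, n_bands=30):
    """Pairs of strictly positive non-constant random spectra."""
    for _ in range(n_pairs):
        a = rng.uniform(0.05, 1.0, n_bands)
        b = rng.uniform(0.05, 1.0, n_bands)
        yield a, b
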