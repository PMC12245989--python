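import numpy as np
import pytest

from leafspec.simulate import LeafSimConfig, simulate_campaign
from leafspec.spectra import GRID, Spectrum, SpectrumMeta


def make_flat(value: float = 0.3, **meta) -> Spectrum:
    return Spectrum(np.full(GRID.size, value), SpectrumMeta(**meta))


def spectrum_with_bands(bands: dict, base: float = 0.2) -> Spectrum:
    """A spectrum equal to ``base`` except at the given {nm: value} bands."""
    refl = np.full(GRID.size, base)
    for lam, v in bands.items():
        refl[lam - GRID[0]] = v
    return Spectrum(refl)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_spectrum():
    return make_flat(0.3)


@pytest.fixture(scope="session")
def tiny_campaign():
    """1 array per treatment, 2 trees, 2 dates, 5 leaves: 40 spectra."""
    return simulate_campaign(LeafSimConfig(
        n_arrays_per_treatment=1, n_trees_per_array=2,
        dates=("2023-07-25", "2023-08-10"),
        n_leaves_per_tree_per_date=5, seed=11,
    ))


@pytest.fixture(scope="session")
def study_campaign():
    """Full study-shaped campaign at the realized 469/463 totals."""
    return simulate_campaign(LeafSimConfig(
        seed=5, treatment_totals={"aCO2": 469, "eCO2": 463},
    ))
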