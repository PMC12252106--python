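import itertools

import numpy as np
import pytest

from ramanmix.cube import SpectralAxis, Spectrum
from ramanmix.unmixing import simplex_volume


@pytest.fixture
def axis1601():
    """Default phantom axis: 300-3500 cm-1 at 2 cm-1 spacing."""
    return SpectralAxis(300.0 + 2.0 * np.arange(1601))


@pytest.fixture
def band_spectrum(axis1601):
    """Smooth Gaussian band (FWHM 40 cm-1) on a constant offset, no noise."""
    wn = axis1601.wavenumbers
    y = 0.3 + np.exp(-4 * np.log(2) * ((wn - 1500) / 40) ** 2)
    return Spectrum(axis1601, y)


def exhaustive_max_volume(coords: np.ndarray, p: int) -> tuple[set, float]:
    """Brute-force max-volume vertex search (independent N-FINDR oracle)."""
    best, best_vol = None, -1.0
    for comb in itertools.combinations(range(coords.shape[0]), p):
        vol = simplex_volume(coords[list(comb)])
        if vol > best_vol:
            best_vol, best = vol, set(comb)
    return best, best_vol
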