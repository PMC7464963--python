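"""Shared fixtures: small trial designs and coarse spectral grids that keep
unit tests fast while exercising the same code paths as full-scale runs."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from cecalomics.design import MetaboliteSpec, Peak, TrialDesign
from cecalomics.simulate import PpmGrid


@pytest.fixture
def small_design() -> TrialDesign:
    """Three groups, three days, 5 birds per cell, no dropouts."""
    return TrialDesign(n_per_group_per_time=5, dropouts={}, seed=3)


@pytest.fixture
def coarse_grid() -> PpmGrid:
    """4x coarser ppm axis; pair with points_per_bin=25 for 0.0183-ppm bins."""
    return PpmGrid(-0.5, 9.5, 7.32e-4)


@pytest.fixture
def one_singlet() -> MetaboliteSpec:
    """Single isolated resonance with a flat time trend, noiseless."""
    return MetaboliteSpec(
        "probe",
        (Peak(2.0),),
        {g: (1.0, 0.0) for g in ("A", "B", "C")},
        noise_sd=0.0,
    )


def lorentzian_spectrum(ppm, centers, heights, gamma=0.002):
    """Direct sum of unit-height-scaled Lorentzians (test-side construction)."""
    y = np.zeros_like(ppm)
    for c, h in zip(centers, heights):
        y += h * gamma**2 / ((ppm - c) ** 2 + gamma**2)
    return y
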