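"""Shared fixtures: small deterministic phantoms and grids.

All fixtures are generated programmatically; nothing is read from disk
except the packaged cohort table.
"""

from __future__ import annotations

import numpy as np
import pytest

from hsimargin import PhantomParams, generate_phantom, make_wavelength_grid
from hsimargin.synthetic import EndmemberSpec


@pytest.fixture(scope="session")
def default_grid():
    return make_wavelength_grid()


def small_params(**overrides) -> PhantomParams:
    """100x100 phantom that trains in seconds."""
    base = dict(
        height=100,
        width=100,
        core_centre=(50.0, 50.0),
        core_semi_axes=(25.0, 18.0),
        n_lobes=2,
        lobe_scale=10.0,
        seed=7,
    )
    base.update(overrides)
    return PhantomParams(**base)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_params(), lesion_id="fixture-small")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and illumination-free phantom with a hard margin."""
    return generate_phantom(
        small_params(noise_sd=0.0, illum_amplitude=0.0, boundary_blur_px=0.0),
        lesion_id="fixture-clean",
    )
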