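"""Shared fixtures.  Monte Carlo work is session-scoped and deliberately small:
the problem sizes here trade statistical precision for runtime, and every
tolerance in the tests accounts for that.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from layerlut import (
    LayeredMedium,
    LUTAxes,
    OpticalLayer,
    SimConfig,
    build_lut_pair,
    homogeneous_medium,
    pool_batches,
    run_layered_mc,
    tissue_medium,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


#: Desk-scale transport settings used throughout the suite: isotropized
#: (similarity) scattering, a wide detector annulus for counting efficiency and
#: a path cap that Beer weights render negligible for mua >= 0.005 mm^-1.
FAST = SimConfig(
    n_photons=60_000,
    detector_half_width=2.0,
    max_total_path=1800.0,
    phase_mode="reduced",
    seed=0,
)

#: Reduced musp axis for round-trip tests (contains the truth used in them).
SMALL_AXES = LUTAxes(musp_min=0.3, musp_max=0.9)


@pytest.fixture(scope="session")
def fast_sim() -> SimConfig:
    return FAST


@pytest.fixture(scope="session")
def small_axes() -> LUTAxes:
    return SMALL_AXES


@pytest.fixture(scope="session")
def homog_medium() -> LayeredMedium:
    """Homogeneous semi-infinite reference medium (mua 0.01, musp 1.0, n 1.4)."""
    return LayeredMedium(
        (
            OpticalLayer(
                "homog",
                math.inf,
                {730.0: 0.01, 830.0: 0.01},
                {730.0: 1.0, 830.0: 1.0},
                0.9,
                1.4,
                bfi=1e-6,
            ),
        )
    )


@pytest.fixture(scope="session")
def homog_batch(homog_medium):
    """A well-populated homogeneous white-MC batch for oracle comparisons."""
    sims = [FAST.with_(n_photons=200_000, seed=100 + i) for i in range(3)]
    return pool_batches([run_layered_mc(homog_medium, s, 830.0) for s in sims])


@pytest.fixture(scope="session")
def tissue_luts(fast_sim, small_axes):
    """Small multi-layer LUT pair (FD 830 nm / DCS) for a light-tone subject."""
    base = tissue_medium("light", 2.0)
    fd, dcs = build_lut_pair(
        base, small_axes, fast_sim.with_(seed=7), 830.0, 149e6,
        mua_bottom=0.02, n_repeats=2,
    )
    return {"medium": base, "fd": fd, "dcs": dcs}
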