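"""Shared fixtures: a synthetic monolayer profile and standard fit inputs.

Everything is generated programmatically and seeded; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from mononr import (
    compute_nd_profiles,
    symmetrize_leaflets,
    water_volume_fraction,
)
from mononr.synth import (
    MonolayerSpec,
    default_true_params,
    gen_monolayer_frames,
    gen_reflectivity_data,
)


@pytest.fixture(scope="session")
def monolayer_frames():
    """Three frames of the default double-monolayer cell at APL 50 Å²."""
    return gen_monolayer_frames(MonolayerSpec(apl=50.0), n_frames=3, seed=1)


@pytest.fixture(scope="session")
def monolayer_profile(monolayer_frames):
    """Symmetrized density profile with normalized water fraction."""
    profile = compute_nd_profiles(monolayer_frames)
    return water_volume_fraction(symmetrize_leaflets(profile))


@pytest.fixture(scope="session")
def q_grid():
    """Measured momentum-transfer range, 60 log-spaced points (Å⁻¹)."""
    return np.geomspace(0.01, 0.6, 60)


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def noisy_datasets(monolayer_profile, q_grid, true_params):
    """Seven-contrast synthetic data at 5% relative noise."""
    return gen_reflectivity_data(
        monolayer_profile, noise_rel=0.05, q_grid=q_grid, seed=11,
        true_params=true_params,
    )
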