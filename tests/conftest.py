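"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from utebone import (
    PhantomGeometry,
    PhantomSpec,
    TissueModel,
    VoxelGrid,
    generate_cohort,
    generate_phantom,
)
from utebone.cli import train_from_cases


@pytest.fixture(scope="session")
def default_cohort():
    """Ten phantoms under the default study conditions (jittered gains)."""
    return generate_cohort(10, PhantomSpec(), jitter_sd=0.1, seed=1)


@pytest.fixture(scope="session")
def trained_map(default_cohort):
    """Constrained posterior map trained on the default cohort."""
    pmap, _ = train_from_cases([(c.ute, c.ct) for c in default_cohort])
    return pmap


@pytest.fixture(scope="session")
def noise_free_case():
    """Separable phantom: point-mass clusters, zero noise."""
    spec = PhantomSpec(
        tissue_model=TissueModel.noise_free(),
        noise_echo_sd=(0.0, 0.0),
        noise_ct_sd=0.0,
        rng_seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture
def small_grid():
    return VoxelGrid.centered((8, 8, 8), (2.0, 2.0, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
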