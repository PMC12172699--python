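"""Shared fixtures: phantom cohorts, templates and VOIs on the test grid.

Expensive objects (template pairs, rendered phantoms) are session-scoped so
registration-heavy tests share them instead of regenerating.
"""

import numpy as np
import pytest

from centiloid.adaptive_template import TemplatePair, build_template
from centiloid.phantom import (PhantomSpec, default_grid, make_cohort,
                               make_voi_set, render_pet)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def vois(grid):
    return make_voi_set(grid)


@pytest.fixture(scope="session")
def template_pair():
    """Aneg/Apos built by averaging small seeded phantom cohorts."""
    neg = make_cohort(10, 0, seed=100, psf_fwhm=8.0, noise_sd=0.02)
    pos = make_cohort(0, 10, seed=200, psf_fwhm=8.0, noise_sd=0.02)
    return TemplatePair(
        build_template([v for v, _ in neg], "negative"),
        build_template([v for v, _ in pos], "positive"),
    )


@pytest.fixture(scope="session")
def reference_phantom():
    """A mildly amyloid-positive, blurred, noisy phantom (registration target)."""
    return render_pet(PhantomSpec(burden=0.2, psf_fwhm=8.0, noise_sd=0.02, seed=1))


@pytest.fixture(scope="session")
def sample_points(grid):
    """World coordinates of every 7th voxel centre, for displacement stats."""
    shape, affine = grid
    idx = np.indices(shape, dtype=float).reshape(3, -1)[:, ::7]
    return (affine[:3, :3] @ idx + affine[:3, 3:4]).T
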