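import numpy as np
import pytest

from qsmfid.core import GridMeta
from qsmfid.phantom import InclusionSpec, PhantomSpec, rasterize_phantom


@pytest.fixture(scope="session")
def small_grid():
    """Isotropic cube grid for operator-level tests."""
    return GridMeta.centered((64, 64, 64), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def pelvis_grid():
    """Anisotropic grid matching the acquisition protocol voxels."""
    return GridMeta.centered((96, 96, 48), (1.0, 1.0, 2.0))


def make_body_phantom(grid, inclusions, body_semi=(36.0, 32.0, 36.0),
                      prostate_semi=(10.0, 10.0, 10.0), oversample=2):
    """Small pelvis-like phantom: ellipsoidal body, central prostate."""
    body = InclusionSpec("ellipsoid", (0.0, 0.0, 0.0), body_semi,
                         chi=0.0, r2star=30.0, m0=1.0, label="tissue")
    prostate = InclusionSpec("ellipsoid", (0.0, 0.0, 0.0), prostate_semi,
                             chi=0.0, r2star=25.0, m0=1.0, label="tissue")
    return PhantomSpec(grid=grid, body=body, prostate=prostate,
                       inclusions=list(inclusions), oversample=oversample,
                       noise_sigma=0.0)


@pytest.fixture(scope="session")
def body_mask_small(pelvis_grid):
    spec = make_body_phantom(pelvis_grid, [])
    _, _, _, truth = rasterize_phantom(spec)
    return truth.masks["body"]
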