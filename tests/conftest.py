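import numpy as np
import pytest

from synquant import ImageStack, SceneConfig, make_bead_scene, make_spreading_scene

NOISELESS = {"noise": (0.0, 0.0)}


@pytest.fixture(scope="session")
def bead_scene():
    """One noiseless bead-conjugate scene with mild polarization."""
    cfg = SceneConfig(polarization_kappa=2.0, seed=7, **NOISELESS)
    return make_bead_scene(cfg)


@pytest.fixture(scope="session")
def spreading_scene():
    """One noiseless spreading scene with an axial gradient."""
    cfg = SceneConfig(axial_bias=2.0, seed=11, **NOISELESS)
    return make_spreading_scene(cfg)


def uniform_stack(
    shape=(4, 40, 40), value=1.0, roles=("LAMP", "LC3", "OVA"), pixel=0.1, step=0.2
) -> ImageStack:
    """Constant-intensity stack: the null case for every ratio metric."""
    vox = np.full((len(roles),) + shape, value, dtype=np.float64)
    return ImageStack(
        voxels=vox,
        pixel_size_um=pixel,
        slice_step_um=step,
        channel_roles={r: i for i, r in enumerate(roles)},
    )


def delta_stack(shape_yx=(41, 41), points=(), roles=("LAMP",), pixel=0.1):
    """Single-slice stack with unit intensity at the given (y, x) pixels."""
    img = np.zeros((len(roles), 1) + shape_yx)
    for y, x, v in points:
        img[0, 0, y, x] = v
    return ImageStack(
        voxels=img,
        pixel_size_um=pixel,
        slice_step_um=0.2,
        channel_roles={r: i for i, r in enumerate(roles)},
    )


def disk_mask(shape_yx, cy, cx, r):
    yy, xx = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
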