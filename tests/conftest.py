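import numpy as np
import pytest

import vesselrad as vr


@pytest.fixture(scope="session")
def cylinder_r2():
    """Straight z-axis cylinder, radius 2 mm, isotropic 1 mm grid."""
    spec = vr.PhantomSpec(kind="cylinder", radius_mm=2.0, length_mm=40.0, spacing=(1, 1, 1))
    return vr.make_cylinder(spec)


@pytest.fixture(scope="session")
def cylinder_r4():
    """Radius 4 mm, 1 mm grid; long enough (100 mm) that the flat-cap end
    annulus (volume fraction ~ 4*spacing/length) stays a small minority."""
    spec = vr.PhantomSpec(kind="cylinder", radius_mm=4.0, length_mm=100.0, spacing=(1, 1, 1))
    return vr.make_cylinder(spec)


@pytest.fixture(scope="session")
def bent_tube():
    spec = vr.PhantomSpec(kind="bent_tube", radius_mm=3.0, length_mm=40.0, spacing=(1, 1, 1))
    return vr.make_bent_tube(spec)


@pytest.fixture(scope="session")
def small_tree():
    spec = vr.PhantomSpec(
        kind="tree", radius_mm=2.2, length_mm=12.0, spacing=(1.0, 0.9, 1.1),
        depth=2, child_scale=0.8, seed=3,
    )
    return vr.make_tree(spec)


def random_blob_mask(seed: int, shape=(9, 9, 9), spacing=(1.0, 1.0, 1.0), p=0.25):
    """Random sparse foreground mask for oracle comparisons."""
    rng = np.random.default_rng(seed)
    labels = (rng.random(shape) < p).astype(np.uint8)
    labels[0, :, :] = labels[-1, :, :] = 0
    labels[:, 0, :] = labels[:, -1, :] = 0
    labels[:, :, 0] = labels[:, :, -1] = 0
    return vr.VoxelMask(labels=labels, spacing=spacing)


def random_small_phantom(seed: int):
    """Random phantom with <= 1e4 foreground voxels, varied kind/spacing."""
    rng = np.random.default_rng(seed)
    kind = ["cylinder", "bent_tube", "tree"][int(rng.integers(3))]
    spacing = tuple(float(s) for s in rng.uniform(0.7, 1.3, size=3))
    radius = float(rng.uniform(max(spacing), 3.2))
    if kind == "tree":
        depth = int(rng.integers(0, 4))
        scale = float(rng.uniform(0.7, 1.0))
        while radius * scale**depth < max(spacing):
            depth -= 1
        spec = vr.PhantomSpec(kind=kind, radius_mm=radius, length_mm=float(rng.uniform(8, 16)),
                              spacing=spacing, depth=depth, child_scale=scale,
                              seed=int(rng.integers(2**31)))
    else:
        direction = tuple(float(d) for d in rng.normal(size=3)) if kind == "cylinder" else (0, 0, 1)
        spec = vr.PhantomSpec(kind=kind, radius_mm=radius, length_mm=float(rng.uniform(15, 35)),
                              spacing=spacing, direction=direction,
                              seed=int(rng.integers(2**31)))
    mask, truth = vr.make_phantom(spec)
    assert mask.foreground_count() <= 10_000
    return mask, truth
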