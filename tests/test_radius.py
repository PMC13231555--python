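import numpy as np
import pytest

import vesselrad as vr
from vesselrad.radius import PROV_CENTERLINE, PROV_CONSTRAINED, PROV_FALLBACK

from conftest import random_blob_mask, random_small_phantom


def _edt_bruteforce(mask, compartment="all"):
    """Independent EDT oracle: exhaustive min over background voxel centers."""
    fg = mask.foreground(compartment)
    sp = np.asarray(mask.spacing)
    fg_idx = np.argwhere(fg).astype(float) * sp
    bg_idx = np.argwhere(~fg).astype(float) * sp
    out = np.zeros(mask.shape)
    for (i, j, k), w in zip(np.argwhere(fg), fg_idx):
        out[i, j, k] = np.sqrt(((bg_idx - w) ** 2).sum(axis=1).min())
    return out


class TestEDT:
    def test_single_voxel_unit_distance(self):
        labels = np.zeros((3, 3, 3), np.uint8)
        labels[1, 1, 1] = 1
        dm = vr.compute_edt(vr.VoxelMask(labels=labels, spacing=(1, 1, 1)))
        assert dm.edt[1, 1, 1] == 1.0
        assert (dm.edt > 0).sum() == 1

    @pytest.mark.parametrize("seed,spacing", [(0, (1, 1, 1)), (1, (0.5, 0.8, 1.2)), (2, (2, 1, 1))])
    def test_matches_bruteforce_oracle(self, seed, spacing):
        """Anisotropic EDT equals the exhaustive pairwise-distance scan."""
        mask = random_blob_mask(seed, spacing=spacing)
        dm = vr.compute_edt(mask)
        assert np.allclose(dm.edt, _edt_bruteforce(mask), atol=1e-9)

    def test_metric_scaling(self):
        mask1 = random_blob_mask(5, spacing=(1, 1, 1))
        mask2 = vr.VoxelMask(labels=mask1.labels, spacing=(0.5, 0.5, 0.5))
        assert np.allclose(vr.compute_edt(mask2).edt, 0.5 * vr.compute_edt(mask1).edt)

    def test_empty_foreground_is_not_an_error(self):
        dm = vr.compute_edt(vr.VoxelMask(labels=np.zeros((4, 4, 4), np.uint8), spacing=(1, 1, 1)))
        assert (dm.edt == 0).all()

    def test_all_foreground_rejected(self):
        with pytest.raises(vr.GeometryError):
            vr.compute_edt(vr.VoxelMask(labels=np.ones((4, 4, 4), np.uint8), spacing=(1, 1, 1)))


class TestCenterline:
    def test_thin_line_is_its_own_skeleton(self):
        labels = np.zeros((7, 7, 12), np.uint8)
        labels[3, 3, 2:10] = 1
        mask = vr.VoxelMask(labels=labels, spacing=(1, 1, 1))
        cl = vr.extract_centerline(mask)
        assert len(cl) == 8
        assert {tuple(p) for p in cl.points} == {(3, 3, z) for z in range(2, 10)}

    def test_isolated_voxel_is_a_centerline_point(self):
        labels = np.zeros((5, 5, 5), np.uint8)
        labels[2, 2, 2] = 1
        cl = vr.extract_centerline(vr.VoxelMask(labels=labels, spacing=(1, 1, 1)))
        assert [tuple(p) for p in cl.points] == [(2, 2, 2)]
        assert cl.radius[0] == 1.0

    def test_empty_mask_gives_empty_set(self):
        cl = vr.extract_centerline(vr.VoxelMask(labels=np.zeros((4, 4, 4), np.uint8), spacing=(1, 1, 1)))
        assert len(cl) == 0

    def test_radius_equals_edt_exactly(self, small_tree):
        mask, _ = small_tree
        dm = vr.compute_edt(mask, "artery")
        cl = vr.extract_centerline(mask, "artery", dm)
        assert (cl.radius == dm.edt[tuple(cl.points.T)]).all()
        # every point is a foreground voxel
        assert (mask.labels[tuple(cl.points.T)] > 0).all()

    def test_cylinder_skeleton_follows_axis(self, cylinder_r4):
        """>= 90% of skeleton points lie within one voxel of the analytic axis."""
        mask, truth = cylinder_r4
        cl = vr.extract_centerline(mask, "artery")
        axis = truth.centerline_points(step_mm=0.1)
        world = cl.world()
        d = np.sqrt(((world[:, None, :] - axis[None, :, :]) ** 2).sum(-1)).min(1)
        assert (d <= max(mask.spacing)).mean() >= 0.90


class TestPropagation:
    def test_all_centerline_identity(self):
        """A 1-voxel-wide mask is pure centerline: no constrained/fallback voxels."""
        labels = np.zeros((5, 5, 12), np.uint8)
        labels[2, 2, 2:10] = 1
        mask = vr.VoxelMask(labels=labels, spacing=(1, 1, 1))
        cl = vr.extract_centerline(mask)
        field = vr.propagate_radius(mask, cl)
        fg = field.provenance > 0
        assert (field.provenance[fg] == PROV_CENTERLINE).all()
        assert np.allclose(field.radius[tuple(cl.points.T)], cl.radius)

    def test_cylinder_recovery(self, cylinder_r4):
        """r=4 mm, 1 mm grid: >= 95% of voxels within 15% of the true radius."""
        mask, _ = cylinder_r4
        field = vr.radius_pipeline(mask, "artery")
        fg = field.provenance > 0
        rel = np.abs(field.radius[fg] - 4.0) / 4.0
        assert (rel <= 0.15).mean() >= 0.95
        med = np.median(field.radius[fg])
        assert 0.0 <= med - 4.0 <= 0.75 * max(mask.spacing)

    def test_coverage_every_foreground_voxel_assigned(self, small_tree):
        mask, _ = small_tree
        field = vr.radius_pipeline(mask, "artery")
        assert np.array_equal(field.provenance > 0, mask.labels > 0)
        assert (field.radius[field.provenance > 0] > 0).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_fast_equals_bruteforce(self, seed):
        """KD-tree-accelerated propagation is bit-identical to the O(N*M) scan."""
        mask, _ = random_small_phantom(seed)
        cl = vr.extract_centerline(mask, "artery")
        fast = vr.propagate_radius(mask, cl, "artery")
        brute = vr.propagate_radius_bruteforce(mask, cl, "artery")
        assert np.array_equal(fast.radius, brute.radius)
        assert np.array_equal(fast.provenance, brute.provenance)

    def test_equidistant_candidates_prefer_larger_radius(self):
        """A voxel exactly between two admissible donors takes the larger radius."""
        labels = np.zeros((3, 3, 7), np.uint8)
        labels[1, 1, 1:6] = 1
        mask = vr.VoxelMask(labels=labels, spacing=(1, 1, 1))
        cl = vr.CenterlineSet(
            points=np.array([[1, 1, 1], [1, 1, 5]]), radius=np.array([2.5, 3.0]),
            spacing=(1, 1, 1), compartment="all",
        )
        field = vr.propagate_radius(mask, cl)
        assert field.radius[1, 1, 3] == 3.0  # equidistant (2.0 mm), larger radius wins
        assert field.provenance[1, 1, 3] == PROV_CONSTRAINED

    def test_fallback_tie_prefers_larger_radius(self):
        """Without any admissible donor, the nearest-point tie also takes the
        larger radius."""
        labels = np.zeros((3, 3, 9), np.uint8)
        labels[1, 1, :] = 1
        mask = vr.VoxelMask(labels=labels, spacing=(1, 1, 1))
        cl = vr.CenterlineSet(
            points=np.array([[1, 1, 0], [1, 1, 8]]), radius=np.array([0.5, 0.6]),
            spacing=(1, 1, 1), compartment="all",
        )
        field = vr.propagate_radius(mask, cl)
        assert field.provenance[1, 1, 4] == PROV_FALLBACK
        assert field.radius[1, 1, 4] == 0.6

    def test_scaling_covariance(self, small_tree):
        """Doubling the spacing doubles every propagated radius."""
        mask, _ = small_tree
        doubled = vr.VoxelMask(labels=mask.labels, spacing=tuple(2 * s for s in mask.spacing))
        f1 = vr.radius_pipeline(mask, "artery")
        f2 = vr.radius_pipeline(doubled, "artery")
        assert np.array_equal(f1.provenance, f2.provenance)
        assert np.allclose(f2.radius, 2.0 * f1.radius, rtol=1e-12, atol=0)

    def test_empty_centerline_with_foreground_raises(self):
        labels = np.zeros((4, 4, 4), np.uint8)
        labels[1:3, 1:3, 1:3] = 1
        mask = vr.VoxelMask(labels=labels, spacing=(1, 1, 1))
        cl = vr.CenterlineSet(points=np.empty((0, 3), np.int64), radius=np.empty(0),
                              spacing=(1, 1, 1), compartment="all")
        with pytest.raises(vr.PropagationError):
            vr.propagate_radius(mask, cl)

    def test_bent_tube_fallback_fraction(self, bent_tube):
        """On a 90-degree bend, at most 5% of voxels need the fallback rule."""
        mask, _ = bent_tube
        field = vr.radius_pipeline(mask, "artery")
        assert field.fallback_fraction <= 0.05

    def test_edge_correction_subtracts_half_voxel(self, cylinder_r4):
        mask, _ = cylinder_r4
        raw = vr.radius_pipeline(mask, "artery")
        corr = vr.radius_pipeline(mask, "artery", edge_correction=True)
        fg = raw.provenance > 0
        assert np.allclose(corr.radius[fg], raw.radius[fg] - 0.5)

    def test_compartments_processed_independently(self):
        """Arterial voxels never borrow a venous centerline radius."""
        labels = np.zeros((26, 12, 32), np.uint8)
        spec_a = vr.PhantomSpec(kind="cylinder", radius_mm=3.0, length_mm=20, spacing=(1, 1, 1))
        mask_a, _ = vr.make_cylinder(spec_a)
        spec_v = vr.PhantomSpec(kind="cylinder", radius_mm=1.5, length_mm=20, spacing=(1, 1, 1))
        mask_v, _ = vr.make_cylinder(spec_v)
        sa, sv = mask_a.labels.shape, mask_v.labels.shape
        labels[: sa[0], : sa[1], : sa[2]] = mask_a.labels
        sub = labels[16 : 16 + sv[0], : sv[1], : sv[2]]
        sub[mask_v.labels > 0] = 2
        mask = vr.VoxelMask(labels=labels, spacing=(1, 1, 1))
        field = vr.radius_field_per_compartment(mask)
        artery_r = field.radius[mask.labels == 1]
        vein_r = field.radius[mask.labels == 2]
        assert np.median(artery_r) > 2.5
        assert vein_r.max() < 2.5  # small tube never inherits the large tube's radius
        assert np.array_equal(field.provenance > 0, mask.labels > 0)
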