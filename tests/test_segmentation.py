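"""Thresholding, cortex-region closing, marrow and void extraction."""

import numpy as np
import pytest

import cortiquant as cq
from cortiquant import segmentation as seg
from conftest import small_spec


def exhaustive_otsu(values: np.ndarray) -> float:
    """Independent oracle: scan every grey level, minimize intra-class
    variance of the two classes it induces."""
    flat = values.ravel()
    levels = np.unique(flat)
    best_t, best_v = levels[0], np.inf
    for t in levels[1:]:
        lo, hi = flat[flat < t], flat[flat >= t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        v = len(lo) * lo.var() + len(hi) * hi.var()
        if v < best_v:
            best_v, best_t = v, t
    return best_t


class TestThresholdBone:
    def test_fixed_threshold_on_binary_volume_is_identity(self):
        vals = (np.arange(64).reshape(4, 4, 4) % 2).astype(float)
        vol = cq.VoxelVolume(vals, 1.0)
        mask = seg.threshold_bone(vol, "fixed", 0.5)
        assert np.array_equal(mask.mask, vals.astype(bool))

    def test_automatic_threshold_on_bimodal_mixture(self):
        # overlapping modes keep the intra-class-variance minimum unique
        rng = np.random.default_rng(42)
        vals = np.concatenate(
            [rng.normal(100, 15, 4000), rng.normal(200, 15, 4000)]
        ).reshape(20, 20, 20)
        vol = cq.VoxelVolume(vals, 1.0)
        mask = seg.threshold_bone(vol, "otsu")
        thr = mask.meta["threshold"]
        assert 140.0 <= thr <= 160.0
        # independent oracle: exhaustive intra-class-variance search on a
        # quantized copy; objective at both thresholds must agree
        q = np.round(vals)
        oracle = exhaustive_otsu(q)
        assert abs(oracle - thr) < 5.0

    def test_constant_volume_rejected(self):
        vol = cq.VoxelVolume(np.full((4, 4, 4), 7.0), 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            seg.threshold_bone(vol, "otsu")

    def test_intensity_shift_invariance(self, phantom_three_canals):
        _, volume, _ = phantom_three_canals
        m1 = seg.threshold_bone(volume)
        shifted = cq.VoxelVolume(volume.values + 500.0, volume.voxel_size_um)
        m2 = seg.threshold_bone(shifted)
        assert np.array_equal(m1.mask, m2.mask)


class TestCortexRegion:
    def test_closing_radius_below_one_voxel_rejected(self, solid_shell):
        _, volume, _ = solid_shell
        bone = seg.threshold_bone(volume, "fixed", 125.0)
        with pytest.raises(ValueError):
            seg.define_cortex_region(bone, 0.0)

    def test_solid_shell_closure_adds_no_voids(self, solid_shell):
        _, volume, _ = solid_shell
        bone = seg.threshold_bone(volume, "fixed", 125.0)
        cortex = seg.define_cortex_region(bone, 40.0)
        assert (bone.mask & ~cortex.mask).sum() == 0  # closing is extensive
        marrow = seg.extract_marrow(cortex)
        assert seg.extract_void_components(cortex, bone, marrow) == []

    def test_pierced_shell_tube_falls_inside_region(self, phantom_three_canals):
        spec, volume, _ = phantom_three_canals
        bone = seg.threshold_bone(volume)
        cortex = seg.define_cortex_region(bone, 40.0)
        # every carved tube voxel is inside the closed region
        from cortiquant.phantom import _carve_tube, shell_masks

        annulus, _ = shell_masks(spec)
        void = np.zeros(spec.grid_shape, dtype=bool)
        for canal in spec.canal_specs:
            _carve_tube(void, spec, canal)
        # interior of the wall: one blur-width in from both surfaces
        from scipy import ndimage

        core = ndimage.binary_erosion(annulus, iterations=2)
        tube = void & core
        assert (tube & cortex.mask).sum() / tube.sum() > 0.99


class TestExtractMarrow:
    def test_marrow_matches_carved_interior(self, solid_shell):
        spec, volume, _ = solid_shell
        from cortiquant.phantom import shell_masks

        bone = seg.threshold_bone(volume, "fixed", 125.0)
        cortex = seg.define_cortex_region(bone, 40.0)
        marrow = seg.extract_marrow(cortex)
        _, interior = shell_masks(spec)
        dice = 2 * (marrow.mask & interior).sum() / (
            marrow.mask.sum() + interior.sum()
        )
        assert dice > 0.99

    def test_solid_cylinder_has_no_cavity(self):
        mask = np.zeros((10, 20, 20), dtype=bool)
        mask[:, 5:15, 5:15] = True
        with pytest.raises(ValueError, match="marrow"):
            seg.extract_marrow(seg.MaskVolume(mask, 1.0, "cortex_region"))

    def test_two_equal_cavities_ambiguous(self):
        mask = np.ones((6, 24, 24), dtype=bool)
        mask[:, 4:8, 4:8] = False
        mask[:, 14:18, 14:18] = False
        with pytest.raises(ValueError, match="ambiguous"):
            seg.extract_marrow(seg.MaskVolume(mask, 1.0, "cortex_region"))


def brute_force_components(void: np.ndarray) -> int:
    """Flood-fill oracle with 26-connectivity."""
    seen = np.zeros_like(void, dtype=bool)
    n = 0
    idx = np.argwhere(void)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in map(tuple, idx):
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (
                    0 <= p[0] < void.shape[0]
                    and 0 <= p[1] < void.shape[1]
                    and 0 <= p[2] < void.shape[2]
                    and void[p]
                    and not seen[p]
                ):
                    seen[p] = True
                    stack.append(p)
    return n


class TestVoidComponents:
    def test_phantom_components_match_truth(self, quantified_three_canals):
        truth, result = quantified_three_canals
        assert len(result.components) == len(truth.canals) + len(truth.lacunae)
        both = [c for c in result.components if c.is_trans_cortical]
        assert len(both) == 3

    def test_two_tubes_one_voxel_apart_stay_separate(self):
        # two parallel 3x3 tubes through a bone block, 1 bone voxel between
        cortex = np.ones((10, 12, 12), dtype=bool)
        bone = np.ones((10, 12, 12), dtype=bool)
        bone[:, 3:6, 2:5] = False
        bone[:, 3:6, 6:9] = False  # gap of one bone column at x=5
        marrow = np.zeros_like(bone)
        comps = seg.extract_void_components(
            seg.MaskVolume(cortex, 1.0, "cortex_region"),
            seg.MaskVolume(bone, 1.0, "bone"),
            seg.MaskVolume(marrow, 1.0, "marrow"),
            min_voxels=1,
            min_depth_vox=0.0,
        )
        void = cortex & ~bone
        assert brute_force_components(void) == 2
        assert len(comps) == 2

    def test_extraction_deterministic(self, quantified_three_canals):
        truth, result = quantified_three_canals
        comps2 = seg.extract_void_components(
            result.cortex_region, result.bone, result.marrow
        )
        assert [c.n_voxels for c in comps2] == [
            c.n_voxels for c in result.components
        ]


def _component(volume_um3, diameter_um, trans):
    idx = (np.array([0]), np.array([0]), np.array([0]))
    return seg.VoidComponent(
        id=0,
        indices=idx,
        n_voxels=1,
        volume_um3=volume_um3,
        centroid_um=(0, 0, 0),
        touches_periosteum=trans,
        touches_endosteum=trans,
        diameter_um=diameter_um,
    )


class TestClassification:
    def test_canals_counted_foramen_excluded(self):
        comps = [_component(5000.0, 24.0, True) for _ in range(5)]
        comps.append(_component(80000.0, 80.0, True))
        seg.classify_components(comps, 2000.0, 50.0)
        labels = [c.class_label for c in comps]
        assert labels.count("canal") == 5 and labels.count("foramen") == 1

    def test_all_below_lacuna_cutoff_yields_no_canals(self):
        comps = [_component(500.0, 8.0, False) for _ in range(4)]
        seg.classify_components(comps, 2000.0, 50.0)
        assert all(c.class_label == "lacuna" for c in comps)

    def test_foramen_cutoff_is_inclusive(self):
        comp = _component(90000.0, 50.0, True)
        seg.classify_components([comp], 2000.0, 50.0)
        assert comp.class_label == "foramen"

    def test_one_surface_contact_large_component_is_partial(self):
        comp = _component(9000.0, 24.0, False)
        comp.touches_periosteum = True
        seg.classify_components([comp], 2000.0, 50.0)
        assert comp.class_label == "partial"
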