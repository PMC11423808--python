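"""Marrow axis, canal diameters, polar orientation, densities."""

import numpy as np
import pytest
from scipy.integrate import quad

import cortiquant as cq
from cortiquant import geometry as g
from cortiquant.segmentation import MaskVolume, VoidComponent


def make_marrow(nz=20, ny=64, nx=64, r=12.0, drift_x=0.0, voxel=1.0):
    """Circular marrow cylinder whose center drifts linearly in x."""
    mask = np.zeros((nz, ny, nx), dtype=bool)
    y, x = np.mgrid[0:ny, 0:nx]
    for iz in range(nz):
        cx = nx / 2 + drift_x * iz / max(nz - 1, 1)
        cy = ny / 2
        mask[iz] = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    return MaskVolume(mask, voxel, "marrow")


class TestMarrowAxis:
    def test_coaxial_cylinder_axis_is_central(self):
        marrow = make_marrow()
        axis = g.compute_marrow_axis(marrow)
        assert axis.endpoint_proximal[0] == pytest.approx(32.0, abs=0.25)
        assert axis.endpoint_proximal[1] == pytest.approx(32.0, abs=0.25)
        assert axis.endpoint_distal[2] == pytest.approx(19.0)

    def test_drifting_marrow_endpoints_match_slice_centroids(self):
        marrow = make_marrow(drift_x=10.0)
        axis = g.compute_marrow_axis(marrow)
        # brute-force per-slice centroid oracle
        for iz, endpoint in ((0, axis.endpoint_proximal), (19, axis.endpoint_distal)):
            rows, cols = np.nonzero(marrow.mask[iz])
            assert endpoint[0] == pytest.approx(cols.mean(), abs=0.5)  # x
            assert endpoint[1] == pytest.approx(rows.mean(), abs=0.5)  # y

    def test_empty_end_slice_rejected(self):
        marrow = make_marrow()
        marrow.mask[0] = False
        with pytest.raises(ValueError, match="axis undefined"):
            g.compute_marrow_axis(marrow)


def tube_component(radius_vox=5.0, length_vox=30, direction=(0, 0, 1)):
    """Voxelized straight tube along an arbitrary direction."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    span = int(length_vox + 2 * radius_vox + 4)
    zz, yy, xx = np.mgrid[0:span, 0:span, 0:span].astype(float)
    c = (span - 1) / 2.0
    p = np.stack([zz - c, yy - c, xx - c], axis=-1)
    along = p @ d
    radial = np.linalg.norm(p - along[..., None] * d, axis=-1)
    mask = (radial <= radius_vox) & (np.abs(along) <= length_vox / 2)
    idx = np.nonzero(mask)
    return VoidComponent(
        id=0,
        indices=idx,
        n_voxels=len(idx[0]),
        volume_um3=float(len(idx[0])),
        centroid_um=(0, 0, 0),
        touches_periosteum=True,
        touches_endosteum=True,
    )


class TestCanalDiameter:
    def test_axis_aligned_tube(self):
        comp = tube_component(radius_vox=5.0, direction=(0, 0, 1))
        d, fallback = g.canal_diameter(comp, 1.0)
        assert not fallback
        assert d == pytest.approx(10.0, abs=1.0)

    def test_oblique_tube_not_overestimated(self):
        comp = tube_component(radius_vox=5.0, direction=(1, 0, 1))
        d, fallback = g.canal_diameter(comp, 1.0)
        assert not fallback
        assert d == pytest.approx(10.0, abs=1.0)

    def test_single_voxel_component_uses_flagged_fallback(self):
        idx = (np.array([3]), np.array([4]), np.array([5]))
        comp = VoidComponent(0, idx, 1, 1.0, (0, 0, 0), False, False)
        d, fallback = g.canal_diameter(comp, 1.0)
        assert fallback and d == pytest.approx(2.0 / np.sqrt(np.pi), rel=1e-6)

    def test_scale_covariance_exact(self):
        comp = tube_component(radius_vox=5.0, direction=(0, 1, 1))
        d1, _ = g.canal_diameter(comp, 1.27)
        d2, _ = g.canal_diameter(comp, 2.54)
        assert d2 == 2.0 * d1


def straight_axis(z_max=100.0):
    centers = np.zeros((2, 2))
    return g.MarrowAxis((0.0, 0.0, 0.0), (0.0, 0.0, z_max), centers)


class TestCanalOrientation:
    @pytest.mark.parametrize(
        "centroid,expected",
        [((5.0, 0.0, 50.0), 0.0), ((-5.0, 0.0, 50.0), 180.0), ((1.0, 1.0, 50.0), 45.0)],
    )
    def test_reference_directions(self, centroid, expected):
        theta = g.canal_orientation(centroid, straight_axis())
        assert theta == pytest.approx(expected, abs=1e-9)

    def test_posterior_rule(self):
        assert abs(g.canal_orientation((-5.0, 0.0, 50.0), straight_axis())) > 90.0
        assert abs(g.canal_orientation((5.0, 0.1, 50.0), straight_axis())) < 90.0

    def test_centroid_on_axis_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            g.canal_orientation((0.0, 0.0, 50.0), straight_axis())

    def test_anterior_direction_rotates_frame(self):
        theta = g.canal_orientation(
            (0.0, 5.0, 50.0), straight_axis(), anterior_direction=(0.0, 1.0)
        )
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_axis_jitter_does_not_flip_classification(self, quantified_three_canals):
        truth, result = quantified_three_canals
        rng = np.random.default_rng(0)
        v = result.marrow.voxel_size_um
        for _ in range(10):
            jitter = rng.uniform(-v, v, size=4)
            axis = g.MarrowAxis(
                (
                    result.axis.endpoint_proximal[0] + jitter[0],
                    result.axis.endpoint_proximal[1] + jitter[1],
                    result.axis.endpoint_proximal[2],
                ),
                (
                    result.axis.endpoint_distal[0] + jitter[2],
                    result.axis.endpoint_distal[1] + jitter[3],
                    result.axis.endpoint_distal[2],
                ),
                result.axis.per_slice_centers,
            )
            for r in result.canal_records:
                if abs(abs(r.theta_deg) - 90.0) < 5.0:
                    continue
                theta = g.canal_orientation(r.centroid_um, axis)
                assert (abs(theta) > 90.0) == r.is_posterior


class TestPosteriorFraction:
    def test_worked_example(self):
        recs = [
            g.CanalRecord(i, "canal", (0, 0, 0), 0, 0, 0, t, abs(t) > 90)
            for i, t in enumerate([0.0, 45.0, 91.0, 179.0, -135.0])
        ]
        frac, n_post, n = g.posterior_fraction(recs)
        assert (frac, n_post, n) == (0.6, 3, 5)

    def test_all_anterior(self):
        recs = [
            g.CanalRecord(i, "canal", (0, 0, 0), 0, 0, 0, t, False)
            for i, t in enumerate([-89.0, 0.0, 89.0])
        ]
        assert g.posterior_fraction(recs)[0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no canals"):
            g.posterior_fraction([])

    def test_uniform_angles_near_half(self):
        rng = np.random.default_rng(123)
        thetas = rng.uniform(-180.0, 180.0, 1000)
        recs = [
            g.CanalRecord(i, "canal", (0, 0, 0), 0, 0, 0, t, abs(t) > 90)
            for i, t in enumerate(thetas)
        ]
        frac = g.posterior_fraction(recs)[0]
        # binomial: 3 sd of 0.5 at n=1000
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(1000)


class TestCanalDensity:
    def _recs(self, thetas):
        return [
            g.CanalRecord(i, "canal", (0, 0, 0), 0, 0, 20.0, t, abs(t) > 90)
            for i, t in enumerate(thetas)
        ]

    def test_definition_arithmetic(self):
        res = g.canal_density(self._recs([0.0] * 12), None, area_mm2=0.2)
        assert res.density_per_mm2 == pytest.approx(60.0)

    def test_empty_records_zero_density(self):
        res = g.canal_density([], None, area_mm2=0.5)
        assert res.density_per_mm2 == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            g.canal_density([], None, area_mm2=0.0)

    def test_sector_counting_with_wraparound(self):
        recs = self._recs([10.0, 170.0, -170.0, -10.0])
        post = g.canal_density(recs, (90.0, -90.0), area_mm2=1.0)
        assert post.canal_count == 2

    def test_endosteal_area_matches_analytic_ellipse_arc(self, solid_shell):
        spec, volume, _ = solid_shell
        from cortiquant import segmentation as seg

        bone = seg.threshold_bone(volume, "fixed", 125.0)
        cortex = seg.define_cortex_region(bone, 40.0)
        marrow = seg.extract_marrow(cortex)
        axis = g.compute_marrow_axis(marrow)
        area = g.endosteal_sector_area_mm2(marrow, axis, None)
        a, b = spec.inner_radii_um
        arc, _ = quad(
            lambda t: np.hypot(a * np.sin(t), b * np.cos(t)), 0, 2 * np.pi
        )
        height = (spec.grid_shape[0] - 1) * spec.voxel_size_um
        expected = arc * height * 1e-6
        assert area == pytest.approx(expected, rel=0.02)
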