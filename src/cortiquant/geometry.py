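"""Per-canal geometry against the marrow axis.

The anatomical reference frame is built from the bone itself: the z-axis is
the line through the centers of gravity of the marrow cavity in the first
(most proximal) and last (most distal) slices.  Each canal is reduced to a
centroid, a diameter (minor axis of the moment-matched ellipse of its
axis-perpendicular cross-section), and a polar angle theta measured in the
slice plane from the anterior direction at the canal's own z-level.
Posterior canals are those with ``|theta| > 90°``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .segmentation import MaskVolume, VoidComponent

__all__ = [
    "MarrowAxis",
    "CanalRecord",
    "DensityResult",
    "compute_marrow_axis",
    "canal_diameter",
    "canal_orientation",
    "canal_density",
    "endosteal_sector_area_mm2",
    "posterior_fraction",
    "wrap_angle_deg",
]


def wrap_angle_deg(theta: float | np.ndarray):
    """Wrap an angle in degrees into (-180, 180]."""
    t = np.mod(np.asarray(theta, dtype=float) + 180.0, 360.0) - 180.0
    t = np.where(t == -180.0, 180.0, t)
    return float(t) if np.isscalar(theta) or np.ndim(theta) == 0 else t


@dataclass(frozen=True)
class MarrowAxis:
    """The proximodistal reference line through the marrow cavity."""

    endpoint_proximal: tuple[float, float, float]  # (x, y, z) µm, first slice
    endpoint_distal: tuple[float, float, float]  # last slice
    per_slice_centers: np.ndarray  # (nz, 2) of (x, y) µm; NaN where empty

    def __post_init__(self) -> None:
        if self.endpoint_distal[2] == self.endpoint_proximal[2]:
            raise ValueError("axis has zero z-extent")

    def center_at(self, z_um: float) -> tuple[float, float]:
        """Point on the two-endpoint axis line at a given z-level (µm)."""
        p0 = np.asarray(self.endpoint_proximal)
        p1 = np.asarray(self.endpoint_distal)
        t = (z_um - p0[2]) / (p1[2] - p0[2])
        c = p0[:2] + t * (p1[:2] - p0[:2])
        return float(c[0]), float(c[1])


@dataclass(frozen=True)
class CanalRecord:
    """One void component reduced to the quantities the statistics use."""

    id: int
    class_label: str
    centroid_um: tuple[float, float, float]  # (x, y, z)
    z_um: float
    volume_um3: float
    diameter_um: float
    theta_deg: float
    is_posterior: bool


@dataclass(frozen=True)
class DensityResult:
    region_label: str
    canal_count: int
    reference_area_mm2: float
    density_per_mm2: float


def compute_marrow_axis(marrow: MaskVolume) -> MarrowAxis:
    """Line through the marrow centroids of the first and last slices.

    Per-slice centroids are stored alongside for diagnostics; the axis
    itself uses only the two end slices.
    """
    m = marrow.mask
    v = marrow.voxel_size_um
    nz = m.shape[0]
    if not m[0].any() or not m[-1].any():
        raise ValueError("axis undefined: marrow absent in an end slice")
    centers = np.full((nz, 2), np.nan)
    for iz in range(nz):
        sl = m[iz]
        if sl.any():
            cy, cx = ndimage.center_of_mass(sl)
            centers[iz] = (cx * v, cy * v)
    p0 = (centers[0, 0], centers[0, 1], 0.0)
    p1 = (centers[-1, 0], centers[-1, 1], (nz - 1) * v)
    return MarrowAxis(
        endpoint_proximal=p0, endpoint_distal=p1, per_slice_centers=centers
    )


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest second central moment."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(c)
    w, vecs = np.linalg.eigh(cov)
    return vecs[:, -1]


def canal_diameter(
    component: VoidComponent, voxel_size_um: float
) -> tuple[float, bool]:
    """Diameter of a void component, in µm.

    The canal axis is estimated from the second central moments of the
    component's voxel coordinates; the voxels are then projected onto the
    plane perpendicular to that axis (a tube projects onto exactly its
    cross-sectional footprint), and the minor axis of the moment-matched
    ellipse of the projection is the diameter.  The cut is perpendicular to
    the *canal* axis, not the image z-axis, so oblique canals are not
    overestimated.  Because a short, wide tube (the nutrient foramen) has
    its *largest* moment across rather than along the tube, every
    eigenvector is tried as a candidate axis and the one whose projected
    footprint is most circular wins.

    Returns ``(diameter_um, used_fallback)``; the fallback (equivalent-
    circle diameter of the largest single-slice section) engages for
    degenerate components with too few voxels for a stable moment fit.
    """
    zz, yy, xx = component.indices
    coords = np.column_stack([zz, yy, xx]).astype(float)
    if len(coords) >= 4:
        centered = coords - coords.mean(axis=0)
        cov = centered.T @ centered / len(centered)
        _, vecs = np.linalg.eigh(cov)
        best: tuple[float, float] | None = None
        for k in range(3):
            axis = vecs[:, k]
            ref = np.array([1.0, 0.0, 0.0])
            if abs(axis[0]) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            # thick mid-slab: complete cross-sections away from the beveled
            # ends where the tube meets the curved surfaces; a single-voxel
            # slab would alias against the lattice, a full projection would
            # be weighted by the bevels
            along = centered @ axis
            slab = np.abs(along) <= 2.5
            pts = centered[slab]
            if len(pts) < 3:
                continue
            q = np.column_stack([pts @ e1, pts @ e2])
            q -= q.mean(axis=0)
            cov2 = q.T @ q / len(q)
            w = np.linalg.eigvalsh(cov2)
            if w[0] <= 0:
                continue
            aspect = np.sqrt(w[1] / w[0])
            minor = 4.0 * np.sqrt(w[0])
            if best is None or aspect < best[0]:
                best = (aspect, minor)
        if best is not None:
            return best[1] * voxel_size_um, False
    # fallback: equivalent circle of the largest single-slice section
    counts = np.bincount(zz - zz.min())
    area_um2 = counts.max() * voxel_size_um**2
    return 2.0 * np.sqrt(area_um2 / np.pi), True


def canal_orientation(
    centroid_um: tuple[float, float, float],
    axis: MarrowAxis,
    anterior_direction: tuple[float, float] = (1.0, 0.0),
) -> float:
    """Signed polar angle of a canal centroid about the marrow axis.

    The reference point is taken on the two-endpoint axis *line* at the
    canal's z-level.  Theta is measured from ``anterior_direction`` in the
    slice plane, positive toward +y, in (-180, 180].
    """
    cx, cy, cz = centroid_um
    rx, ry = axis.center_at(cz)
    d = np.array([cx - rx, cy - ry])
    if np.linalg.norm(d) < 1e-9:
        raise ValueError("undefined orientation: centroid on the axis")
    a = np.asarray(anterior_direction, dtype=float)
    a = a / np.linalg.norm(a)
    perp = np.array([-a[1], a[0]])  # +90° from anterior, toward +y
    theta = np.degrees(np.arctan2(d @ perp, d @ a))
    return wrap_angle_deg(theta)


def endosteal_sector_area_mm2(
    marrow: MaskVolume,
    axis: MarrowAxis,
    sector_deg: tuple[float, float] | None = None,
    anterior_direction: tuple[float, float] = (1.0, 0.0),
) -> float:
    """Endocortical surface area of an angular sector, in mm².

    Computed as the per-slice marrow contour arc length restricted to the
    sector, times the slice thickness, summed over slices.  ``sector_deg``
    is ``(lo, hi)`` in (-180, 180] degrees (wrap-around allowed, e.g.
    ``(90, -90)`` for the posterior half); ``None`` means the full surface.
    """
    v = marrow.voxel_size_um
    a = np.asarray(anterior_direction, dtype=float)
    a = a / np.linalg.norm(a)
    perp = np.array([-a[1], a[0]])
    total_um2 = 0.0
    for iz in range(marrow.mask.shape[0]):
        sl = marrow.mask[iz]
        if not sl.any():
            continue
        cx, cy = axis.center_at(iz * v)
        # smooth the binary slice before contouring: marching squares on raw
        # binary data yields a staircase whose length overestimates a smooth
        # anatomical boundary by several percent
        padded = ndimage.gaussian_filter(np.pad(sl.astype(float), 4), 2.0)
        for contour in measure.find_contours(padded, 0.5):
            pts = (contour - 4.0) * v  # (row=y, col=x) µm
            seg = np.diff(pts, axis=0)
            lengths = np.hypot(seg[:, 0], seg[:, 1])
            if sector_deg is None:
                total_um2 += lengths.sum() * v
                continue
            mid = 0.5 * (pts[:-1] + pts[1:])
            dx = mid[:, 1] - cx
            dy = mid[:, 0] - cy
            theta = wrap_angle_deg(np.degrees(np.arctan2(dx * perp[0] + dy * perp[1],
                                                         dx * a[0] + dy * a[1])))
            lo, hi = sector_deg
            if lo <= hi:
                keep = (theta >= lo) & (theta <= hi)
            else:
                keep = (theta >= lo) | (theta <= hi)
            total_um2 += lengths[keep].sum() * v
    return total_um2 * 1e-6


def canal_density(
    records,
    sector_deg: tuple[float, float] | None = None,
    *,
    area_mm2: float | None = None,
    marrow: MaskVolume | None = None,
    axis: MarrowAxis | None = None,
    region_label: str = "whole",
    anterior_direction: tuple[float, float] = (1.0, 0.0),
) -> DensityResult:
    """Canal count per mm² of endocortical surface within a sector.

    Counts records with ``class_label == "canal"`` whose theta falls in the
    sector.  The reference area is either given directly (``area_mm2``) or
    computed from the marrow mask via :func:`endosteal_sector_area_mm2`.
    """
    if area_mm2 is None:
        if marrow is None or axis is None:
            raise ValueError("need area_mm2 or (marrow, axis)")
        area_mm2 = endosteal_sector_area_mm2(
            marrow, axis, sector_deg, anterior_direction
        )
    if area_mm2 <= 0:
        raise ValueError("zero reference area")
    count = 0
    for r in records:
        if r.class_label != "canal":
            continue
        if sector_deg is None:
            count += 1
            continue
        lo, hi = sector_deg
        t = r.theta_deg
        inside = (lo <= t <= hi) if lo <= hi else (t >= lo or t <= hi)
        count += inside
    return DensityResult(
        region_label=region_label,
        canal_count=count,
        reference_area_mm2=area_mm2,
        density_per_mm2=count / area_mm2,
    )


def posterior_fraction(records) -> tuple[float, int, int]:
    """Fraction of canals in the posterior half (``|theta| > 90°``).

    Returns ``(fraction, n_posterior, n_total)``.
    """
    thetas = [r.theta_deg for r in records]
    if not thetas:
        raise ValueError("no canals")
    n_post = sum(abs(t) > 90.0 for t in thetas)
    return n_post / len(thetas), n_post, len(thetas)
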