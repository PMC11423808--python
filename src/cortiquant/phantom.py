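"""Synthetic CT phantoms of a long-bone diaphysis with known canal geometry.

The phantom emulates the kind of volume a nano-CT scan of a juvenile mouse
fibula produces: a hollow, roughly elliptic-cylindrical cortical shell
containing straight tubular trans-cortical canals, small ellipsoidal
osteocyte lacunae, optionally one large nutrient foramen, partial-volume
blur and additive Gaussian noise.  Every structure carved into the volume is
echoed in a :class:`PhantomTruth` ledger, so the phantom doubles as an exact
oracle for the downstream segmentation and morphometry stages.

Conventions
-----------
Axes are ``(z, y, x)`` with ``z`` the proximodistal slice index.  The
anatomical *anterior* direction is fixed as ``+x``; polar angles ``theta``
are measured in the slice plane from anterior, positive toward ``+y``, and
reported in ``(-180, 180]`` degrees.  Physical coordinates are in µm from
the voxel-center of index 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CanalSpec",
    "ForamenSpec",
    "PhantomSpec",
    "PhantomTruth",
    "CanalTruth",
    "LacunaTruth",
    "PhantomSpecError",
    "PhantomOverlapError",
    "generate_phantom",
    "generate_contour_pair",
    "random_phantom_spec",
    "posterior_contrast_spec",
]

# Nano-CT sampling of the study this phantom emulates (µm per voxel).
DEFAULT_VOXEL_SIZE_UM = 1.27


class PhantomSpecError(ValueError):
    """The phantom specification violates one of its invariants."""


class PhantomOverlapError(RuntimeError):
    """Void structures merged into one component; truth would be ambiguous."""


@dataclass(frozen=True)
class CanalSpec:
    """One straight tubular canal piercing the cortex.

    theta_deg : polar position around the shell, anterior = 0, in (-180, 180].
    z_frac : fractional height of the piercing point, in (0, 1).
    diameter_um : tube diameter.
    inclination_deg : tilt of the tube axis out of the slice plane
        (0 = purely radial).
    """

    theta_deg: float
    z_frac: float
    diameter_um: float
    inclination_deg: float = 0.0


@dataclass(frozen=True)
class ForamenSpec:
    """The single large nutrient foramen (same geometry as a canal)."""

    theta_deg: float
    z_frac: float
    diameter_um: float
    inclination_deg: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (110, 168, 168)
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    outer_radii_um: tuple[float, float] = (105.0, 90.0)  # (x, y) semi-axes
    inner_radii_um: tuple[float, float] = (65.0, 55.0)
    axis_tilt_um_per_slice: tuple[float, float] = (0.0, 0.0)  # (x, y) drift
    canal_specs: tuple[CanalSpec, ...] = ()
    lacuna_count: int = 0
    lacuna_semiaxes_um: tuple[float, float, float] = (5.0, 3.0, 3.0)
    foramen: ForamenSpec | None = None
    bone_intensity: float = 200.0
    background_intensity: float = 50.0
    noise_sd: float = 0.0
    blur_sigma_um: float | None = None  # None -> 0.5 voxel
    seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.grid_shape
        if min(nz, ny, nx) < 8:
            raise PhantomSpecError("grid too small")
        if self.voxel_size_um <= 0:
            raise PhantomSpecError("voxel_size_um must be positive")
        ax_o, ay_o = self.outer_radii_um
        ax_i, ay_i = self.inner_radii_um
        if not (ax_i < ax_o and ay_i < ay_o):
            raise PhantomSpecError(
                "inner radii must be strictly less than outer radii"
            )
        if min(ax_i, ay_i) <= 0:
            raise PhantomSpecError("radii must be positive")
        min_diam = 2.0 * self.voxel_size_um
        for c in self.canal_specs:
            if not (-180.0 < c.theta_deg <= 180.0):
                raise PhantomSpecError(
                    f"canal theta_deg {c.theta_deg} outside (-180, 180]"
                )
            if not (0.0 < c.z_frac < 1.0):
                raise PhantomSpecError(f"canal z_frac {c.z_frac} outside (0, 1)")
            if c.diameter_um < min_diam:
                raise PhantomSpecError(
                    f"canal diameter {c.diameter_um} µm below 2 voxels"
                )
            if self.foramen is not None and c.diameter_um >= self.foramen.diameter_um:
                raise PhantomSpecError(
                    "canal diameter must be smaller than the foramen diameter"
                )
        if self.lacuna_count < 0:
            raise PhantomSpecError("lacuna_count must be >= 0")
        if self.bone_intensity <= self.background_intensity:
            raise PhantomSpecError("bone must be brighter than background")

    @property
    def blur_sigma_vox(self) -> float:
        if self.blur_sigma_um is None:
            return 0.5
        return self.blur_sigma_um / self.voxel_size_um


@dataclass(frozen=True)
class CanalTruth:
    id: int
    theta_deg: float
    z_um: float
    diameter_um: float
    inclination_deg: float
    is_foramen: bool


@dataclass(frozen=True)
class LacunaTruth:
    id: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    semiaxes_um: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth ledger of every structure carved into the volume."""

    canals: tuple[CanalTruth, ...]
    lacunae: tuple[LacunaTruth, ...]
    spec: PhantomSpec
    anterior_direction: tuple[float, float] = (1.0, 0.0)  # (x, y), unit

    @property
    def n_canals(self) -> int:
        return sum(not c.is_foramen for c in self.canals)

    @property
    def posterior_fraction(self) -> float:
        thetas = [c.theta_deg for c in self.canals if not c.is_foramen]
        if not thetas:
            raise ValueError("truth holds no canals")
        return sum(abs(t) > 90.0 for t in thetas) / len(thetas)


# Local import guard: VoxelVolume lives in volume_io but phantom is the
# natural producer; import lazily to avoid a cycle at module import time.
def _voxel_volume(values: np.ndarray, voxel_size_um: float):
    from .volume_io import VoxelVolume

    return VoxelVolume(values=values, voxel_size_um=voxel_size_um)


def _shell_centers_um(spec: PhantomSpec) -> np.ndarray:
    """Per-slice (x, y) shell centers in µm, drifting by axis_tilt."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_um
    mid = np.array([(nx - 1) / 2.0 * v, (ny - 1) / 2.0 * v])
    tilt = np.asarray(spec.axis_tilt_um_per_slice, dtype=float)
    iz = np.arange(nz)[:, None]
    return mid[None, :] + tilt[None, :] * (iz - (nz - 1) / 2.0)


def _ellipse_radius(ax: float, ay: float, theta_rad: np.ndarray) -> np.ndarray:
    """Radius of an axis-aligned ellipse along direction theta."""
    return (ax * ay) / np.sqrt(
        (ay * np.cos(theta_rad)) ** 2 + (ax * np.sin(theta_rad)) ** 2
    )


def _tube_axis(spec: PhantomSpec, tube: CanalSpec | ForamenSpec):
    """Return (point, direction) of the tube's axis line in µm, (x, y, z)."""
    nz = spec.grid_shape[0]
    v = spec.voxel_size_um
    th = np.deg2rad(tube.theta_deg)
    incl = np.deg2rad(tube.inclination_deg)
    u = np.array([np.cos(th), np.sin(th)])
    z_um = tube.z_frac * (nz - 1) * v
    iz = z_um / v
    centers = _shell_centers_um(spec)
    # interpolate the drifting center at the (generally fractional) slice
    i0 = int(np.clip(np.floor(iz), 0, nz - 1))
    i1 = min(i0 + 1, nz - 1)
    w = iz - i0
    c = (1 - w) * centers[i0] + w * centers[i1]
    r_in = _ellipse_radius(*spec.inner_radii_um, np.array(th))
    r_out = _ellipse_radius(*spec.outer_radii_um, np.array(th))
    r_mid = 0.5 * (float(r_in) + float(r_out))
    point = np.array([c[0] + u[0] * r_mid, c[1] + u[1] * r_mid, z_um])
    direction = np.array(
        [u[0] * np.cos(incl), u[1] * np.cos(incl), np.sin(incl)]
    )
    return point, direction


def _carve_tube(
    void: np.ndarray, spec: PhantomSpec, tube: CanalSpec | ForamenSpec
) -> None:
    """Mark voxels within diameter/2 of the tube's axis line as void."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_um
    point, d = _tube_axis(spec, tube)
    r = tube.diameter_um / 2.0
    # Clamp the carved segment to the near-wall radial span: it must pierce
    # both surfaces of *this* wall crossing with margin, but never reach the
    # opposite side of the shell through the marrow.
    th0 = np.deg2rad(tube.theta_deg)
    r_in_c = float(_ellipse_radius(*spec.inner_radii_um, np.array(th0)))
    dth = np.arcsin(min(0.9, (r + 2 * v) / r_in_c)) + 0.05
    foot = th0 + np.array([-dth, 0.0, dth])
    r_in_min = float(np.min(_ellipse_radius(*spec.inner_radii_um, foot)))
    r_out_max = float(np.max(_ellipse_radius(*spec.outer_radii_um, foot)))
    margin = 4.0 * v
    r_mid = 0.5 * (
        float(_ellipse_radius(*spec.inner_radii_um, np.array(th0)))
        + float(_ellipse_radius(*spec.outer_radii_um, np.array(th0)))
    )
    cos_i = np.cos(np.deg2rad(tube.inclination_deg))
    t_lo = (r_in_min - margin - r_mid) / cos_i
    t_hi = (r_out_max + margin - r_mid) / cos_i
    t = np.linspace(t_lo, t_hi, 9)
    seg = point[None, :] + t[:, None] * d[None, :]
    lo = seg.min(axis=0) - (r + 2 * v)
    hi = seg.max(axis=0) + (r + 2 * v)
    ix0, ix1 = int(max(0, lo[0] / v)), int(min(nx, hi[0] / v + 2))
    iy0, iy1 = int(max(0, lo[1] / v)), int(min(ny, hi[1] / v + 2))
    iz0, iz1 = int(max(0, lo[2] / v)), int(min(nz, hi[2] / v + 2))
    zz, yy, xx = np.meshgrid(
        np.arange(iz0, iz1) * v,
        np.arange(iy0, iy1) * v,
        np.arange(ix0, ix1) * v,
        indexing="ij",
    )
    px = xx - point[0]
    py = yy - point[1]
    pz = zz - point[2]
    proj = px * d[0] + py * d[1] + pz * d[2]
    dist2 = (
        (px - proj * d[0]) ** 2
        + (py - proj * d[1]) ** 2
        + (pz - proj * d[2]) ** 2
    )
    within = (dist2 <= r * r) & (proj >= t_lo) & (proj <= t_hi)
    void[iz0:iz1, iy0:iy1, ix0:ix1] |= within


def _point_line_distance(p: np.ndarray, point: np.ndarray, d: np.ndarray) -> float:
    w = p - point
    proj = w @ d
    return float(np.linalg.norm(w - proj * d))


def _place_lacunae(
    spec: PhantomSpec, rng: np.random.Generator
) -> list[LacunaTruth]:
    """Rejection-sample lacuna centroids strictly inside the cortical wall,
    clear of every tube and of each other."""
    v = spec.voxel_size_um
    nz = spec.grid_shape[0]
    sa = np.asarray(spec.lacuna_semiaxes_um)
    max_sa = float(sa.max())
    clearance = 3.0
    tubes = list(spec.canal_specs)
    if spec.foramen is not None:
        tubes.append(spec.foramen)
    axes = [_tube_axis(spec, t) for t in tubes]
    tube_r = [t.diameter_um / 2.0 for t in tubes]
    centers = _shell_centers_um(spec)
    placed: list[LacunaTruth] = []
    for lid in range(spec.lacuna_count):
        for _ in range(2000):
            th = rng.uniform(-np.pi, np.pi)
            zf = rng.uniform(0.12, 0.88)
            r_in = float(_ellipse_radius(*spec.inner_radii_um, np.array(th)))
            r_out = float(_ellipse_radius(*spec.outer_radii_um, np.array(th)))
            margin = max_sa + 2.0 * v + spec.blur_sigma_vox * v
            if r_out - r_in < 2 * margin + 1.0:
                continue
            rr = rng.uniform(r_in + margin, r_out - margin)
            z_um = zf * (nz - 1) * v
            c_xy = centers[int(round(zf * (nz - 1)))]
            p = np.array(
                [c_xy[0] + rr * np.cos(th), c_xy[1] + rr * np.sin(th), z_um]
            )
            ok = all(
                _point_line_distance(p, pt, d) > r + max_sa + clearance
                for (pt, d), r in zip(axes, tube_r)
            )
            if ok:
                for prev in placed:
                    q = np.array(
                        [prev.centroid_um[2], prev.centroid_um[1], prev.centroid_um[0]]
                    )
                    if np.linalg.norm(p - q) < 2 * max_sa + clearance:
                        ok = False
                        break
            if ok:
                placed.append(
                    LacunaTruth(
                        id=lid,
                        centroid_um=(p[2], p[1], p[0]),  # store (z, y, x)
                        semiaxes_um=tuple(sa),
                    )
                )
                break
        else:
            raise PhantomSpecError(
                f"could not place lacuna {lid}: wall too crowded"
            )
    return placed


def _carve_lacuna(void: np.ndarray, spec: PhantomSpec, lac: LacunaTruth) -> None:
    v = spec.voxel_size_um
    nz, ny, nx = spec.grid_shape
    cz, cy, cx = lac.centroid_um
    # axis-aligned ellipsoid; semiaxes given as (x, y, z) extents
    sx, sy, sz = lac.semiaxes_um
    iz0 = int(max(0, (cz - sz) / v - 1))
    iz1 = int(min(nz, (cz + sz) / v + 2))
    iy0 = int(max(0, (cy - sy) / v - 1))
    iy1 = int(min(ny, (cy + sy) / v + 2))
    ix0 = int(max(0, (cx - sx) / v - 1))
    ix1 = int(min(nx, (cx + sx) / v + 2))
    zz, yy, xx = np.meshgrid(
        np.arange(iz0, iz1) * v,
        np.arange(iy0, iy1) * v,
        np.arange(ix0, ix1) * v,
        indexing="ij",
    )
    q = ((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2 + ((zz - cz) / sz) ** 2
    void[iz0:iz1, iy0:iy1, ix0:ix1] |= q <= 1.0


def shell_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (annulus, marrow) boolean masks of the un-carved shell."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_um
    centers = _shell_centers_um(spec)
    x = np.arange(nx) * v
    y = np.arange(ny) * v
    ax_o, ay_o = spec.outer_radii_um
    ax_i, ay_i = spec.inner_radii_um
    annulus = np.zeros(spec.grid_shape, dtype=bool)
    marrow = np.zeros(spec.grid_shape, dtype=bool)
    for iz in range(nz):
        cx, cy = centers[iz]
        dx = (x[None, :] - cx)
        dy = (y[:, None] - cy)
        q_out = (dx / ax_o) ** 2 + (dy / ay_o) ** 2
        q_in = (dx / ax_i) ** 2 + (dy / ay_i) ** 2
        annulus[iz] = (q_out <= 1.0) & (q_in > 1.0)
        marrow[iz] = q_in <= 1.0
    return annulus, marrow


def generate_phantom(spec: PhantomSpec):
    """Generate a phantom volume and its ground-truth ledger.

    Returns ``(volume, truth)`` where *volume* is a
    :class:`~cortiquant.volume_io.VoxelVolume` and *truth* a
    :class:`PhantomTruth`.  Carving is pure masking — a voxel is void if any
    void structure covers it — so the result is invariant to the order of
    ``canal_specs``.  Identical seeds yield bit-identical volumes.

    Raises
    ------
    PhantomOverlapError
        If the carved void structures merge into fewer connected components
        than specified (the truth ledger would be ambiguous).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    v = spec.voxel_size_um
    nz = spec.grid_shape[0]

    annulus, _ = shell_masks(spec)
    void = np.zeros(spec.grid_shape, dtype=bool)

    tubes: list[CanalSpec | ForamenSpec] = list(spec.canal_specs)
    if spec.foramen is not None:
        tubes.append(spec.foramen)
    for tube in tubes:
        _carve_tube(void, spec, tube)
    lacunae = _place_lacunae(spec, rng) if spec.lacuna_count else []
    for lac in lacunae:
        _carve_lacuna(void, spec, lac)

    carved_void = annulus & void
    n_expected = len(tubes) + len(lacunae)
    if n_expected:
        _, n_found = ndimage.label(carved_void, structure=np.ones((3, 3, 3)))
        if n_found != n_expected:
            raise PhantomOverlapError(
                f"expected {n_expected} void components, found {n_found}; "
                "structures overlap or fall outside the wall"
            )

    bone = annulus & ~void
    values = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float32)
    values[bone] = spec.bone_intensity
    if spec.blur_sigma_vox > 0:
        values = ndimage.gaussian_filter(values, sigma=spec.blur_sigma_vox)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape).astype(
            np.float32
        )

    canal_truths = []
    next_id = 0
    for c in spec.canal_specs:
        canal_truths.append(
            CanalTruth(
                id=next_id,
                theta_deg=c.theta_deg,
                z_um=c.z_frac * (nz - 1) * v,
                diameter_um=c.diameter_um,
                inclination_deg=c.inclination_deg,
                is_foramen=False,
            )
        )
        next_id += 1
    if spec.foramen is not None:
        f = spec.foramen
        canal_truths.append(
            CanalTruth(
                id=next_id,
                theta_deg=f.theta_deg,
                z_um=f.z_frac * (nz - 1) * v,
                diameter_um=f.diameter_um,
                inclination_deg=f.inclination_deg,
                is_foramen=True,
            )
        )

    truth = PhantomTruth(
        canals=tuple(canal_truths), lacunae=tuple(lacunae), spec=spec
    )
    return _voxel_volume(values.astype(np.float32), v), truth


# ---------------------------------------------------------------------------
# 2D contour-pair fixture for the periosteal-thickness module
# ---------------------------------------------------------------------------

def _polygon_is_simple(pts: np.ndarray) -> bool:
    """Brute-force segment-intersection test for a closed polygon."""
    n = len(pts)
    segs = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        p, p2 = segs[i]
        d1 = p2 - p
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # shared endpoints
            q, q2 = segs[j]
            d2 = q2 - q
            denom = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(denom) < 1e-12:
                continue
            w = q - p
            t = (w[0] * d2[1] - w[1] * d2[0]) / denom
            s = (w[0] * d1[1] - w[1] * d1[0]) / denom
            if 1e-9 < t < 1 - 1e-9 and 1e-9 < s < 1 - 1e-9:
                return False
    return True


def generate_contour_pair(
    radius_inner_um: float,
    thickness_profile: float | Callable[[np.ndarray], np.ndarray],
    n_points: int = 256,
    exclusion_arc: tuple[float, float] | None = None,
):
    """Build an (inner, outer) closed-contour pair with known thickness.

    The inner contour is a circle of ``radius_inner_um``; the outer contour
    is the inner contour offset outward along its normals by
    ``thickness_profile`` (a nonnegative scalar, or a function of the polar
    angle in radians).  ``exclusion_arc`` is a ``(start_deg, end_deg)``
    angular range recorded for downstream masking (e.g. the interosseous
    membrane analogue).

    Returns ``(inner, outer, exclusion_arcs)`` with contours as ``(n, 2)``
    arrays of (x, y) µm, counter-clockwise, not repeating the first point.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if radius_inner_um <= 0:
        raise ValueError("radius_inner_um must be positive")
    theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    if callable(thickness_profile):
        t = np.asarray(thickness_profile(theta), dtype=float)
    else:
        t = np.full(n_points, float(thickness_profile))
    if np.any(t < 0):
        raise ValueError("thickness_profile must be nonnegative")
    normal = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    inner = radius_inner_um * normal
    outer = (radius_inner_um + t)[:, None] * normal
    if not _polygon_is_simple(outer):
        raise ValueError(
            "offset contour self-intersects (thickness too large vs curvature)"
        )
    arcs = [exclusion_arc] if exclusion_arc is not None else []
    return inner, outer, arcs


# ---------------------------------------------------------------------------
# Spec builders used by the validation studies
# ---------------------------------------------------------------------------

def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    b = d1 @ d2
    c = d1 @ r
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-12 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))


def _tube_wall_segment(
    spec: PhantomSpec, tube: CanalSpec | ForamenSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints (x, y, z µm) of the tube's axis across the cortical wall."""
    point, d = _tube_axis(spec, tube)
    th = np.deg2rad(tube.theta_deg)
    r_in = float(_ellipse_radius(*spec.inner_radii_um, np.array(th)))
    r_out = float(_ellipse_radius(*spec.outer_radii_um, np.array(th)))
    r_mid = 0.5 * (r_in + r_out)
    cos_i = np.cos(np.deg2rad(tube.inclination_deg))
    t_lo = (r_in - 5.0 - r_mid) / cos_i
    t_hi = (r_out + 5.0 - r_mid) / cos_i
    return point + t_lo * d, point + t_hi * d


def _tubes_clear(spec: PhantomSpec, gap_um: float = 6.0) -> bool:
    tubes: list[CanalSpec | ForamenSpec] = list(spec.canal_specs)
    if spec.foramen is not None:
        tubes.append(spec.foramen)
    segs = [_tube_wall_segment(spec, t) for t in tubes]
    for i in range(len(tubes)):
        for j in range(i + 1, len(tubes)):
            need = (tubes[i].diameter_um + tubes[j].diameter_um) / 2.0 + gap_um
            if _segment_distance(*segs[i], *segs[j]) < need:
                return False
    return True


def random_phantom_spec(
    seed: int,
    n_canals: int | None = None,
    with_foramen: bool | None = None,
    lacuna_count: int | None = None,
    grid_shape: tuple[int, int, int] = (96, 176, 176),
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> PhantomSpec:
    """Draw a random, guaranteed-non-overlapping phantom specification.

    Canal polar positions are sampled with a minimum angular separation of
    25° so straight tubes of up to 30 µm diameter never merge on the
    endosteal perimeter; inclinations up to ±20° and a drifting shell axis
    exercise the oblique-geometry paths downstream.
    """
    rng = np.random.default_rng(seed)
    if n_canals is None:
        n_canals = int(rng.integers(3, 9))
    if with_foramen is None:
        with_foramen = bool(rng.integers(0, 2))
    if lacuna_count is None:
        lacuna_count = int(rng.integers(15, 35))

    n_tubes = n_canals + (1 if with_foramen else 0)
    tilt = rng.uniform(-0.3, 0.3, size=2)
    for _ in range(500):
        # jittered even angular spacing guarantees a minimum gap of half the
        # nominal spacing even for dense specs
        spacing = 360.0 / max(n_tubes, 1)
        offset = rng.uniform(-180.0, 180.0)
        jitter = rng.uniform(-0.25, 0.25, size=n_tubes) * spacing
        thetas = np.mod(
            offset + np.arange(n_tubes) * spacing + jitter + 180.0, 360.0
        ) - 180.0
        thetas[thetas == -180.0] = 180.0
        # keep canals clear of the anterior/posterior boundary so the truth
        # classification is never decided by sub-voxel centroid rounding
        margin = 3.0
        near = np.abs(np.abs(thetas) - 90.0) < margin
        thetas[near] += np.where(
            np.abs(thetas[near]) >= 90.0, margin, -margin
        ) * np.sign(thetas[near])
        rng.shuffle(thetas)
        # spread z-levels evenly (shuffled) so angular neighbours are offset
        # proximodistally; random z draws pack tubes too tightly for dense specs
        z_fracs = rng.permutation(np.linspace(0.2, 0.8, max(n_canals, 1)))
        canals = tuple(
            CanalSpec(
                theta_deg=float(th),
                z_frac=float(zf),
                diameter_um=float(rng.uniform(16.0, 30.0)),
                inclination_deg=float(rng.uniform(-20.0, 20.0)),
            )
            for th, zf in zip(thetas[:n_canals], z_fracs)
        )
        foramen = None
        if with_foramen:
            foramen = ForamenSpec(
                theta_deg=float(thetas[n_canals]),
                z_frac=float(rng.uniform(0.35, 0.65)),
                diameter_um=60.0,
            )
        spec = PhantomSpec(
            grid_shape=grid_shape,
            voxel_size_um=voxel_size_um,
            outer_radii_um=(100.0, 85.0),
            inner_radii_um=(62.0, 52.0),
            axis_tilt_um_per_slice=(float(tilt[0]), float(tilt[1])),
            canal_specs=canals,
            lacuna_count=lacuna_count,
            foramen=foramen,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # pairwise 3D clearance between tube axes across the wall
        if _tubes_clear(spec):
            return spec
    raise PhantomSpecError("cannot place canals with required separation")


def posterior_contrast_spec(
    n_total: int,
    n_posterior: int,
    seed: int,
    grid_shape: tuple[int, int, int] = (90, 208, 208),
) -> PhantomSpec:
    """Phantom with an exact posterior canal count, for group contrasts.

    Posterior canals (|theta| > 90°) and anterior canals are laid out evenly
    within their half-circles with a seeded jitter, keeping 8° clear of the
    ±90° boundary so discretization can never flip a classification.
    """
    if not 0 <= n_posterior <= n_total:
        raise ValueError("need 0 <= n_posterior <= n_total")
    rng = np.random.default_rng(seed)
    margin = 8.0
    for _ in range(500):
        thetas: list[float] = []
        n_ant = n_total - n_posterior
        if n_ant:
            span = 180.0 - 2 * margin  # (-82, 82)
            step = span / n_ant
            for i in range(n_ant):
                base = -90.0 + margin + (i + 0.5) * step
                thetas.append(base + float(rng.uniform(-0.25, 0.25)) * step)
        if n_posterior:
            span = 180.0 - 2 * margin  # |theta| in (98, 180]
            step = span / n_posterior
            for i in range(n_posterior):
                base = 90.0 + margin + (i + 0.5) * step
                th = base + float(rng.uniform(-0.25, 0.25)) * step
                if th > 180.0:
                    th -= 360.0
                thetas.append(th)
        # stride z-assignment: canals adjacent in angle land far apart in z
        order = np.argsort(np.argsort(thetas))
        stride = max(n_total // 2, 1)
        z_levels = np.linspace(0.2, 0.8, max(n_total, 1))
        z_fracs = [
            float(z_levels[(int(o) * stride) % n_total]) for o in order
        ]
        canals = tuple(
            CanalSpec(
                theta_deg=float(th),
                z_frac=zf,
                diameter_um=float(rng.uniform(14.0, 18.0)),
            )
            for th, zf in zip(thetas, z_fracs)
        )
        spec = PhantomSpec(
            grid_shape=grid_shape,
            voxel_size_um=DEFAULT_VOXEL_SIZE_UM,
            outer_radii_um=(120.0, 100.0),
            inner_radii_um=(75.0, 62.0),
            canal_specs=canals,
            lacuna_count=10,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if _tubes_clear(spec):
            return spec
    raise PhantomSpecError("cannot place contrast canals without overlap")
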