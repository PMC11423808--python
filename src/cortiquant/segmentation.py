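"""Bone / cortex / marrow masks and labeled intracortical void components.

The segmentation chain realizes threshold-based canal extraction on a
cortical shell: global thresholding separates bone from background, a
morphological closing of the bone mask defines the cortex *region* (the
shell with its voids sealed), the marrow cavity is the interior non-bone
component of that region, and the intracortical voids are the connected
components of ``cortex_region \\ bone`` outside the marrow.  Voids use
26-connectivity (diagonal chains of void voxels read as one canal), bone
6-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import VoxelVolume

__all__ = [
    "MaskVolume",
    "VoidComponent",
    "threshold_bone",
    "define_cortex_region",
    "extract_marrow",
    "extract_void_components",
    "classify_components",
]

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MaskVolume:
    """Binary 3D mask congruent with its source volume."""

    mask: np.ndarray
    voxel_size_um: float
    role: str  # bone | cortex_region | marrow | void
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")


@dataclass
class VoidComponent:
    """One intracortical void connected component."""

    id: int
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]  # (z, y, x) voxel indices
    n_voxels: int
    volume_um3: float
    centroid_um: tuple[float, float, float]  # (x, y, z)
    touches_periosteum: bool
    touches_endosteum: bool
    class_label: str = "unclassified"
    diameter_um: float | None = None
    diameter_fallback: bool = False
    theta_deg: float | None = None

    @property
    def is_trans_cortical(self) -> bool:
        return self.touches_periosteum and self.touches_endosteum


def threshold_bone(
    volume: VoxelVolume, method: str = "otsu", fixed_value: float | None = None
) -> MaskVolume:
    """Threshold the volume into a bone mask (``values >= threshold``).

    The automatic method picks the grey level minimizing intra-class
    intensity variance over the histogram (equivalently maximizing
    between-class variance).  The threshold actually used is logged and
    stored in ``mask.meta["threshold"]``.
    """
    values = volume.values
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        if float(values.max()) == float(values.min()):
            raise ValueError("degenerate histogram: constant-intensity volume")
        thr = float(threshold_otsu(values))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    logger.info("bone threshold (%s): %.4f", method, thr)
    return MaskVolume(
        mask=values >= thr,
        voxel_size_um=volume.voxel_size_um,
        role="bone",
        meta={"threshold": thr, "method": method},
    )


def _ball_closing(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Morphological closing with a Euclidean ball, via two distance
    transforms (exact and far faster than an explicit ball footprint)."""
    # Work on a padded copy so the structuring ball can extend beyond the
    # grid: laterally the surroundings are air (background); along z the
    # diaphysis continues beyond the scanned stack, so the end slices are
    # replicated rather than letting the erosion eat the open shell ends.
    pad = int(np.ceil(radius_vox)) + 2
    work = np.pad(mask, ((pad, pad), (0, 0), (0, 0)), mode="edge")
    work = np.pad(work, ((0, 0), (pad, pad), (pad, pad)), constant_values=False)
    d1 = ndimage.distance_transform_edt(~work)
    dilated = d1 <= radius_vox
    d2 = ndimage.distance_transform_edt(dilated)
    closed = d2 > radius_vox
    return closed[pad:-pad, pad:-pad, pad:-pad]


def define_cortex_region(bone: MaskVolume, closing_radius_um: float) -> MaskVolume:
    """Close the bone mask with a ball so intracortical voids (canals,
    lacunae, the foramen) fall inside the region.

    The closing radius must exceed the largest expected canal radius — a
    tube is only sealed by a ball that does not fit through it — and stay
    below the minimum radius of curvature of the endosteal surface, or the
    closing would carve slivers off the marrow cavity.
    """
    r_vox = closing_radius_um / bone.voxel_size_um
    if r_vox < 1.0:
        raise ValueError("closing radius below 1 voxel")
    closed = _ball_closing(bone.mask, r_vox)
    return MaskVolume(
        mask=closed,
        voxel_size_um=bone.voxel_size_um,
        role="cortex_region",
        meta={"closing_radius_um": closing_radius_um},
    )


def extract_marrow(region: MaskVolume) -> MaskVolume:
    """Extract the marrow cavity from a (closed) cortex-region mask.

    The marrow is the largest connected non-bone component that does not
    touch the lateral (x/y) faces of the grid.  Pass the *cortex region*
    mask when trans-cortical voids are present — on a raw bone mask the
    canals connect the cavity to the exterior and no interior component
    exists.
    """
    labels, n = ndimage.label(~region.mask)  # 6-connectivity background
    if n == 0:
        raise ValueError("no marrow cavity: mask fills the grid")
    lateral = np.zeros(region.mask.shape, dtype=bool)
    lateral[:, 0, :] = lateral[:, -1, :] = True
    lateral[:, :, 0] = lateral[:, :, -1] = True
    touching = set(np.unique(labels[lateral])) - {0}
    sizes = ndimage.sum_labels(
        np.ones_like(labels), labels, index=np.arange(1, n + 1)
    )
    interior = [
        (int(sizes[i - 1]), i) for i in range(1, n + 1) if i not in touching
    ]
    if not interior:
        raise ValueError("no marrow cavity")
    interior.sort(reverse=True)
    if len(interior) > 1 and interior[0][0] == interior[1][0]:
        raise ValueError("ambiguous marrow: two equal-size cavities")
    marrow = labels == interior[0][1]
    return MaskVolume(mask=marrow, voxel_size_um=region.voxel_size_um, role="marrow")


def extract_void_components(
    cortex_region: MaskVolume,
    bone: MaskVolume,
    marrow: MaskVolume,
    min_voxels: int = 4,
    min_depth_vox: float = 1.8,
) -> list[VoidComponent]:
    """Label the intracortical voids and annotate surface contacts.

    Components are the 26-connected pieces of ``cortex_region & ~bone``
    outside the marrow.  Periosteal contact means 26-adjacency to the
    exterior space (outside both cortex region and marrow); endosteal
    contact means 26-adjacency to the marrow.  Components below
    ``min_voxels``, or hugging the region boundary without ever reaching
    deeper than ``min_depth_vox`` voxels into it, are discarded: those are
    sub-voxel partial-volume films along the segmented surfaces, not voids.
    """
    shapes = {cortex_region.mask.shape, bone.mask.shape, marrow.mask.shape}
    if len(shapes) != 1:
        raise ValueError("masks are not congruent")
    v = cortex_region.voxel_size_um
    void = cortex_region.mask & ~bone.mask & ~marrow.mask
    # A one-voxel opening strips the sub-voxel partial-volume films that the
    # region closing leaves along the segmented surfaces; real voids (canals,
    # lacunae) are several voxels across and pass through unchanged.
    void = ndimage.binary_opening(
        void, structure=ndimage.generate_binary_structure(3, 1)
    )
    labels, n = ndimage.label(void, structure=_STRUCT_26)
    if n == 0:
        return []
    depth = ndimage.distance_transform_edt(cortex_region.mask)
    max_depth = ndimage.labeled_comprehension(
        depth, labels, np.arange(1, n + 1), np.max, float, 0.0
    )
    exterior = ~(cortex_region.mask | marrow.mask)
    # 2-voxel adjacency: the opening may recede a canal mouth by one voxel
    ext_adj = set(
        np.unique(labels[ndimage.binary_dilation(exterior, _STRUCT_26, iterations=2)])
    )
    endo_adj = set(
        np.unique(
            labels[ndimage.binary_dilation(marrow.mask, _STRUCT_26, iterations=2)]
        )
    )
    comps: list[VoidComponent] = []
    objects = ndimage.find_objects(labels)
    next_id = 0
    for lab, sl in enumerate(objects, start=1):
        idx_local = np.nonzero(labels[sl] == lab)
        nvox = len(idx_local[0])
        if nvox < min_voxels or max_depth[lab - 1] <= min_depth_vox:
            continue
        idx = tuple(
            loc + s.start for loc, s in zip(idx_local, sl)
        )  # (z, y, x) arrays
        cz, cy, cx = (float(a.mean()) * v for a in idx)
        comps.append(
            VoidComponent(
                id=next_id,
                indices=idx,  # type: ignore[arg-type]
                n_voxels=nvox,
                volume_um3=nvox * v**3,
                centroid_um=(cx, cy, cz),
                touches_periosteum=lab in ext_adj,
                touches_endosteum=lab in endo_adj,
            )
        )
        next_id += 1
    return comps


def classify_components(
    components: list[VoidComponent],
    lacuna_max_volume_um3: float,
    foramen_min_diameter_um: float,
) -> list[VoidComponent]:
    """Assign canal / lacuna / foramen / partial labels in place.

    A *canal* must be trans-cortical (touching both surfaces), larger than
    an osteocyte lacuna by volume, and narrower than the nutrient-foramen
    cutoff (the cutoff itself is inclusive on the foramen side).  Only
    canals enter the downstream canal statistics.
    """
    for c in components:
        if c.is_trans_cortical:
            if c.diameter_um is None:
                raise ValueError(
                    f"component {c.id}: diameter required before classification"
                )
            if c.diameter_um >= foramen_min_diameter_um:
                c.class_label = "foramen"
            elif c.volume_um3 > lacuna_max_volume_um3:
                c.class_label = "canal"
            else:
                c.class_label = "lacuna"
        elif c.volume_um3 <= lacuna_max_volume_um3:
            c.class_label = "lacuna"
        else:
            c.class_label = "partial"
    return components
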