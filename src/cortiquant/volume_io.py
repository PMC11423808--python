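"""Reading and writing the formats the pipeline touches.

Volumes travel as multi-page TIFF (one page per z-slice) or NIfTI-1 with the
voxel size carried in the header; tables as CSV with fixed 4-decimal float
formatting so writers are byte-deterministic; run configuration as JSON or
YAML.  All geometry downstream assumes isotropic voxels, so anisotropic
headers are rejected at the door.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VoxelVolume",
    "RunConfig",
    "read_volume",
    "write_volume",
    "write_canal_table",
    "read_canal_table",
    "load_config",
    "write_truth_table",
]


@dataclass
class VoxelVolume:
    """3D scalar image with isotropic voxel size.

    Axes are ``(z, y, x)``; anterior is ``+x`` by package convention.
    """

    values: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D grid")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with the package defaults.

    lacuna_max_volume_um3 is a generous upper bound on an osteocyte lacuna;
    foramen_min_diameter_um separates the nutrient foramen from canals; both
    cutoffs are deliberately exposed because the anatomical literature gives
    ranges, not constants.
    """

    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    closing_radius_um: float = 40.0
    lacuna_max_volume_um3: float = 2000.0
    foramen_min_diameter_um: float = 50.0
    theta_step_deg: float = 20.0
    histogram_bin_deg: float = 15.0
    anterior_direction: tuple[float, float] = (1.0, 0.0)  # (x, y)
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        for name in ("theta_step_deg", "histogram_bin_deg"):
            v = getattr(self, name)
            if v <= 0 or abs(360.0 / v - round(360.0 / v)) > 1e-9:
                raise ValueError(f"{name} must divide 360 evenly")
        ax = np.asarray(self.anterior_direction, dtype=float)
        if np.linalg.norm(ax) == 0:
            raise ValueError("anterior_direction must be nonzero")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anterior_direction"] = list(self.anterior_direction)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if "anterior_direction" in data:
        data["anterior_direction"] = tuple(data["anterior_direction"])
    return RunConfig(**data)


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def read_volume(
    path: str | Path, voxel_size_override: float | None = None
) -> VoxelVolume:
    """Read a multi-page TIFF or NIfTI-1 volume.

    The voxel size is taken from the NIfTI header when present; TIFF carries
    no trustworthy size metadata here, so ``voxel_size_override`` is required
    for it.  Anisotropic voxels are rejected — every geometric stage assumes
    isotropy.
    """
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError("expected a 3D NIfTI volume")
        if max(zooms) - min(zooms) > 1e-4 * max(zooms):
            raise ValueError(f"anisotropic voxels {zooms}: geometry assumes isotropy")
        voxel = float(zooms[0])
        if voxel <= 0:
            voxel = -1.0
        if voxel <= 0 and voxel_size_override is None:
            raise ValueError("voxel size required (header empty, no override)")
        if voxel <= 0:
            voxel = float(voxel_size_override)  # type: ignore[arg-type]
        # stored (x, y, z) -> pipeline (z, y, x)
        values = np.transpose(data, (2, 1, 0))
        return VoxelVolume(values=values, voxel_size_um=voxel)
    values = tifffile.imread(str(path))
    if values.ndim == 2:
        values = values[None]
    if voxel_size_override is None:
        raise ValueError("voxel size required: TIFF carries no size metadata")
    return VoxelVolume(values=values, voxel_size_um=float(voxel_size_override))


def write_volume(volume: VoxelVolume, path: str | Path, dtype=None) -> Path:
    """Write a volume as multi-page TIFF or NIfTI-1 (by extension).

    Float data is written losslessly as float32 by default; pass
    ``dtype=np.uint16`` for 16-bit output for external viewers.
    """
    path = Path(path)
    values = volume.values
    if dtype is not None:
        values = np.clip(values, 0, np.iinfo(dtype).max).astype(dtype)
    elif values.dtype not in (np.uint8, np.uint16, np.float32):
        values = values.astype(np.float32)
    if _is_nifti(path):
        v = volume.voxel_size_um
        affine = np.diag([v, v, v, 1.0])
        img = nib.Nifti1Image(np.transpose(values, (2, 1, 0)), affine)
        img.header.set_zooms((v, v, v))
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
    else:
        tifffile.imwrite(str(path), values)
    return path


_CANAL_COLUMNS = [
    "id",
    "class",
    "centroid_x_um",
    "centroid_y_um",
    "centroid_z_um",
    "z_um",
    "volume_um3",
    "diameter_um",
    "theta_deg",
    "is_posterior",
]


def write_canal_table(records, path: str | Path) -> Path:
    """Write canal records as CSV, one row per component, ordered by id.

    Floats are formatted to 4 decimals so repeated runs produce
    byte-identical files.
    """
    path = Path(path)
    rows = []
    for r in sorted(records, key=lambda r: r.id):
        cx, cy, cz = r.centroid_um
        rows.append(
            {
                "id": r.id,
                "class": r.class_label,
                "centroid_x_um": cx,
                "centroid_y_um": cy,
                "centroid_z_um": cz,
                "z_um": r.z_um,
                "volume_um3": r.volume_um3,
                "diameter_um": r.diameter_um,
                "theta_deg": r.theta_deg,
                "is_posterior": r.is_posterior,
            }
        )
    df = pd.DataFrame(rows, columns=_CANAL_COLUMNS)
    df.to_csv(path, index=False, float_format="%.4f")
    return path


def read_canal_table(path: str | Path):
    """Read a canal-record CSV back into CanalRecord objects."""
    from .geometry import CanalRecord

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            CanalRecord(
                id=int(row["id"]),
                class_label=str(row["class"]),
                centroid_um=(
                    float(row["centroid_x_um"]),
                    float(row["centroid_y_um"]),
                    float(row["centroid_z_um"]),
                ),
                z_um=float(row["z_um"]),
                volume_um3=float(row["volume_um3"]),
                diameter_um=float(row["diameter_um"]),
                theta_deg=float(row["theta_deg"]),
                is_posterior=bool(row["is_posterior"]),
            )
        )
    return records


def write_truth_table(truth, path: str | Path) -> Path:
    """Persist a PhantomTruth ledger: CSV of structures + JSON spec echo."""
    path = Path(path)
    rows = []
    for c in truth.canals:
        rows.append(
            {
                "id": c.id,
                "kind": "foramen" if c.is_foramen else "canal",
                "theta_deg": c.theta_deg,
                "z_um": c.z_um,
                "diameter_um": c.diameter_um,
                "inclination_deg": c.inclination_deg,
            }
        )
    base = len(truth.canals)
    for l in truth.lacunae:
        cz, cy, cx = l.centroid_um
        rows.append(
            {
                "id": base + l.id,
                "kind": "lacuna",
                "theta_deg": float("nan"),
                "z_um": cz,
                "diameter_um": 2.0 * max(l.semiaxes_um),
                "inclination_deg": float("nan"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["id", "kind", "theta_deg", "z_um", "diameter_um", "inclination_deg"],
    )
    df.to_csv(path, index=False, float_format="%.4f")
    spec_echo = dataclasses.asdict(truth.spec)
    spec_echo["canal_specs"] = [dataclasses.asdict(c) for c in truth.spec.canal_specs]
    if truth.spec.foramen is not None:
        spec_echo["foramen"] = dataclasses.asdict(truth.spec.foramen)
    Path(str(path) + ".spec.json").write_text(json.dumps(spec_echo, indent=2))
    return path
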