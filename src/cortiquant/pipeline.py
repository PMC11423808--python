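"""End-to-end orchestration: volume in, canal morphometry out.

``quantify_volume`` chains thresholding, cortex-region closing, marrow
extraction, void labeling, per-canal geometry, classification and the polar
summary, and returns everything downstream consumers (CLI, statistics,
validation studies) need.  ``run_quantify`` adds the file I/O around it and
an output manifest with content hashes so identical inputs provably yield
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import geometry, panorama, segmentation, stats, volume_io
from .geometry import CanalRecord, MarrowAxis
from .segmentation import MaskVolume, VoidComponent
from .volume_io import RunConfig, VoxelVolume

__all__ = ["QuantifyResult", "quantify_volume", "run_quantify", "run_simulate"]


@dataclass
class QuantifyResult:
    bone: MaskVolume
    cortex_region: MaskVolume
    marrow: MaskVolume
    axis: MarrowAxis
    components: list[VoidComponent]
    records: list[CanalRecord]
    polar: stats.PolarSummary | None
    threshold_used: float

    @property
    def canal_records(self) -> list[CanalRecord]:
        return [r for r in self.records if r.class_label == "canal"]

    def posterior_fraction(self) -> tuple[float, int, int]:
        return geometry.posterior_fraction(self.canal_records)


def quantify_volume(volume: VoxelVolume, config: RunConfig | None = None
                    ) -> QuantifyResult:
    """Run the full canal-quantification chain on one volume."""
    cfg = config or RunConfig()
    bone = segmentation.threshold_bone(
        volume, method=cfg.threshold_method, fixed_value=cfg.fixed_threshold
    )
    cortex = segmentation.define_cortex_region(bone, cfg.closing_radius_um)
    marrow = segmentation.extract_marrow(cortex)
    axis = geometry.compute_marrow_axis(marrow)
    comps = segmentation.extract_void_components(cortex, bone, marrow)
    for c in comps:
        d, fallback = geometry.canal_diameter(c, volume.voxel_size_um)
        c.diameter_um = d
        c.diameter_fallback = fallback
        try:
            c.theta_deg = geometry.canal_orientation(
                c.centroid_um, axis, cfg.anterior_direction
            )
        except ValueError:
            c.theta_deg = None
    segmentation.classify_components(
        comps, cfg.lacuna_max_volume_um3, cfg.foramen_min_diameter_um
    )
    records = []
    for c in comps:
        if c.theta_deg is None:
            continue
        records.append(
            CanalRecord(
                id=c.id,
                class_label=c.class_label,
                centroid_um=c.centroid_um,
                z_um=c.centroid_um[2],
                volume_um3=c.volume_um3,
                diameter_um=c.diameter_um,
                theta_deg=c.theta_deg,
                is_posterior=abs(c.theta_deg) > 90.0,
            )
        )
    canal_records = [r for r in records if r.class_label == "canal"]
    polar = (
        stats.polar_histogram(canal_records, cfg.histogram_bin_deg)
        if canal_records
        else None
    )
    return QuantifyResult(
        bone=bone,
        cortex_region=cortex,
        marrow=marrow,
        axis=axis,
        components=comps,
        records=records,
        polar=polar,
        threshold_used=bone.meta["threshold"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, files: list[Path], config_echo: dict) -> Path:
    manifest = {
        "config": config_echo,
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return p


def run_simulate(spec, out_dir: str | Path) -> dict:
    """Generate a phantom and write volume + truth + spec echo + manifest."""
    from .phantom import generate_phantom

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume, truth = generate_phantom(spec)
    files = [
        volume_io.write_volume(volume, out / "phantom.tif"),
        volume_io.write_truth_table(truth, out / "truth.csv"),
        Path(str(out / "truth.csv") + ".spec.json"),
    ]
    manifest = _write_manifest(out, files, {"seed": spec.seed})
    return {"volume": files[0], "truth": files[1], "manifest": manifest}


def run_quantify(
    volume_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    voxel_size_override: float | None = None,
    make_panorama: bool = True,
) -> QuantifyResult:
    """File-level pipeline: read volume, quantify, write all artifacts."""
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume = volume_io.read_volume(volume_path, voxel_size_override)
    result = quantify_volume(volume, cfg)
    files = [volume_io.write_canal_table(result.records, out / "canal_table.csv")]
    report: dict = {
        "threshold_used": result.threshold_used,
        "n_components": len(result.components),
        "n_canals": len(result.canal_records),
    }
    if result.canal_records:
        frac, n_post, n_tot = result.posterior_fraction()
        report["posterior_fraction"] = frac
        report["posterior_count"] = n_post
        density = geometry.canal_density(
            result.records,
            None,
            marrow=result.marrow,
            axis=result.axis,
            anterior_direction=cfg.anterior_direction,
        )
        report["density_per_mm2"] = density.density_per_mm2
        report["endosteal_area_mm2"] = density.reference_area_mm2
    if result.polar is not None:
        (out / "polar_summary.json").write_text(
            json.dumps(result.polar.to_dict(), indent=2)
        )
        files.append(out / "polar_summary.json")
        files.append(
            stats.plot_polar_histogram(result.polar, out / "polar_histogram.png")
        )
    if make_panorama:
        pano = panorama.unwrap_stitch(
            result.bone,
            result.axis,
            theta_step_deg=cfg.theta_step_deg,
            anterior_direction=cfg.anterior_direction,
        )
        files.append(panorama.write_panorama(pano, out / "panorama.tif"))
        files.append(Path(str(out / "panorama.tif") + ".json"))
        report["panorama_views"] = pano.views_generated
    stats.write_report(report, out / "report.json")
    files += [out / "report.json", out / "report.txt"]
    _write_manifest(out, files, cfg.to_dict())
    return result
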