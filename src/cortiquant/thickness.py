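"""Periosteal thickness as inter-edge distance between two contours.

The measurement walks the inner contour at uniform arc-length spacing,
casts the outward normal at each sample, and takes the distance to the
first crossing of the outer contour.  Angular exclusion arcs mask regions
that must not enter the summary (the interosseous-membrane analogue, which
is excluded manually in histological practice).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ThicknessMeasurement", "interedge_distance", "read_contour_csv"]


@dataclass
class ThicknessMeasurement:
    distances_um: np.ndarray  # retained per-point distances
    sample_angles_deg: np.ndarray  # polar angle of each retained sample
    mean_um: float
    sd_um: float
    n: int
    n_excluded: int
    n_dropped: int
    excluded_arcs: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"angle_deg": self.sample_angles_deg, "distance_um": self.distances_um}
        )


def read_contour_csv(path: str | Path) -> np.ndarray:
    """Read an ordered closed contour from a 2-column CSV (x_um, y_um)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("contour CSV needs two columns (x_um, y_um)")
    return df.iloc[:, :2].to_numpy(dtype=float)


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    total = s[-1]
    targets = np.arange(n) * total / n
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def _ray_first_crossing(p: np.ndarray, d: np.ndarray, poly: np.ndarray,
                        t_max: float) -> float | None:
    """Smallest t in (0, t_max] with p + t d crossing a polygon edge."""
    q = poly
    q2 = np.roll(poly, -1, axis=0)
    e = q2 - q
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    w = q - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        s = (w[:, 0] * d[1] - w[:, 1] * d[0]) / denom
    valid = (np.abs(denom) > 1e-12) & (s >= 0) & (s < 1) & (t > 1e-9) & (t <= t_max)
    if not valid.any():
        return None
    return float(t[valid].min())


def _in_arc(angle_deg: float, arc: tuple[float, float]) -> bool:
    lo, hi = arc
    a = (angle_deg - lo) % 360.0
    span = (hi - lo) % 360.0
    if span == 0:
        span = 360.0
    return a <= span


def interedge_distance(
    contour_inner: np.ndarray,
    contour_outer: np.ndarray,
    exclusion_arcs=(),
    n_samples: int = 180,
    max_search_um: float | None = None,
) -> ThicknessMeasurement:
    """Normal-based inter-edge distance from the inner to the outer contour.

    Parameters
    ----------
    contour_inner, contour_outer
        Closed, ordered, non-self-intersecting ``(n, 2)`` point lists in µm
        (first point not repeated).
    exclusion_arcs
        Iterable of ``(start_deg, end_deg)`` arcs of polar angle about the
        inner-contour centroid; samples inside are excluded from the summary.
    n_samples
        Number of uniform arc-length samples along the inner contour (≥ 16).
    max_search_um
        Search length for the outward normal; defaults to the outer
        contour's bounding-box diagonal.  A sample whose normal never
        crosses the outer contour is dropped with a warning; if more than
        half of the non-excluded samples drop, the measurement errors out.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    inner = np.asarray(contour_inner, dtype=float)
    outer = np.asarray(contour_outer, dtype=float)
    if inner.ndim != 2 or inner.shape[1] != 2 or len(inner) < 3:
        raise ValueError("inner contour must be (n>=3, 2)")
    if outer.ndim != 2 or outer.shape[1] != 2 or len(outer) < 3:
        raise ValueError("outer contour must be (n>=3, 2)")
    if _polygon_area(inner) < 0:
        inner = inner[::-1]
    if max_search_um is None:
        span = outer.max(axis=0) - outer.min(axis=0)
        max_search_um = float(np.hypot(*span))

    samples = _resample_closed(inner, n_samples)
    nxt = np.roll(samples, -1, axis=0)
    prv = np.roll(samples, 1, axis=0)
    tangents = nxt - prv
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])  # outward (CCW)

    centroid = inner.mean(axis=0)
    rel = samples - centroid
    angles = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))

    dists, kept_angles = [], []
    n_excluded = 0
    n_dropped = 0
    for p, nvec, ang in zip(samples, normals, angles):
        if any(_in_arc(ang, arc) for arc in exclusion_arcs):
            n_excluded += 1
            continue
        t = _ray_first_crossing(p, nvec, outer, max_search_um)
        if t is None:
            n_dropped += 1
            continue
        dists.append(t)
        kept_angles.append(ang)
    n_considered = n_samples - n_excluded
    if n_considered == 0:
        raise ValueError("all samples excluded")
    if n_dropped > 0.5 * n_considered:
        raise ValueError(
            f"{n_dropped}/{n_considered} normals failed to cross the outer contour"
        )
    d = np.asarray(dists)
    return ThicknessMeasurement(
        distances_um=d,
        sample_angles_deg=np.asarray(kept_angles),
        mean_um=float(d.mean()),
        sd_um=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        n=len(d),
        n_excluded=n_excluded,
        n_dropped=n_dropped,
        excluded_arcs=tuple(exclusion_arcs),
    )
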