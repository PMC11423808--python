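"""Group statistics and polar summaries for canal morphometry.

Two-group comparisons mirror standard small-sample bone-morphometry
practice: the Mann–Whitney U test for independent groups (exact p by full
enumeration when the combined sample is small and tie-free, otherwise the
tie-corrected normal approximation with continuity correction), and the
paired t-test for left/right within-animal contrasts.  Polar summaries bin
canal angles over (-180, 180] and report anterior/posterior percentages by
the |theta| > 90° rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .geometry import wrap_angle_deg

__all__ = [
    "PolarSummary",
    "TestResult",
    "polar_histogram",
    "mann_whitney_u",
    "paired_t_test",
    "null_rejection_rate",
    "plot_polar_histogram",
]


@dataclass(frozen=True)
class PolarSummary:
    bin_edges_deg: np.ndarray  # len nbins + 1, from -180 to 180
    counts: np.ndarray
    anterior_count: int
    posterior_count: int
    anterior_pct: float
    posterior_pct: float
    specimen_id: str = ""

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "bin_edges_deg": self.bin_edges_deg.tolist(),
            "counts": self.counts.tolist(),
            "anterior_count": self.anterior_count,
            "posterior_count": self.posterior_count,
            "anterior_pct": self.anterior_pct,
            "posterior_pct": self.posterior_pct,
        }


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _thetas(records_or_thetas) -> np.ndarray:
    arr = []
    for r in records_or_thetas:
        arr.append(r.theta_deg if hasattr(r, "theta_deg") else float(r))
    return np.asarray(arr, dtype=float)


def polar_histogram(records_or_thetas, bin_deg: float = 15.0,
                    specimen_id: str = "") -> PolarSummary:
    """Bin canal angles into right-closed bins over (-180, 180].

    Bin i covers ``(edge_i, edge_{i+1}]``; anterior/posterior counts follow
    the |theta| > 90° posterior rule.
    """
    nbins_f = 360.0 / bin_deg
    if bin_deg <= 0 or abs(nbins_f - round(nbins_f)) > 1e-9:
        raise ValueError("bin_deg must divide 360")
    theta = wrap_angle_deg(_thetas(records_or_thetas))
    theta = np.atleast_1d(theta)
    if theta.size == 0:
        raise ValueError("empty record set")
    nbins = int(round(nbins_f))
    edges = -180.0 + bin_deg * np.arange(nbins + 1)
    idx = np.ceil((theta + 180.0) / bin_deg).astype(int) - 1
    idx = np.clip(idx, 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    n_post = int(np.sum(np.abs(theta) > 90.0))
    n_ant = int(theta.size - n_post)
    return PolarSummary(
        bin_edges_deg=edges,
        counts=counts,
        anterior_count=n_ant,
        posterior_count=n_post,
        anterior_pct=100.0 * n_ant / theta.size,
        posterior_pct=100.0 * n_post / theta.size,
        specimen_id=specimen_id,
    )


def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact p by full enumeration of arrangements when ``n_a + n_b <= 12``
    and the pooled sample is tie-free; otherwise the normal approximation
    with midrank tie-corrected variance and continuity correction.  The
    method actually used is recorded in the result.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all observations identical: U at its null mean, no evidence
        return TestResult(
            test_name="mann_whitney_u",
            statistic=a.size * b.size / 2.0,
            p_value=1.0,
            n=(a.size, b.size),
            method="degenerate",
            flags={"ties": True, "degenerate": True},
        )
    if a.size + b.size <= 12 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return TestResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        n=(a.size, b.size),
        method=method,
        flags={"ties": bool(has_ties)},
    )


def paired_t_test(sample_a, sample_b) -> TestResult:
    """Two-sided paired t-test on equal-length samples.

    t = mean(d) / (sd(d)/sqrt(n)) with the n-1 denominator in sd and n-1
    degrees of freedom.  All-zero differences are degenerate and rejected.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    if np.all(d == 0):
        raise ValueError("degenerate pairing: all differences zero")
    res = sps.ttest_rel(a, b)
    return TestResult(
        test_name="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(n,),
        method=f"t, df={n - 1}",
    )


def null_rejection_rate(
    n_reps: int = 2000,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the Mann–Whitney test under the null
    (both groups drawn from one continuous distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n_per_group)
        y = rng.normal(size=n_per_group)
        if mann_whitney_u(x, y).p_value <= alpha:
            rejections += 1
    return rejections / n_reps


def plot_polar_histogram(summary: PolarSummary, path: str | Path) -> Path:
    """Render a polar histogram with anterior/posterior percentage labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = np.deg2rad(
        0.5 * (summary.bin_edges_deg[:-1] + summary.bin_edges_deg[1:])
    )
    width = np.deg2rad(np.diff(summary.bin_edges_deg))
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.bar(centers, summary.counts, width=width, bottom=0.0,
           color="#4878b0", edgecolor="k", linewidth=0.5)
    ax.set_theta_zero_location("E")  # anterior (+x) to the right
    ax.set_title(summary.specimen_id or "canal orientation")
    ax.annotate(f"anterior {summary.anterior_pct:.0f}%", xy=(0.02, 0.02),
                xycoords="figure fraction")
    ax.annotate(f"posterior {summary.posterior_pct:.0f}%", xy=(0.62, 0.02),
                xycoords="figure fraction")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_report(results: dict, path: str | Path) -> Path:
    """Emit a JSON stats report plus a human-readable text twin."""
    path = Path(path)
    path.write_text(json.dumps(results, indent=2, default=_jsonify))
    txt = Path(path.with_suffix(".txt"))
    lines = [f"{k}: {v}" for k, v in results.items()]
    txt.write_text("\n".join(lines) + "\n")
    return path


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    if hasattr(o, "__dict__"):
        return {k: _jsonify(v) for k, v in vars(o).items()}
    return str(o)
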