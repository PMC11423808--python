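"""Measure periosteal thickness as inter-edge distance between contours.

At uniformly spaced points along the inner contour the outward normal is
cast to its first crossing of the outer contour; an angular exclusion arc
removes the region a histologist would mask out (e.g. the interosseous
membrane), exactly as done on sections.
"""

import numpy as np

import cortiquant as cq

# synthetic periosteum: inner edge a 10 um circle, thickness 5 + 2 sin(2t)
inner, outer, _ = cq.generate_contour_pair(
    10.0, lambda t: 5.0 + 2.0 * np.sin(2 * t), n_points=512
)

full = cq.interedge_distance(inner, outer, n_samples=256)
print(f"full contour: mean {full.mean_um:.3f} um, sd {full.sd_um:.3f} um, "
      f"n={full.n}")

masked = cq.interedge_distance(
    inner, outer, exclusion_arcs=[(0.0, 90.0)], n_samples=256
)
print(f"with 90-degree exclusion arc: mean {masked.mean_um:.3f} um over "
      f"n={masked.n} retained samples ({masked.n_excluded} excluded)")

# The analytic mean of the profile is 5.0 over the full contour; the
# exclusion arc removes the thick lobe in the first quadrant (where
# sin(2t) > 0), so the retained mean drops below 5.
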