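"""Unwrap the endocortical surface into a cylindrical panorama.

Stitch mode reproduces the rotate-and-stitch workflow (18 views at 20-degree
steps, each cropped to its central quarter); resample mode maps (theta, z)
directly to the radius of first bone contact.  Canal openings appear as
gap patches whose centroids localize each canal on the unwrapped surface.
"""

import cortiquant as cq
from cortiquant import panorama

spec = cq.PhantomSpec(
    canal_specs=(
        cq.CanalSpec(theta_deg=90.0, z_frac=0.5, diameter_um=24.0),
        cq.CanalSpec(theta_deg=-140.0, z_frac=0.3, diameter_um=20.0),
    ),
    lacuna_count=0,
    seed=3,
)
volume, truth = cq.generate_phantom(spec)
result = cq.quantify_volume(volume)

stitched = panorama.unwrap_stitch(result.bone, result.axis, theta_step_deg=20.0)
print(f"stitch mode: {stitched.views_generated} views, "
      f"panorama {stitched.values.shape} (z rows x theta columns)")

resampled = panorama.unwrap_resample(result.bone, result.axis)
print(f"resample mode: unwrapped width {resampled.physical_width_um():.0f} um "
      f"(mean endosteal perimeter)")

print("\ncanal openings located on the panorama (theta deg, z um):")
for theta, z in sorted(resampled.gap_centroids()):
    print(f"  ({theta:8.2f}, {z:7.1f})")
print("truth positions:")
for c in truth.canals:
    print(f"  ({c.theta_deg:8.2f}, {c.z_um:7.1f})")
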