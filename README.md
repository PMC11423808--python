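# cortiquant

3D quantification of **trans-cortical canals** in long-bone cortices from
high-resolution CT, with a synthetic phantom generator that provides exact
ground truth for every stage.

## The problem

During growth, long bones such as the mouse fibula change shape by *paired*
remodeling across the cortex: osteoclasts resorb one surface while
osteoblasts deposit bone on the opposite one. Cortices undergoing
endocortical formation are pierced by **trans-cortical canals** — channels
running from the periosteum to the endosteum that carry vessels and
migrating osteoprogenitors. Quantifying these canals in nano-CT volumes
(≈1.27 µm voxels) means answering, per specimen:

- how many canals cross the cortex, excluding osteocyte lacunae and the
  single large nutrient foramen;
- how wide each canal is (minor axis *b* of the best-fitting ellipse of its
  canal-perpendicular cross-section);
- where each canal sits around the shaft — the polar angle θ ∈ (−180°, 180°]
  of its center of gravity about the marrow z-axis, measured from the
  anterior direction, with |θ| > 90° defining the *posterior half*;
- the canal density per mm² of endocortical surface, and the fraction of
  canals in the posterior half — the readout that distinguishes normally
  loaded from unloaded bones.

The marrow z-axis is the line through the centers of gravity of the marrow
cavity in the first (most proximal) and last (most distal) slices. The
endocortical surface can also be unwrapped into a cylindrical panoramic
image — either by stitching views rendered every 20° of rotation (18 views
per revolution) or by direct (θ, z) resampling of the surface radius —
so canal openings can be seen and localized on a flat map.

Because the original CT volumes of such studies are rarely deposited, the
package ships a first-class **phantom generator**: a hollow elliptic-
cylindrical cortical shell with straight tubular canals at specified
(θ, z, diameter, inclination), ellipsoidal lacunae, an optional nutrient
foramen, partial-volume blur and Gaussian noise — plus a truth ledger of
every carved structure. All validation is parameter recovery against this
ground truth.

A 2D module measures **periosteal thickness** as the inter-edge distance
between two contours (outward normals from the inner edge to their first
crossing of the outer edge) with angular exclusion arcs for regions like
the interosseous membrane. Group comparisons use the Mann–Whitney U test
(exact by full enumeration for small tie-free samples) and the paired
t-test.

## Worked example

```python
import cortiquant as cq
from cortiquant import geometry

spec = cq.random_phantom_spec(seed=42, n_canals=6, with_foramen=True,
                              lacuna_count=25)
volume, truth = cq.generate_phantom(spec)
result = cq.quantify_volume(volume)

for rec in sorted(result.canal_records, key=lambda r: r.theta_deg):
    print(f"theta {rec.theta_deg:8.2f}  d {rec.diameter_um:5.1f} um")
frac, n_post, n = geometry.posterior_fraction(result.canal_records)
print(f"posterior fraction: {n_post}/{n} = {100*frac:.1f}%")
```

prints (seed 42):

```
theta  -115.77  d  28.5 um
theta   -69.93  d  16.5 um
theta   -17.85  d  20.9 um
theta    16.67  d  24.8 um
theta    76.36  d  18.6 um
theta   134.19  d  16.9 um
posterior fraction: 2/6 = 33.3%
```

All six carved canals are recovered; angles agree with the truth ledger to
≪1° and diameters to ≪1 voxel, the 60 µm foramen is recognized and
excluded, and the posterior fraction equals the truth exactly. The
`examples/` directory holds one short script per capability (simulation,
quantification, panoramic unwrapping, thickness, group statistics); each
prints the numbers it computes and what they mean.

A thin CLI wraps the same pipeline:

```bash
cortiquant simulate --canals 6 --seed 1 --out sim/
cortiquant quantify sim/phantom.tif --voxel-size-um 1.27 --out quant/
```

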