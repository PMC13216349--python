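# myoshear

Cardiomyocytes are usually modelled as if every myofibril ran perfectly
parallel to the cell's long axis. Volume electron microscopy says otherwise:
the z-discs that bound each sarcomere — and whose plane normals track the
local myofibril direction — deviate from the contraction axis by up to ~30°,
with a near-Gaussian signed distribution (mean ≈ 0.03°, sd ≈ 6.56°). Because
passive myocardium is strongly anisotropic along the fibre, even these small
local tilts reshape the intracellular stress field during contraction,
producing internal rotation, off-axis deformation, and shear stresses that a
uniaxial model cannot generate.

`myoshear` is a tested Python implementation of that analysis chain for
people working on cell-scale cardiac mechanics:

1. **synthetic z-disc volumes** (`myoshear.synthetic`) — instance-labelled
   voxel volumes of disc-shaped z-discs on parallel myofibril tracks, with
   known ground-truth normals, spacings (sarcomere slack length 1.8–2 μm)
   and thicknesses (100–140 nm), replacing unpublished microscopy data;
2. **orientation morphometry** (`myoshear.morphometry`) — per-instance PCA
   of the physical voxel cloud: the third principal component is the disc
   normal, the first principal component of the pooled cloud is the
   contraction axis, and signed spherical/azimuth/elevation angles are
   reported with 1.5°-binned population statistics and per-region
   Mann-Whitney U + Welch tests;
3. **fibre fields** (`myoshear.fibres`) — nearest-neighbour mapping of disc
   angles onto the nodes of a quadratic tetrahedral mesh and anisotropic
   Gaussian smoothing (sd 1.9 μm along the fibre, 0.12 μm transversely),
   plus the fibre-aligned orthonormal frames used by the solver;
4. **contraction** (`myoshear.solver`) — incompressible transversely
   isotropic Guccione hyperelasticity,

   Ψ = c₁/2·(e^Q − 1),  Q = b_f·E_ff² + b_t·(E_tt²+E_ss²+E_ts²+E_st²) + b_s·(E_fs²+E_sf²+E_tf²+E_ft²),

   with b_t = b_s (transverse isotropy) and converged constants
   c₁ = 2.81 kPa, b_f = 12.68, b_t = b_s = 11.04. The mixed
   displacement/pressure weak form (Taylor–Hood P2/P1 tetrahedra,
   incompressibility enforced by a pressure Lagrange multiplier) is solved
   by incremental Newton iteration: end faces displaced 2% per step to 20%
   total shortening, fixed in y and z;
5. **post-processing** (`myoshear.analysis`) — y-z plane rotation about the
   contraction axis, interior-averaged Cauchy stresses (hydrostatic pressure
   omitted, boundary layers excluded), shear trends over the loading
   history, shear-vs-orientation regressions and cluster comparisons.

The solver follows the statsmodels convention: `ContractionModel(...)` is
built from a mesh and fibre field, `fit()` runs the incremental solve and
returns a `ContractionResults` with the displacement/pressure states,
kinematics, stresses and a `summary()` table.

## Worked example

```python
import numpy as np
from myoshear import (SyntheticCellParams, generate_cell_volume, analyse_volume,
                      build_prism_mesh, FibreField, ContractionModel)

# synthetic cell: ~1.1k z-discs, isotropic 0.05 um voxels, known statistics
params = SyntheticCellParams(seed=42)
volume, truth = generate_cell_volume(params)
records, stats, axis = analyse_volume(volume)
print(f"instances: {stats.n}")
print(f"signed deviation: mean = {stats.mean:+.2f} deg, sd = {stats.sd:.2f} deg")
frac = 100 * np.mean(np.abs(records['theta']) < 1.0)
print(f"within 1 deg of the contraction axis: {frac:.1f}%")

# uniaxial reference contraction with free lateral end motion
mesh = build_prism_mesh((11.0, 11.0, 5.0), (4, 4, 2))
model = ContractionModel(mesh, FibreField.uniaxial(mesh.n_nodes),
                         end_constraint="frictionless")
print(model.fit().summary())
```

prints

```
instances: 1152
signed deviation: mean = +0.41 deg, sd = 6.61 deg
within 1 deg of the contraction axis: 12.9%

Incompressible Guccione contraction
===================================================
mesh: 160 quadratic tets, 373 nodes, 1194 dofs
region: 11 x 11 x 5 um, constraint: frictionless
material: c1=2.81 kPa, b_f=12.68, b_t=b_s=11.04
loading: shorten to 20% in 10 increments
---------------------------------------------------
step  frac   iters  |R|        interior stress (kPa)
                               s_xx     s_xz     s_yz
   1  0.02     3    3.8e-08   -0.682   -0.000    0.000
   ...
  10  0.20     3    5.5e-07   -8.740   -0.000   -0.000
---------------------------------------------------
max |J-1| (interior, final step): 3.64e-10
```

The recovered angle statistics match the generator (population mean 0.03°,
sd 6.56°) to within sampling error, only ~12% of discs lie within 1° of the
axis, and the axis-aligned reference produces zero xz/yz shear. The final
axial stress, −8.74 kPa, equals the closed-form homogeneous incompressible
Guccione response at stretch 0.8 to machine precision (the built-in solver
oracle `homogeneous_uniaxial_response`). With the end faces clamped in y and
z — the simulated cell-region condition — boundary layers raise the interior
axial stress magnitude to ~10.6 kPa.

A command-line pipeline mirrors the library:

```sh
myoshear synth --seed 1 --out run/
myoshear morph --labels run/labels.tif --out run/
myoshear field --labels run/labels.tif --records run/orientation_records.csv --out run/
myoshear simulate --fibres run/fibre_field.csv --out run/
myoshear post --fibres run/fibre_field.csv --out run/
```

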