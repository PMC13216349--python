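# Methods

This note documents the models, conventions and numerical choices behind
`myoshear`, and what the synthetic-data tests do and do not establish.

## Orientation morphometry

Each z-disc instance is a connected set of labelled voxels. All geometry is
computed on *physical* coordinates (voxel indices scaled by the per-axis
voxel size in μm) so that anisotropic acquisitions are handled correctly.
The disc normal is the third principal component of the instance's voxel
cloud: the first two components span the disc face, and for an oblate disc
the third is its symmetry axis. The contraction axis is the first principal
component of the pooled voxel cloud of all instances. Both are sign-fixed
to a non-negative x component; instances whose two smallest variances tie
(a face viewed edge-on) are resolved toward the candidate with larger |x|
component, and the event is logged.

Angles, all in degrees, are measured in the frame in which the contraction
axis is +x (reached by the minimal rotation taking the axis to +x):

* azimuth — signed angle of the (x, y) projection of the normal;
* elevation — signed angle of the (x, z) projection;
* spherical deviation θ — magnitude arccos(n·axis), *signed by the
  elevation*: the angle between two vectors is inherently non-negative, and
  attaching the x–z sign is the convention that makes the spherical and
  elevation distributions co-vary for populations tilted predominantly in
  the x–z plane, which is the coupling seen in regional cluster data. This
  is a convention choice; the magnitude and the azimuth/elevation pair are
  reported alongside so no information is lost.

Population statistics use sample sd (ddof = 1), Fisher skew, and *both*
kurtosis conventions (Fisher, normal = 0; Pearson, normal = 3) in separate,
explicitly named fields, since reported single-number kurtoses are
ambiguous. Histograms default to 1.5° bins covering the observed range.
Regional tests compare each region's angles with the global set using
two-sided Mann-Whitney U and Welch's t; a region is flagged significant only
when both give p < 0.05 (the conservative combination), with no
multiple-testing correction. Degenerate regions are flagged untestable
rather than raising. Instances below `min_voxels = 10` are dropped (and
counted): smaller fragments are rank-deficient for PCA.

## Synthetic z-disc volumes

The generator emulates the features of a rod-shaped cardiomyocyte that the
morphometry relies on; defaults are the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| volume | 22 × 15 × 10 μm | ≥ 1000 instances at the default track pitch |
| voxel size | 0.05 μm isotropic | ≤ half the disc thickness, so the disc is resolved along its normal; the anisotropic EM spacing (0.11, 0.11, 0.5 μm) is available as a stress-test preset but under-samples 0.1 μm discs |
| tracks | 96, jittered lattice, pitch ≈ 1.25 μm | myofibril calibre ≈ 1 μm |
| disc diameter | 1.0 μm | myofibril cross-section |
| disc thickness | U(0.10, 0.14) μm | reported cardiac z-disc range |
| spacing | U(1.8, 2.0) μm | sarcomere slack length |
| angle distribution | Normal(0.03°, 6.56°), azimuth uniform | measured global population; no azimuthal anisotropy |

Discs are voxelised as solid oblate ellipsoids whose symmetry axis is the
sampled normal; voxel conflicts are resolved first-writer-wins (deterministic
and cheap) with a logged overlap count. By default the tracks share one set
of striation planes with a small (±0.05 μm) per-disc longitudinal jitter:
z-discs of neighbouring myofibrils are laterally registered in real cardiac
muscle (that registration is the striation pattern), and without it the
random per-track phase imbalances tilt the pooled-PCA contraction axis by a
few tenths of a degree, which is an artefact of the generator rather than of
the pipeline. Independent per-track spacings remain available
(`registered_striations=False`) and are used for the spacing-recovery study,
where independent draws are the point.

The generator does **not** emulate EM texture or noise, membrane/organelle
exclusion volumes, or the curvature of real discs around mitochondria and
nuclei — discs are flat ellipsoids. Recovery results on synthetic data
therefore bound the *geometric* fidelity of the PCA pipeline (voxelisation
and sampling error) but say nothing about segmentation quality on real
micrographs, and population statistics on real cells may deviate more where
discs curve.

With the defaults, per-instance normal recovery error is ≈ 0.3° (median)
and < 2° for ≥ 95% of instances; the recovered population sd exceeds the
generated sample sd by well under the 0.5° acceptance margin, and the
recovered fraction within 1° of the axis lands at the ~12% implied by a
Normal(0.03°, 6.56°) population.

## Fibre field

Mesh nodes take the angles of their nearest z-disc voxel (cKDTree; nodes
inside a disc get that disc's angles; exact ties go to the lowest instance
id, logged). Smoothing acts on the (azimuth, elevation) *angle* components,
not on raw vectors: at the small angles involved (< 30°) angle averaging
avoids the shrinkage bias of naive vector averaging, and the smoothed field
is renormalised to unit directions afterwards. The kernel is a normalised
anisotropic Gaussian with sd 1.9 μm along x (sarcomere slack length — the
scale over which myofilaments connect consecutive discs) and 0.12 μm
transversely (z-disc thickness), the midpoints of the quoted ranges. The
kernel is axis-aligned rather than rotated per-point: the fields are
near-axial, so the difference is second order in the tilt. Constant fields
are exact fixed points; smoothed values are convex combinations of the raw
values.

Local frames: A₁ = f with A₂, A₃ completed by the minimal rotation taking
+x to f (rotation axis e_x × f). This is unique and continuous because the
field invariant f_x > 0 excludes the antiparallel singularity, and it
reduces to the Cartesian triad for f = e_x. The frames are orthonormal, so
the undeformed metric G_ij = A_i·A_j is the identity and the Christoffel
symbols of the material frame vanish; the curvilinear machinery
(`myoshear.curvilinear`) implements the general formulas and is verified
against symbolic differentiation on genuinely curvilinear metrics, and the
index-form internal work T^{αβ} F^j_β ∇_α v^j is verified to integrate to
the same value as the Cartesian total-Lagrangian assembly.

## Contraction solver

Incompressible transversely isotropic Guccione hyperelasticity in mixed
form. The second Piola-Kirchhoff stress entering the weak form is
S = ∂Ψ/∂E + p J C⁻¹: the constitutive part (evaluated in the fibre frame
and rotated back) plus the pressure term, the unique two-term decomposition
consistent with P = JσF⁻ᵀ + pJG⁻¹F⁻ᵀ. The pressure multiplies +J C⁻¹ and
vanishes in the stress-free state. Reported Cauchy stresses omit the
hydrostatic term (σ = J⁻¹ F S_con Fᵀ); the total is available behind
`include_pressure=True`.

Discretisation and solution:

* 10-node quadratic tetrahedra for displacement, 4-node linear for pressure
  (Taylor-Hood pairing, inf-sup stable); degree-4 Keast quadrature
  (11 points), exactness verified against closed-form monomial integrals.
* The structured prism mesh splits each hexahedral cell into five
  tetrahedra with alternating chirality (conforming); with even subdivision
  counts the triangulation is mirror-symmetric about all three centre
  planes, so symmetric problems have symmetric discrete solutions — the
  uniaxial run's mean shear and mean rotation vanish to round-off rather
  than to discretisation error.
* Loading: prescribed end-face displacements in 2% increments to 20% total
  shortening, split symmetrically (10% per face; the split is a convention
  — the interior state depends only on the total). Default is shortening;
  a `stretch` mode exists because passive constants are conventionally
  calibrated against tension. Clamped ends fix y and z ("the simulated
  condition"); a frictionless variant (x prescribed, lateral motion free,
  minimal rigid-body pins on the centreline) admits the homogeneous
  closed-form solution and serves as the solver oracle.
* Newton iteration per increment with a finite-difference element tangent
  (all 34 element dofs perturbed in one vectorised pass, ε = 10⁻⁶);
  convergence when the relative increment norm < 10⁻⁵ or the residual
  drops below 10⁻⁵ of its step-initial value, with at most 50 iterations.
  A failed increment (non-convergence or element inversion J ≤ 0) is
  halved and retried, at most three halvings deep.
* Units: lengths μm, stresses and pressure kPa. The exponent coefficients
  b_f, b_t, b_s are treated as dimensionless (the exponent Q must be
  dimensionless); c₁ carries the stress unit.

Verification: the frictionless uniaxial run reproduces the closed-form
incompressible response F = diag(λ, λ^-1/2, λ^-1/2) — stresses, pressure
and J = 1 — to machine precision, because the homogeneous solution lies in
the discrete space. Objectivity (joint rotation of geometry, fibres and
boundary displacements maps σ to RσRᵀ) and the ±tilt mirror antisymmetry of
σ_xz hold to solver tolerance.

## Post-processing

* Rotation: on the plane of nodes at mid-length in x (the plane farthest
  from the constrained ends), positions are centred on the plane centroid
  in both configurations and the signed y-z angle from undeformed to
  deformed position vector is reported (counter-clockwise positive viewed
  from +x). Rigid rotations are reproduced exactly; translations and
  radial (isotropic in-plane) motion give zero. Nodes at the centroid have
  no defined angle and are excluded.
* Interior stress means: volume-weighted quadrature averages over the box
  scaled by 0.9 *per axis* about the centroid (72.9% of the volume), one
  reading of "internal 90% volume"; the fraction is a parameter.
* Regressions: equally weighted ordinary least squares of regional mean
  shear on regional mean orientation (and variance on variance), with
  Pearson R, optionally per cluster; pairwise cluster comparisons use
  Welch's t at 0.05 without correction.

## Problem sizes

The working ("desk") resolution for the 11 × 11 × 5 μm region is 8 × 8 × 4
subdivisions (1280 quadratic tets, ≈ 8.2 k dofs). The built-in
`convergence_study` helper quantifies refinement: the interior mean axial
stress changes by 0.4% from 8 × 8 × 4 to 10 × 10 × 6 (3000 tets, ≈ 18 k
dofs) and by 1.0% from 6 × 6 × 2, so interior averages are converged well
inside 2% at the working resolution. The synthetic recovery volume uses
≈ 1150 instances on a 440 × 300 × 200 voxel grid.

## Known limitations

* **Clamped-face boundary layers.** Fixing y and z on the end faces of a
  rectangular section creates edge/corner stress concentrations. Three
  consequences, all properties of the boundary-value problem rather than of
  the discretisation: (i) the interior mean axial stress magnitude depends
  on the averaging box — at 20% shortening ≈ 9.5 kPa over the whole box,
  ≈ 10.6 kPa over the 0.9-per-axis interior, ≈ 12.3 kPa in the deep core,
  versus 8.74 kPa for the free-lateral homogeneous response; (ii) the y-z
  rotation field on the central plane is antisymmetric — mean and median
  are zero to round-off, quartiles ≈ ±0.07° — but its pointwise maximum
  (≈ 0.44°, stable under refinement) is not zero, because the lateral
  contraction reaching the mid-plane is slightly anisotropic between the
  11 μm and 5 μm cross-section directions; (iii) pointwise |J − 1| at
  quadrature points does not converge uniformly near the clamped corners
  (≈ 0.17 max over the 0.9-interior box at desk resolution, ≈ 10⁻² at the
  half-box, median ≈ 2 × 10⁻³ and improving with refinement), although the
  constraint holds weakly by construction and exactly (10⁻¹⁰) for the
  smooth frictionless solution. Statements that the uniaxial case "does not
  rotate" are therefore statements about the distribution's centre, not its
  extremes.
* The generator's flat discs and isotropic azimuth are idealisations; real
  discs curve near organelles.
* No active-tension model, no viscoelasticity, no contact; material
  constants are taken as given, not re-calibrated.
* The smoothing kernel is axis-aligned, appropriate for near-axial fields
  only.
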