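# Methods

## Physical model

At the TTFields operating frequency (200 kHz) tissue behaves as a
resistive volume conductor: displacement currents are small against
conduction currents, so the potential obeys the conductivity-weighted
Laplace equation ∇·(σ∇φ) = 0 with real, isotropic σ. Permittivity is
carried in the data model but ignored by the solver; field distributions
in this regime are dominated by conductivity, and a complex-admittivity
mode is deliberately out of scope.

Each channel (AP–PA and LEFT–RIGHT) is solved independently with
Dirichlet potentials ±V₀/2 on its anode/cathode electrode voxels and
natural zero-flux conditions on all air boundaries; the other channel's
gel and electrode voxels are present only as passive conductive
material. Because the device alternates between channels, a single
summary map is a modelling choice: the package exposes `per_channel`,
`average` (default — the time-average of the alternation) and `max`
combination of the |E| and |J| magnitude maps.

### Drive normalization

The solution of the linear system is computed at a unit drive and then
rescaled so the delivered channel current equals a target (default
0.9 A per channel). Current- rather than voltage-normalization was
chosen because reported plan metrics scale linearly with drive amplitude,
which is a device property, not a montage property; with a fixed current
the montage comparison is well posed. All comparative claims are
invariant to this choice; absolute field values are not.

## Discretization and linear solver

Cell-centered finite volumes on the voxel grid: the face between two
voxels carries conductance g = σ_harm · A/d with σ_harm the harmonic
mean of the two voxel conductivities (exact for layered series
composites), A the face area and d the center distance. This yields a
symmetric positive-definite 7-point system whose discrete currents are
conserved exactly at every interior cell. Air voxels (σ = 0) are excluded
from the domain, which realizes the zero-normal-flux boundary condition.

The system is solved by conjugate gradients with Jacobi (diagonal)
preconditioning from a zero initial guess, relative tolerance 1e-8
(≈1100–2900 iterations for the default head at 4 mm, about 1–3 s per
channel); systems below 2000 unknowns use a sparse direct solve. The
diagonal scaling is what makes CG practical here: tissue conductivities
span six orders of magnitude (skull 0.01 S/m to electrode 1e4 S/m).
Everything is deterministic — no seed enters the solver.

E = −∇φ uses central differences where both axial neighbors are in the
domain and one-sided differences at domain/material boundaries; J = σE
voxelwise. Channel current is the discrete surface integral of J·n over
the electrode patch faces, evaluated with the same face conductances as
the solve, so the anode/cathode balance reflects only the linear-solver
residual (measured ~1e-7 relative).

## Synthetic phantom

The phantom emulates the product of a segmented head MRI as a labeled
voxel volume in RAS world coordinates (voxel-center convention):

* Nested ellipsoid shells: scalp (semi-axes 82 × 102 × 88 mm), skull,
  CSF and brain, with shell thicknesses 8 / 8 / 4 mm. Thicknesses are
  integer multiples of the working grid spacings (4 mm default, 2 mm
  fine) so the thin shells rasterize consistently rather than aliasing;
  the builder rejects grids on which the skull shell would be under two
  voxels thick.
* A posterior-inferior cerebellar ellipsoid compartment, a brainstem
  cylinder, and a spherical GTV (default radius 12 mm, necrotic core
  4 mm) placed dorsally at the midline of the posterior fossa — the
  geometry of interest for the montage comparison. GTV size and depth
  are free parameters, not calibrated to any patient.
* A neck cylinder (skin over muscle over vertebral bone) below the skull
  base so that the PA array variants can sit on the lower occiput and
  upper neck with a realistic conductive return path.
* Finer anatomy (vessels, parotid glands, mandible, tongue, epidural
  tissue) is collapsed into the generic soft-tissue label; the label
  vocabulary reserves distinct codes so real segmentations can be loaded.

Default conductivities (S/m, configurable): scalp 0.465, skull 0.010,
CSF 1.654, brain/cerebellum/brainstem 0.276, muscle 0.355, vertebra
0.010, GTV 0.24, necrotic core 1.0, gel 4.0, electrode 1e4. These are
literature-style values at 200 kHz, not measurements from any specific
study.

The phantom is left/right mirror-symmetric by default, which makes the
±2 cm lateral-shift comparison interpretable as a pure symmetry test. A
seed-driven jitter option displaces the head-shell center by a uniform
random offset so tests can cover asymmetric anatomy.

### What the phantom does and does not emulate

It reproduces the topology that matters for the transcranial current
problem — resistive skull shell, conductive CSF film, a posterior-fossa
target near the occiput, a neck return path — but not gyral folding,
anisotropic white matter, ventricles, or realistic scalp-muscle
geometry. Tests passing on the phantom therefore validate the machinery
and the comparative geometry argument (proximity of arrays to a
posterior-fossa target), not patient-specific field predictions.

## Montage geometry

Arrays are placed by parallel ray casting: the nine disc target points
of a 3×3 array (pitch 22 mm, disc radius 10 mm) are laid out on the
plane through the array anchor perpendicular to the outward placement
direction, and each is projected onto the scalp along that direction
(sampled at quarter-voxel steps, refined by bisection to sub-voxel
precision). This conforms the array to convex scalps; geodesic unrolling
for strongly non-convex surfaces is a documented non-goal.

The supratentorial baseline puts the AP array on the forehead, the PA
array high on the occiput and the laterals over temporoparietal scalp.
The six posterior-fossa alternatives share posteriorly displaced,
slightly rotated (default 15°) lateral arrays and differ in the PA
array: horizontal on the posterior neck (long axis left–right), the same
shifted ±20 mm laterally, or vertical (long axis superior–inferior) at
two heights. All anchor directions, offsets and rotations are explicit
configuration parameters with documented defaults — they encode a
geometric reading of the published montage figures, not measured
coordinates.

Rasterization turns each disc into the one-voxel air layer in contact
with the body inside the disc footprint (conductive gel) capped by the
adjacent air layer (electrode). By construction electrodes touch the
body only through gel, and anatomy labels are never modified.

One consequence of the idealized square 3×3 array: rotating an array 90°
about its center maps its nine target points onto themselves, so
`AP_PA_HORIZONTAL` coincides exactly with `PA_HORIZONTAL` in this model.
This is consistent with published observations that the rotation changes
the metrics only marginally; the configuration is kept as a distinct
name because physical arrays are not perfectly square-symmetric.

## Plan-quality metrics

The EVH/CDVH uses exact voxel counting with the closed "≥ threshold"
convention; ties in the percentile computation resolve toward the larger
threshold ("at least x% of the volume at or above t"). `E_AUC`
integrates the fraction-vs-threshold curve from 0 to the ROI maximum;
with per-unique-value thresholds (the default inside `pqm`) the
right-Riemann rule makes the layer-cake identity exact, so `E_AUC` is
precisely the ROI mean magnitude. Sampled curves (default 2048 uniform
thresholds, used for exported histogram CSVs) use the trapezoidal rule.
Fractional (0–1) volume is used on the y-axis, which makes AUC values
commensurate with median field intensities. Voxels are weighted equally;
partial-volume weighting is out of scope. Volume-coverage thresholds are
fixed at 75/50/25 V/m for E and 15/10/5 A/m² for current density.

Reported tables round half-up to one decimal. Percent changes recomputed
from rounded table entries can differ from values printed from unrounded
internals; the report flags differences ≤ 0.3 percentage points as
rounding-consistent rather than asserting equality.

## Numerical behavior and limitations

* **Analytic accuracy.** On homogeneous and layered slabs the solver is
  exact to solver tolerance (parallel-plate field error ~1e-14; series
  two-layer field ratio and normal-J continuity to 1e-6 or better).
* **Symmetry.** On the symmetric phantom, symmetric montages give |E|
  fields mirror-symmetric to ~1e-7 relative, and the ±2 cm PA shift
  pair agrees on GTV metrics to ~1e-5 relative.
* **Grid sensitivity of absolute values.** The absolute intracranial
  field scale shifts with voxel size (about 20% between 4 mm and 2 mm on
  the default phantom), dominated by the staircase rasterization of the
  high-contrast skull shell; the CSF film contributes secondarily. The
  *distribution* of the field is grid-stable — the GTV-to-cerebellum
  mean-|E| ratio changes by under 2% between 4 mm and 2 mm — as are the
  montage comparisons. The package therefore claims comparative
  quantities (rankings, ratios, percent gains) and treats absolute
  magnitudes as resolution- and drive-dependent. A boundary-conforming
  FEM would be required to pin absolute values.
* **Problem sizes.** The default analysis grid is 4 mm (~60k unknowns
  per solve, ~1–3 s per channel; the full seven-montage comparison runs
  in under a minute), with 2 mm (~470k unknowns) for fine runs. These
  defaults keep the full test suite and the end-to-end reproduction
  script fast on a single CPU.
* **Determinism.** The only random element anywhere is the optional
  phantom jitter, driven by the `PhantomSpec` seed; identical configuration and
  seed reproduce every metric CSV byte for byte.
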