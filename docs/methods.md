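# Methods

This note documents the models, numerical choices and limitations behind
`osteolattice`, module by module, in the order the pipeline runs.

## Compression-curve analytics (`curves`)

A record is either a `(strain, stress)` table or a force–displacement
record converted to engineering stress and strain (σ = F/A, ε = d/l₀),
with all compressive quantities reported as positive magnitudes.
Records that include the preconditioning protocol — a hysteresis loop
cycled between 0.16 and 0.33 MPa before the final ramp — are trimmed by
keeping everything after the last downward crossing of the 0.16 MPa
level; strain is re-zeroed at the ramp start so the plateau window
refers to deformation accumulated during the final ramp.  Records that
never cross downward are kept whole.

**Modulus.**  The "quasilinear range" of a cellular-solid curve has no
sharp definition, so E is the maximum over sliding windows of the
ordinary-least-squares slope of stress on strain.  Defaults: window span
1 % strain, search restricted to strain < 20 % (both configurable).
Only windows covering the full span with ≥ 3 samples count, which keeps
a noisy tail fragment from winning the search.  A toe region or
post-yield softening can only lower a window's slope, so the estimate is
robust to both.  The window choice is the main tunable: curves whose
quasilinear branch is shorter than the window will be underestimated.

**Yield.**  σ_y is the stress at the first intersection of the curve
with the offset line σ = E·(ε − 0.002).  Curve and line are treated as
piecewise linear between samples; the first sign change of their
difference beyond 0.2 % strain is bracketed and solved by linear
interpolation, so the result is exact for sampled piecewise-linear
curves and sampling-density invariant otherwise.  A curve that never
crosses the line before 20 % strain (e.g. a purely elastic record) is a
"no yield" error, not a number.

**Plateau.**  σ_p is the trapezoidal (strain-weighted integral) average
of stress over ε ∈ [0.20, 0.40], with interpolated endpoint values, and
is therefore invariant to sampling density — a raw sample mean is not,
which is why it is not the default.  Records ending before 40 % strain
get `sigma_p = None` plus a warning flag rather than an extrapolation.

## Curve estimation (`curvefit`)

Power (y = a·x^b) and exponential (y = a·e^(bx)) models are fitted by
OLS on the log-transformed data; linear models directly.  R² and the
p-value (F-test of the single regressor, identical to the two-sided t
test of the slope) are reported in the transformed space, matching the
convention of the classic SPSS-style "curve estimation" used when such
calibration tables are published.  Whether published R² for power fits
refers to log or linear space is usually unstated; log space is the
documented default here.  A nonlinear least-squares refinement
(Levenberg–Marquardt, initialised at the log-space estimate) is
available behind a flag for sensitivity checks, never as the default —
log-space fitting is exactly identifiable on noiseless model data, which
the tests exploit.  A constant response returns slope 0, R² = 0, p = 1
rather than NaN; constant regressors and non-positive values for the
log-transformed models are errors.

The exponential family printed in pull-out tables as "y = a·e^b" is
interpreted as y = a·e^(b·x): it is the only two-parameter exponential a
curve-estimation routine fits.

## HU → t/L inversion (`parametrize`)

For each mechanical parameter with power laws on both sides the strut
ratio solves u·(t/L)^v = a·HU^b in closed form:
t/L = (a·HU^b/u)^(1/v).  The central correctness property — evaluating
the lattice law at the returned ratio reproduces the bone property to
floating-point accuracy — is enforced by a property-based test over
random law/HU combinations.

The final ratio is the arithmetic mean over the parameters present in
both calibrations.  Calibration entries whose constant is non-positive
are skipped with a warning: the bundled human-bone plateau-stress
constant rounds to 0.000 in print, so only the modulus and yield-stress
inversions contribute there, and the three published per-vertebra ratios
can be bracketed and ordered but not reproduced exactly.  Which HU feeds
the inversion (whole-body, hemisphere, screw-side) is a configuration
choice; the default is the hemisphere being modeled.

Ratios outside the characterized span [0.1, 0.4] — the range the printed
porosity series covers — are clamped with a warning: extrapolating the
lattice law beyond what was printed and tested has no physical support.

## Lattice geometry (`lattice`)

The cell is a regular hexagon of side L in the xy-plane with struts of
diameter t along its edges and vertical struts of length L rising from
its corners; cells stack directly above one another (AA stacking), as
the vertical connecting bars require.  Struts are circular cylinders
(the published geometry gives a strut *diameter*), and junctions are
closed by spheres of diameter t so that unions are watertight.  The
printable floor t = 0.4 mm is the default diameter.

All solids are built as signed-distance-like fields sampled on a voxel
grid (distance to the nearest strut axis minus radius); Boolean union
and intersection are pointwise min/max, and surfaces are extracted by
marching cubes on the zero level.  Sub-voxel accuracy comes from the
continuous field (not binary occupancy); default pitches are 0.05 mm for
unit cells and 0.25 mm for full specimens.  Exact mesh CSG was rejected:
on many-strut unions and segmentation-grade surfaces it fails
unpredictably, while voxel CSG degrades gracefully and always returns a
closed, watertight mesh.  The test suite verifies mesh volume against an
independent occupancy count at finer pitch (2 % agreement).

**Relative density.**  Counting 3 in-plane and 2 vertical struts per
hexagonal prism cell (volume (3√3/2)L³) gives the leading-order
ρ = (5π/6√3)·(t/L)².  The default returned value refines this with a
junction correction: struts carry spherical caps (+5·(4/3)π(t/2)³ per
cell) and the material double-counted where five struts interpenetrate
at each node (two nodes per cell) is subtracted.  The per-node overlap
has no convenient closed form; it is evaluated once per ratio by fine
local voxel counting of the node neighbourhood and cached.  The
corrected value tracks an independent whole-cell occupancy count within
about 1 % across t/L ∈ [0.1, 0.4], where the uncorrected estimate drifts
to +26 % at t/L = 0.4.

**Test specimens.**  Cylinders with length = 2 × diameter; the diameter
defaults to 10 × the largest lattice spacing, interpreted as the
across-corners hexagon diameter 2L (the largest repeating void
dimension).  The lattice is clipped at the cylinder wall — partial
struts survive, as they do in a physical print — and fused with two
1 mm end plates.  The vertical period is taken as exactly L (the layer
pitch is not dimensioned independently of the strut length).

## HU extraction (`ctvol`)

The bone mask is a threshold (default lower bound 150 HU — the published
workflow reports none, so this is a package default chosen to capture
cortex against soft tissue) with hole filling per slice and in 3-D, so a
closed cortical shell yields a filled body.  Erosion uses the Euclidean
distance transform with the physical voxel spacing, which handles
anisotropic voxels exactly and makes erosion radii additive.  The
default radius of 3 mm must exceed the cortical thickness; it is the
parameter to check first on new data.  Hemisphere means split the mask
at the sagittal plane through the mask centroid along the left-right
axis, which is read from the volume's orientation metadata — never
guessed from array order.  A midline-anchored split is available as an
alternative by passing a pre-split mask.

## Whole-bone models (`bonemodel`)

Inputs are the outer and inner cortical surfaces as watertight meshes.
Validation remeshes to a 0.8 mm target edge (longest-edge subdivision),
then checks watertightness, containment of the inner surface, and
non-intersection; all point-in-volume queries run against a voxelized
interior (surface subdivided below the pitch, crust stamped, interior
flood-filled), which keeps the package free of spatial-index
dependencies.  The lattice is tiled over the inner bounding box with its
vertical struts along z (the cranio-caudal, i.e. compression, axis),
clipped to the inner volume by voxel occupancy — clipped cells, not
whole-cell-only filling — and unioned with the shell on a shared grid
(default pitch 0.2 mm for whole vertebrae).  Drain holes, required by a
physical print to evacuate resin, are deliberately excluded from the
computational model; a cylindrical-cutout utility exists but is off by
default.

## Synthetic data (`synthetic`)

The generators emulate the statistical structure the pipeline assumes,
not the biology:

* **Curves** are piecewise: a quadratic toe (default span 0.3 % strain,
  kept below the 0.4 % bound so the offset construction lands on the
  post-yield branch), a linear branch of slope exactly E, a yield vertex
  placed so the 0.2 %-offset intersection equals σ_y exactly (also under
  optional linear hardening), cubic-Hermite softening with zero end
  slopes, and a constant plateau at σ_p through 45 % strain with an
  optional zero-mean sinusoidal ripple (integer periods across the
  20–40 % window, so the integral mean is unchanged).  Parameters whose
  linear branch would be shorter than the 1 % modulus window are
  rejected as inconsistent.  Noise is additive Gaussian on stress.  The
  preconditioning prefix is generated in stress space so loop bottoms
  land exactly on the 0.16 MPa bound, and is only available in
  force–displacement form (strain is non-monotonic inside the loop).
* **Power-law tables** use multiplicative lognormal noise with unit mean
  and a given CV, keeping responses positive as the log-space fits
  require.  Default sample sizes and spans mirror the study conditions:
  43 (HU, property) pairs over 61–364 HU; 24 pull-out records over
  58–343 HU.
* **Phantoms** are ellipsoidal shells (default semiaxes 22 × 16 × 12 mm,
  a vertebral-body scale) of uniform cortical thickness at high HU, a
  Gaussian trabecular interior with per-hemisphere means, and an air
  background at −1000 HU; voxel spacing defaults to 0.5 × 0.5 × 1 mm,
  typical of clinical protocols.

All generators take a mandatory seed and are byte-reproducible.  What
passing tests show is that the *pipeline's operations* are correct on
data with the assumed structure: real curves have no exactly linear
branch, real scatter is not exactly lognormal, and real vertebrae are
not ellipsoids with uniform cortex, so quantitative agreement on real
scans is a calibration question, not something these tests establish.
Measured quantities from the physical experiments (pull-out forces and
their spread, compressive property ranges, observed R², group-difference
p-values) depend on unpublished raw data and are checked only as
properties: exact parameter recovery at zero noise, R² = 1 at zero noise
and decreasing with noise, and generated forces inside the observed
span.

## Known limitations

* HU calibration transfers poorly across scanners and tube voltages; the
  bundled bone-vs-HU law is specific to the acquisition it came from.
  The lattice-vs-t/L laws are scanner-independent and can be re-pointed
  at any bone-property calibration.
* Voxel-based Booleans bound feature fidelity by the pitch; struts
  thinner than the pitch vanish.
* The hexagonal cell is spatially homogeneous: one t/L per bone, no
  local density adaptation.
* The analytic density model is for t/L < 0.5; beyond that struts merge
  and the cellular-solid description stops making sense.
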