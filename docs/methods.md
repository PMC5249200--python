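# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `cupwear`. It is written for users who need to judge
what the package's results do and do not demonstrate.

## Geometry and coordinates

All lengths are mm, masses mg, volumes mm³, cycle counts Mc (millions of
load cycles), wear rates mg/Mc. Coordinates are right-handed with the cup
pole along +z and the origin at the ideal inner-sphere centre; voxel index
`i` maps to physical space as `origin + i · voxel_size`, where `origin` is
the centre of voxel (0, 0, 0).

The unworn cup is an implicit solid: the hemispherical shell
`R_in ≤ |p| ≤ R_out, z ≥ 0`, represented by an approximate signed-distance
function composed with min/max CSG. Its analytic volume
(2π/3)(R_out³ − R_in³) is exposed for oracle use. Default dimensions are a
32 mm inner and 50 mm outer diameter.

## Wear model

Wear is generated by a single-sphere penetration: the articulating head (by
default the cup's own inner diameter) translates by the penetration depth
along the load direction from the concentric position, and the displaced
sphere is boolean-subtracted from the shell. Material is only ever removed.
This is the simplest generator producing a localized, load-direction-
dependent articular scar with maximum depth equal to the penetration; it
makes no attempt to reproduce any particular retrieved scar shape and does
not separate wear from creep or plastic deformation (neither does the CT
measurement chain being emulated — its maps show the combined effect).
For a head of the cavity's own radius r penetrating axially by d the
removed volume has the closed form (4/3)πr³ − (π/12)(4r + d)(2r − d)²,
which the tests use as an independent third oracle.

`true_wear_volume` provides ground truth by brute force, restricted to a
bounding spherical shell that provably contains all removed material
(radii `[R_in, d + r_head]`):

- **grid** — Cartesian integration at `grid_step` (default 0.02 mm) with
  first-order antialiased occupancy `clip(0.5 − sdf/h, 0, 1)`; relative
  error ~1e−5 at the default step for mm-scale scars.
- **mc** — Monte-Carlo with draws uniform in the bounding shell (closed-form
  volume), default 2×10⁷ samples (standard error a few 0.01 %), seeded.

The two oracles and the closed form agree within 0.1 % in the tests.

## CT image model

`voxelize` renders occupancy (supersampled 3³ on boundary voxels, trivially
0/1 elsewhere), scales to a material gray level of 100 over background 0
(arbitrary, fixed), convolves with an isotropic Gaussian of `blur_sigma`
(default one voxel) as the partial-volume/PSF surrogate, and adds i.i.d.
Gaussian gray noise. What this emulates: the two image properties the
surface-determination step actually confronts — blurred edges and noise.
What it does not emulate: beam hardening, scatter, rings, cone-beam
artifacts, detector physics, or scale errors; source/detector settings
(e.g. 194 kV, 46 μA, 1500 projections, 31 μm voxels) travel as metadata
only. Passing tests therefore demonstrate the correctness of the
measurement chain on ideal-physics images, not robustness to scanner
artifacts.

The 31 μm voxel size of a real metrological scan of a 50 mm cup implies a
~1600³ volume, beyond desk scale; tests and examples run at 0.2–0.3 mm
voxels (the package handles any voxel size; 0.031 remains the configuration
default for real data). Problem sizes used by the test suite and the
acceptance script: 0.2 mm voxels (~259×259×134 grid) for recovery and
registration, 0.3 mm for the end-to-end pipeline, 128² slices and 45–180
angles for the FBP round trip.

## Reconstruction (toy scale)

Parallel-beam, slice-wise radon/iradon (scikit-image) over uniform angles in
[0, 180°), ramp (Ram-Lak) filter by default, Hann optional for noisy data.
A real instrument is cone-beam; reconstruction enters the wear method only
as a black box that yields a gray-value volume, so the parallel geometry
preserves the method's structure while staying testable. The filter and
geometry are implementation choices, not claims about any particular
scanner.

## Surface determination

The ISO-50 threshold is the midpoint of the two dominant modes of the
(Gaussian-smoothed, 256-bin) gray histogram. Peaks are local maxima with
prominence ≥ 2 % of the histogram maximum; the two most prominent must be
separated by a valley below half the smaller peak, otherwise the volume is
declared inseparable (documented failure mode: low-contrast images).

Marching cubes at that iso-level gives sub-voxel vertex placement by linear
interpolation. The adaptive local step then relocates each vertex along its
local gray-gradient direction (central differences at the vertex) to the
50 % crossing between locally estimated background/material levels — the
10th/90th percentiles of the interpolated profile within ±5 voxels (the
window is configurable). This removes the bias a single global threshold
suffers when gray levels drift across the field; with no drift it reduces
to the pure iso-surface (and the `adaptive=False` path is exactly that).
The published adaptive methods used by commercial metrology software are
not specified at algorithm level; this is an explicit reimplementation
choice honouring the same contract.

Mesh volume uses the divergence theorem (signed tetrahedra, via trimesh)
after an orientation fix, with watertightness required. Gray-value-weighted
voxel counting is kept as an independent test oracle only. The MPE utility
implements the metrological CT length-error budget (9 + L/50) μm with a
pass/fail predicate; calibration-artifact workflows themselves are out of
scope.

## Registration and wear quantification

Registration is rigid point-to-plane ICP: sample points from the moving
mesh (8000 by default, seeded), match to closest points on the reference
surface (cKDTree over triangle centroids + exact point-triangle projection;
trimesh's own proximity queries need an optional dependency not assumed
here), solve the linearized 6-DoF update in closed form, iterate to an RMS
change below 1e−9 mm. The point-to-plane metric converges quadratically on
these smooth, feature-poor surfaces where point-to-point ICP crawls.

The articular calotte (default: everything within `inner_radius + 2 mm` of
the cup centre) is excluded from the fit, re-evaluated at each iteration,
because including the worn region would bias the alignment; the fit then
rests on the unchanged back side and rim. Note the cup is axisymmetric, so
rotation about the cup axis is a gauge freedom the registration cannot and
need not determine — only point-to-surface residuals are meaningful, and an
axial scar is invariant under it.

ΔV is the difference of total enclosed volumes of the two closed meshes
(not a boolean mesh subtraction): simpler, exactly invariant to any common
rigid motion, and exactly what "subtraction of volumes" means. Negative
measured wear is reported with a warning, never clipped — it is a
diagnostic of noise or registration failure. Mass conversion is the exact
product Δm = ρ·ΔV; both published polyethylene densities (0.934 and
0.945 mg/mm³) ship as named presets because both appear in the literature
for the same conversion, and the choice is always explicit.

Wear maps: for each vertex of the unworn articular surface, the worn
surface is located along the vertex-normal line by iterating
`t ← t − s(t)` on the signed distance `s` to the worn mesh (locally linear
for near-parallel surfaces), with damping and step clamping near creases
and a dense-sampling fallback for stragglers; vertices with no crossing
within ±3 mm are flagged NaN, never silently zeroed. The sign convention is
fixed: negative = material loss (the worn surface receding into the
material). Consistency check: integrating −deviation × vertex area over the
calotte reproduces ΔV within a few percent on noiseless phantoms (the
residual comes from measuring along normals rather than radial columns and
from flat-triangle areas on a curved surface).

## Gravimetric workflow

The weighing simulator models the specimen mass as
`w(t) = w₀ − rate·t + a(1 − exp(−t/τ))` with a paired unloaded control
gaining the same saturating soak term (defaults a = 1 mg, τ = 0.3 Mc —
uptake saturating within the first weighing interval, a realistic scale for
pre-soaked polyethylene); each reported weight is the mean of three draws
with balance SD 0.01 mg (the microbalance readability). Soak correction is
the additive control-gain form `loss(t) = (w(0) − w(t)) + (c(t) − c(0))`,
standard simulator practice; with a noiseless generator it recovers
`rate·t` exactly at every stop, which the tests assert.

"Steady state" is not universally defined; the regression start is a
parameter, defaulting to 0.4 Mc (i.e. only the zero point is dropped).

Kruskal–Wallis uses the tie-corrected H. For total N ≤ 12 the p-value is
exact, by full enumeration of all assignments of the pooled ranks to the
groups (1680 partitions for 3/3/3, vectorized over the last two groups);
the chi-square approximation is unreliable at n = 3 per group, which is
exactly the design of simulator studies. Larger samples use chi-square, and
the result object always reports which method produced the p-value.

## Agreement analysis

Gravimetric mass loss on x, CT on y; R² is the squared Pearson correlation.
Bland–Altman uses the sample SD (n − 1) and limits bias ± k·SD with
k = 1.96 by default. Shapiro–Wilk is Royston's approximation (scipy),
valid for 3 ≤ n ≤ 5000. Percentage differences are 100·(CT − grav)/grav
per specimen, with the mean signed value and the maximum absolute value
(with its specimen) reported. The difference convention CT − gravimetric is
fixed in the pair type rather than offered as a flag, so a sign flip cannot
silently invert a bias. Report rounding (masses 2 d.p., R² 4 d.p.,
p-values 2 d.p.) matches conventional reporting of such tables. Constant
(regression-based) limits of agreement only; repeated-measures designs are
out of scope.

## Degenerate inputs and numerical tie-breaks

- Constant losses regress to slope 0 with R² defined as 1 (perfect fit of a
  constant), avoiding a 0/0.
- All-identical Kruskal–Wallis samples return H = 0, p = 1 (the tie
  correction would otherwise vanish).
- Exact K-W counts `H ≥ H_obs − 1e−12` so float jitter cannot drop the
  observed partition itself.
- Mesh volume takes |signed volume| after orientation fixing, so inverted
  input orientation cannot produce a negative volume.
- Registration refuses to run when the exclusion leaves fewer than 1000
  sample points, and raises (with diagnostics) rather than returning a
  non-converged transform.
- MHD headers are validated before reading: missing/malformed fields and
  RAW payload size mismatches raise errors naming the offending field.

## Known limitations

- No X-ray physics: results say nothing about beam hardening, scatter or
  cone-beam artifacts on real scans, nor about scale-error correction via
  calibrated artifacts.
- The penetration wear model is a stand-in; real scar morphology (and the
  wear-vs-creep split) is not reconstructed.
- The centroid-KDTree closest-point query tests the k nearest candidate
  triangles (k = 6); on pathologically irregular meshes the true nearest
  triangle could be missed, though this does not occur on the dense,
  near-uniform marching-cubes meshes the package produces.
- Registration of an axisymmetric component leaves the axial rotation
  undetermined (harmless for axial scars, relevant for oblique ones if the
  transform itself is of interest).
- The per-material comparison on the packaged mean ± SD table cannot
  reproduce per-specimen significance tests: individual specimen series are
  not part of the fixture.
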