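# Methods

## Coordinate frames and conventions

All transforms are elements of SE(3) stored as a rotation matrix plus a
translation in millimetres; 4×4 homogeneous matrices exist only in
serialized form. Quaternions are scalar-first (w, x, y, z) and hemisphere
normalized (w ≥ 0; if w = 0, first nonzero component positive) so that
serialization is deterministic. Construction accepts rotations orthonormal
to 1e-6 (file round-trips), never re-orthonormalizes silently, and rejects
reflections.

The camera frame is x-right, y-down, z-forward with the pixel origin at
the top-left pixel centre (mainstream computer-vision convention, so a real
detector adapter drops in unchanged). The ultrasound-image ("probe") frame
has its origin at the orthogonal projection of the transducer centre on the
probe surface, x along the transducer array, y along the beam, z = 0 in the
image plane. The calibrator frame has its origin at the wire cross with the
same axis convention; the exact in-plane orientation of a physical
calibrator is under-determined by a single snapshot, so this definition is
a declared package choice.

## Cluster geometry

The marker cluster is a regular dodecahedron built from the canonical
(±1, ±1, ±1) / golden-ratio vertex construction, vertices enumerated in
lexicographic order for bit-determinism. Each face carries one square
marker of side 25 mm placed in the face plane with its lower side parallel
to the face's *canonical edge* (the edge whose sorted vertex-index pair is
lexicographically smallest) at a perpendicular inset of 2.5 mm, centred on
that edge's midpoint. Corner order follows the ArUco convention: clockwise
from top-left as seen from outside. A geometric fit check rejects
configurations where the square leaves the pentagon (`MarkerDoesNotFit`).

The physical cluster's edge length is not recoverable from the source
description; the default is **31 mm**, the smallest integer edge for which
a 25 mm square with 2.5 mm inset passes the fit check. Face-plane distance
from the centroid equals the dodecahedron inradius
(a/2)·√((25+11√5)/10) ≈ 1.113516·a, which the tests pin.

Marker visibility combines a front-facing test (outward normal obtuse to
the viewing ray of the face centre) with an all-four-corners-inside-image
test. This emulates self-occlusion geometrically; it does not model
lighting, blur, or decoder failure (Bernoulli dropout in the simulator
stands in for those).

## Pose estimation

Correspondences are the 4 corner points of every detected marker. With k
detected markers the set is augmented with the k(k−1)/2 unordered pair
midpoints of the marker centres, computed in the object frame and in the
pixel frame. The pixel-side midpoint is not exactly the projection of the
3D midpoint under perspective (≈0.5 px mismatch at 400 mm with a 900 px
focal length), so augmented points serve the robust consensus stage but
are deliberately excluded from the final refinement: including them caps
noiseless accuracy near half a millimetre, while the corner points are
exact measurements. This split keeps the augmentation's purpose — more
support for RANSAC and for frames with few markers — without biasing the
estimate.

The minimal solver is Grunert's P3P: with camera-frame distances s₁, s₂,
s₃ to three object points, the laws of cosines in the distance ratios
u = s₂/s₁, v = s₃/s₁ reduce (u enters linearly in the difference of two
ratio equations) to a quartic in v solved by companion-matrix roots; each
admissible root yields camera-frame points and a pose via an SVD rigid
fit. RANSAC samples 4 correspondences (3 for P3P, the 4th disambiguates),
scores by pixel reprojection against a 2.0 px threshold, requires 4
inliers, and exits early at 0.99 confidence; 500 iterations maximum; all
overridable and deterministic under the given seed. Levenberg–Marquardt
(scipy `least_squares`, ftol 1e-10, ≤100 iterations) then minimizes the
summed squared reprojection error of the inlier corners over a
rotation-vector + translation parametrization, with full Brown–Conrady
distortion in the residual. The refined pose is discarded if it would
worsen the inlier RMS (it never should; the guard enforces the contract).
When only one marker is visible the four corners are coplanar and two
poses can explain the image nearly equally well; the runner-up RANSAC
candidate is refined too, the better kept, and the estimate flagged
ambiguous when the two costs are within 5 %.

Observed pixels are undistorted to normalized coordinates by fixed-point
iteration (20 rounds), which converges for factory-grade distortion.

## Probe calibration

A valid snapshot shows exactly one proximal echo (the wire cross at 8 mm
depth) plus the distal parallel-wire echoes (18 mm depth, 4 mm spacing).
Snapshots flagged with multiple proximal echoes — the pitched/rolled probe
cases — are refused outright; no in-plane correction is attempted. The
solve is exact composition: T_Probe = T_Cam2Dod⁻¹ · T_Cam2Cal, satisfying
T_Cam2Dod · T_Probe · T_Cam2Cal⁻¹ = I to numerical precision. Pixel size
is isotropic, wire spacing divided by the mean adjacent echo gap along the
echoes' principal axis; echoes straying off that line by more than 10 % of
the mean gap raise `CollinearityViolation`. The ultrasound-origin offset
places the cross at (cross_u − centre_u)·pixel_size laterally and
cross_v·pixel_size in depth, validated against the nominal 8 mm within
1 mm.

## Trajectory processing and evaluation

- **Savitzky–Golay**: translation components only, rotations untouched.
  Window 15 samples, polynomial order 3 by default (a standard choice for
  slow hand-held motion at 60 Hz; both exposed in configuration); edge
  handling by polynomial fit on the truncated window. The filter
  reproduces polynomials up to its order exactly, which the tests pin at
  1e-9.
- **Resampling**: the 200 Hz reference is always resampled onto the 60 Hz
  candidate timestamps, never the reverse. Rotations: SLERP between the
  bracketing quaternions after hemisphere alignment (negate q₁ when
  q₀·q₁ < 0) so interpolation takes the shorter arc; translations:
  component-wise linear. Source timestamps reproduce source poses exactly;
  extrapolation raises `OutOfRange`.
- **Kabsch–Umeyama**: closed-form SVD Procrustes solution with scale fixed
  at 1 (both systems measure metric millimetres); a reflection is
  corrected via the sign of the smallest singular value, so the rotation
  is always proper. Collinear point sets are rejected.
- **Statistics**: ε̄ and σ are per-axis mean and *population* standard
  deviation (divide by N, matching the defining formula σ = √((1/N)Σ(ε −
  ε̄)²)); the norm columns are Euclidean norms of the two 3-vectors. The
  "origin" route evaluates the translation vector alone, discarding the
  rotational component of the final matrix — the reading adopted for the
  published table's "multiplying by the null element in SE(3)" footnote,
  which is mathematically odd as printed.

## Synthetic data

The simulator emulates the study conditions: a 60 Hz RGB camera (720p,
fx = fy = 900 px, zero distortion by default) watching the cluster at a
nominal 400 mm; a 200 Hz IR system observing a rigid 4-marker tetrahedral
cluster (40 mm circumradius — the physical cluster layout is not reported,
so this is a declared default) in a world frame related to the camera by a
fixed transform; and an operator moving "slowly with constant velocity":
a 50 mm lateral sweep with 3 mm waypoint wobble, C²-smooth via cubic
splines (translation) and a rotation spline through small-angle waypoints,
angular velocity capped at 30°/s. Noise is isotropic Gaussian — 0.5 px on
corners and 0.2 mm on IR markers in the stochastic suite — plus Bernoulli
per-marker dropout (0.1). RGB and IR share one clock (the hardware's
clock synchronization is assumed perfect; a constant-offset knob exists
for robustness tests). Everything is a pure function of (config, seed);
serialized output is byte-identical across runs.

What passing tests show, and what they do not: the synthetic suite
validates the geometry, the estimators and the statistics under the stated
noise model. It does not model real detector behaviour (corner bias,
blur, lighting), lens miscalibration, or IR/RGB clock drift, so the
sub-millimetre synthetic errors are a floor, not a prediction, for the
millimetre-scale errors of a physical rig at longer range.

## Problem sizes

The default evaluation runs use 5 s recordings (301 RGB frames, 1001 IR
samples) for the round-trip and stochastic suites — N ≈ 1200 corner points
per report row. The distance-degradation trend is seed-averaged (5 × 1.5 s
runs per distance in the test suite; 8 × 2.5 s in the reproduction script,
where the extra averaging stabilizes the mean-error norm, a noisy
statistic of a near-zero-mean error vector). These sizes give stable
statistics at interactive compute cost.

## Known limitations

- Single-snapshot calibration: no multi-snapshot least squares, no
  temporal calibration, anisotropic pixel scale out of scope.
- The ArUco *detector* is out of scope; observations enter as corner
  coordinates (simulator or external adapter).
- B-mode image formation and voxel compounding are out of scope; only the
  geometric mapping of image pixels/corners into 3D is provided.
- Gap semantics: frames whose pose estimation fails are dropped from the
  stream (and counted), not interpolated; downstream stages operate on the
  surviving timestamps.
- Two rows of the published benchmark table are internally inconsistent as
  printed (see `probetrack.published_results`); they are carried with
  `consistent=False` flags and excluded from equality checks.
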