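# Methods

## Measurement model

Linear wear of a polyethylene acetabular cup is modelled as the
displacement of the femoral-head sphere centre relative to the cup
between an unworn and a worn state. Each scan contributes labelled 3D
point sets (mm) for four (optionally five) surfaces: the cup outer
shell, the femoral head, the two cup opening faces and, for the
tactile-reference variant, the cup inner bearing surface. All
processing assumes rigid geometry within a scan; the two scans may be
arbitrarily rigidly displaced relative to each other.

### Primitive fitting with artifact elimination

Spheres are fitted by geometric (orthogonal-distance) least squares,
minimising Σ(|pᵢ − c| − r)², initialised with the closed-form algebraic
(linearised) estimate and refined with a Levenberg–Marquardt iteration
(`scipy.optimize.least_squares`, xtol = ftol = gtol = 1e-12). Planes
are fitted by total least squares (SVD of the centred points). After
each fit, points whose orthogonal residual is **strictly greater** than
the filter threshold (default 0.5 mm) are eliminated and the fit
repeated, to a fixed point or at most `max_iterations` (default 10)
passes; a residual exactly at the threshold is retained. A single
elimination pass is available via `max_iterations=1`, but the
fixed-point loop is the default because a single pass depends on the
provisional surface, which is not otherwise meaningful. Elimination
bookkeeping always satisfies `n_used + n_rejected = n_input`.
Degenerate inputs (fewer than 4 non-coplanar points for a sphere, fewer
than 3 non-collinear for a plane) raise `FitDegeneracyError`; a loop
that never reaches a fixed point raises `FitConvergenceError`.

### Cup coordinate frame

The frame is anchored entirely on fitted primitives so that it moves
rigidly with the cup:

- origin: cup-sphere centre;
- z: normalised mean of the two opening-face normals, oriented away
  from the dome. The opening side is identified by a reference point —
  the head-cloud centroid in the CT route, the reflection of the
  inner-surface centroid through the cup centre in the CMM route, and
  the mean of the two plane centroids when no reference is supplied;
- x: the unit direction of the intersection line of the two opening
  faces, i.e. `n₁ × n₂` projected orthogonal to z. Taking the cross
  product in label order makes the sign deterministic and rigid-motion
  equivariant; a rule based on the distribution of face points would be
  unstable for the rotationally symmetric annular faces the phantom
  produces;
- y = z × x (right-handed; orthonormality enforced at 1e-9).

If the two faces are parallel within 1°, the intersection line is
undefined and the azimuth falls back to the world +x axis projected
into the opening plane — deterministic but *not* reposition-invariant,
which is the honest behaviour: a rotationally symmetric cup carries no
intrinsic azimuth reference, and in that regime only the wear
*magnitude* and polar angle are identifiable. (Clinically the azimuth
would instead be referenced to the pelvis.)

### Wear vector and angles

Each scan's head-sphere centre is expressed in that scan's cup frame;
the wear vector is the difference of these local coordinates and linear
wear its Euclidean norm. This realises the "register both scans into a
common frame" step without an explicit registration: cup-frame
coordinates are invariant to rigid motions of the raw data, so the
subtraction is too. θ ∈ [0°, 180°] is the polar angle from z,
φ ∈ (−180°, 180°] the azimuth from x about z. A numerically zero wear
vector has no direction; the angles are then flagged
(`angles_defined=False`) and reported as the conventional 0 rather than
propagating NaN. φ at the exact pole is likewise reported as 0.

The CMM-style variant measures wear on the cup *inner* surface: the
hip simulator loads the cup asymmetrically, so the inner surface is
split at the cup-frame x = 0 plane into the ultimately worn (x ≥ 0) and
unworn sides (a `flip` switch serves mirrored cups); a sphere fitted to
the unworn side anchors the frame origin and the wear vector is the
between-scan displacement of the worn-side sphere centre. The split
assumes the wear direction points into the worn hemisphere; wear
directed across the split plane would contaminate the unworn-side fit.
Creep is not subtracted from either route's reported wear — radiographic
penetration is inherently creep plus wear — and is instead estimated
separately from soak-control cups (`estimate_creep`, the mean of their
penetration readings).

Gravimetric conversion divides mass loss by the cup material density,
default 0.935 mg/mm³ (935 kg/m³ for the UHMWPE studied).

## Synthetic phantom

`PhantomSpec` defaults describe the physical validation setup: 54 mm
outer cup (mid-range of the 48–64 mm series), 28 mm head, 0.51 mm
diametral clearance, 45° inclination, 2,000/3,000/400/8,000 points on
cup/head/face/inner surfaces. The unworn head seats half the diametral
clearance toward the dome (configurable, since manufacturing clearance
permits exactly this initial displacement); wear displaces the head and
the worn inner hemisphere by `wear_vector_true`. Gaussian noise
(default σ = 0.15 mm, chosen so plane-fit rms lands in the 0.15–0.20 mm
band observed on real opening faces; the σ = 0.1 mm used in the recovery
studies is set explicitly there) is applied along surface normals, with
a 1.5× multiplier on the mesh-backed outer shell whose roughness is not
otherwise modelled. A fraction (default 2%) of points per surface is
displaced outward by ≥ 1 mm to mimic metal artifacts; their indices are
recorded in the returned truth for recall checks. Each scan is placed
at the anatomical inclination and then, by default, repositioned by a
random rigid motion (≤ 50 mm, ≤ 30°) — deliberately larger than
patient repositioning would be. Optional axial quantisation snaps world
z to a slice grid (e.g. 1.25 mm); off by default.

The two opening faces are annuli 2 mm apart tilted by ∓3° about the cup
x-axis — a chamfer-like wedge. The tilt is deliberate: exactly parallel
faces leave the cup rotationally symmetric, the azimuth unidentifiable,
and the wear *vector* unrecoverable under repositioning; the wedge's
intersection line gives the frames of both scans a common, intrinsic
x reference. Parallel faces (`plane_tilt_deg=0`) remain available to
exercise the fallback path. The generator does not model CT physics
(beam hardening, partial-volume blur, vendor artifact suppression) or
simulator kinematics; passing tests demonstrate the geometry and
statistics pipeline, not segmentation quality on real scans.

All sampling is driven by one `numpy` Generator seeded from
`PhantomSpec.seed`; identical specs reproduce identical clouds
bit-for-bit.

## Statistics

Differences use the convention method-under-test minus reference.
Sample standard deviations use the n−1 denominator throughout. Limits
of agreement are mean ± 1.96 SD; the bias interval is the Student-t CI
of the mean difference. Repeatability from duplicate measurements uses
the within-unit SD s_w = √(Σdᵢ²/2n) and reports 1.96·√2·s_w ≈ 2.77 s_w,
the largest absolute difference expected between two repeated
measurements in 95% of cases; an alternative convention (1.96 × SD of
the signed differences) is available by flag. Accuracy at the 95% level
is taken as |bias| + 1.96 SD — a documented convention combining
systematic and random error; published accuracy figures computed from
unpublished raw data cannot be re-derived from summary tables alone and
are not asserted anywhere. Normality is assessed graphically
(`bland_altman_plot`); no formal test is imposed.

## Numerical choices and problem sizes

- Fit convergence at 1e-12 (parameter update), orthonormality and
  rotation checks at 1e-9; wear below 1e-12 mm is treated as zero for
  angle reporting.
- Display rounding follows reporting convention (mm to 2 dp, degrees to
  integers, ties half-to-even); JSON always retains full precision.
- The recovery studies in the test suite and acceptance script use
  50–100 phantom pairs at the default point counts and
  20 repositioning motions, enough to estimate bias/RMSE to a few
  thousandths of a millimetre; coverage simulations use 2,000
  replicates at n = 12.

## Known limitations

- The in-plane wear direction (φ) is only as good as the opening-face
  geometry; with near-parallel faces it degrades to a convention.
  Pelvis-referenced directions are out of scope.
- The CMM variant's hemisphere split presumes the simulator's
  one-sided wear pattern.
- CSV is the only point-cloud format; DICOM reading, isosurface
  extraction and landmark placement belong to upstream tools.
- Angle estimates are ill-conditioned at small wear magnitudes; tests
  only constrain them for wear ≥ 0.5 mm.
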