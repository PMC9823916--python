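# Methods

## Geometric model and conventions

The IR eye camera defines the world frame: its center is the origin, its
rotation the identity, and all 3D quantities are millimetres in this frame.
The RGB eye camera has relative pose `(R, T)` in the convention of its
perspective matrix `M_rgb = K_rgb [R | T]`: a world point `X` projects to
`K_rgb (R X + T)`.  It follows that the RGB camera center is `−Rᵀ T` and
the world direction of an RGB pixel `p` is `Rᵀ K_rgb⁻¹ p`.  (The two common
textbook conventions differ by transposition of `R`; we anchor everything
on the projection matrix, because the IR→RGB output mapping is computed
with it, and derive every other formula consistently.  A rig calibrated
under the opposite convention must be transposed when written to the
calibration file.)  Pixels are 0-based, top-left origin, x right, y down.
Lenses are modelled as ideal pinholes; no distortion terms.

The eyeball is a sphere of fixed radius `r = 12 mm` — the adult population
average.  The radius is never estimated; only the center `C` is (a
`r` override exists for sensitivity analysis).  The gaze proxy is the
optical axis, the ray from `C` through the pupil center; the kappa offset
to the visual axis is per-person and not modelled.

## Triangulation and filtering

IR/RGB detections are paired per 1 s interval by minimal timestamp
difference (ties: earlier RGB frame).  For each pair, the bounding
rectangle's top-left, center and bottom-right points are triangulated as
independent samples (they all lie near the corneal surface); a switch
restricts to centers.  Triangulation solves the two-ray closest-approach
problem by linear least squares; the estimate is the midpoint of the
closest points, and the residual gap `d` plus the signed ray depths
`(α_ir, α_rgb)` are kept for filtering.  Exactly parallel rays (cross
product below 1e−12) are refused as degenerate.

Two filters remove detection and synchronization failures:

* gap rule — `d ≤ 2 mm`;
* depth rule — each ray depth within `±2 mm` of the *per-camera* median
  depth.  Per-camera (rather than pooled) medians are used because the two
  cameras sit at different distances from the eye, so their depth
  distributions are systematically offset and a pooled median would bias
  one side.  Points with a negative depth are removed before the medians
  are computed — the eye is always in front of both cameras.

## Sphere fit

Initialization exploits that the pupil samples span a small, nearly planar
cap of the sphere: `C₀ = mean(P) + r·N`, with `N` the smallest-singular-
vector normal of the centered cloud, signed toward larger depth (the
center is behind the pupils as seen from the cameras).  The offset by
exactly `r` ignores the cap height `r(1−cos a)` (≈0.4 mm for a 15° cap);
this bias is absorbed by the refinement.  Collinear clouds (second
singular value < 1e−9) are refused, and fits on fewer than 10 points are
refused outright to guard the plane estimate.

Refinement minimizes the truncated-absolute objective
`Σ min(|‖P−C‖−r|, δ)` with a derivative-free Nelder–Mead simplex (the
truncation makes the objective only piecewise smooth, so gradient methods
are unattractive), run twice: δ = 1 mm bounds the influence of gross
outliers while correcting the initialization, then δ = 0.5 mm effectively
ignores them.  Stopping: simplex size below 1e−6 mm, at most 500
iterations per pass; on non-convergence the best iterate is returned with
a warning, and the result is never allowed to be worse than its starting
point.  The fit is exposed as the sklearn-style `EyeballEstimator`
(`fit(X)` → `center_`), which composes with sklearn tooling;
`fit_eyeball()` is the functional wrapper.

## Mapping, validation, self-labeling

Ray–sphere intersection takes the smaller positive root (the near,
camera-facing surface).  A negative smaller root with a positive larger
root would put the camera inside the eyeball and is rejected as a broken
model, as are both-negative roots; the measure-zero tangent case is just
two equal roots.  A negative discriminant (ray missing the slightly-wrong
sphere) falls back to the real part of the conjugate roots, `α = v·C`, and
the result is flagged `approximated_complex` so consumers can weight such
frames.

Rectangles are mapped corner-by-corner (top-left, bottom-right) and
re-normalized to remain axis-aligned.  Online validation scans for
`n_consecutive` successive frames whose mapped/detected rectangles
disagree (IoU < 0.5); frames without a detection neither break nor extend
a run.  `n_consecutive` defaults to 10 frames and the validation cadence
(default every 10th frame) is a parameter — the scan itself is
cadence-agnostic.  Self-labeling emits one candidate label per frame with
a detection, accepted iff IoU ≥ 0.5.

## Evaluation

Rectangle IoU (Jaccard), angular gaze error in degrees (clamped arccos of
the normalized dot product), and pixel error in the RGB plane.  Session
summaries take the median of each metric over *valid* frames (IR detected
and ground truth present) — the median deliberately discards outlier
measurements — while detection/validity/consensus rates are computed over
all frames and stored as exact fractions.  Even-length medians use the
mean of the central pair.  Cohort summaries are medians of
per-participant medians, overall and per session type.

## Synthetic rig

The simulator emulates the device scale: 1280×960 sensors, 20 mm baseline,
RGB camera yawed 30° toward the eye, eyeball center 35 mm from the IR
camera on its optical axis.  The focal length (200 px) is chosen so a
~3 mm pupil at ~23 mm depth subtends ~26 px, inside the plausible 8–30 px
detector rectangle range.  Gaze directions are sampled uniformly in a 25°
half-angle cone about the camera-facing direction (a natural free-viewing
range); the pupil center is that direction's point on the sphere.
Detection rectangles are built from two 3D corner points offset ±1.5 mm
in the tangent plane and re-projected onto the sphere, so at zero pixel
noise the corner correspondences are geometrically exact and the whole
pipeline must recover the ground truth to numerical precision; rectangle
size jitter (±10%) perturbs the 3D half-extent and therefore stays
consistent between cameras.  Detector error is isotropic Gaussian pixel
noise on corners and centers.  Failure injections: *outlier* frames
replace one camera's detection with a uniform random in-image rectangle;
*desynced* frames compute one camera's detection from a different gaze
sample, as during a saccade; a *headset slip* translates the eye center
mid-session.  One master seed drives four independent sub-streams (gaze,
noise, failures, timing), so e.g. changing the noise level does not change
the gaze trajectory.

What the simulator does not emulate: eyelid occlusion, corneal refraction,
specular-reflection detector failures correlated with gaze angle,
non-spherical eyes, rolling-shutter distortion.  Passing tests therefore
demonstrate the geometry, the robustness machinery and the decision rules
— not detector performance on real imagery (detectors are pluggable and
out of scope; a sidecar-oracle fixture detector stands in for them, and is
labelled synthetic).

## Numerical and design notes

* Problem sizes in the test suite and reproduction script — 100
  calibration pairs per session, 20-seed sweeps, 500–1000-case oracle
  comparisons — were chosen to keep each run in seconds while leaving the
  statistics stable across seeds.
* The noisy-sweep contrast fit (`naive_sphere_fit`) is an unrobust
  fixed-radius least-squares fit on the *unfiltered* points from the same
  initialization; with 20% planted outliers its median center error is
  ~24 mm versus ~0.2–0.3 mm for the filtered robust fit.
* A 3 mm *depth* translation of the eye center reliably trips the
  validator (post-shift IoU collapses to ≈0.05).  A purely *lateral* 3 mm
  shift is largely self-correcting: both cameras see the pupil move
  coherently, so the point-to-point mapping tracks it and the IoU only
  sags to ≈0.5.  The validation scenario therefore uses the depth
  component, which is also the component a real slip always has (the
  headset moving along the nose changes the eye–camera distance).
* Even with an exact model the mapped rectangle is not bit-identical to a
  detector's rectangle: mapping is exact for points *on* the sphere, and
  detector rectangles are axis-aligned summaries.  At 1 px noise the
  mapped/detected IoU medians ≈0.79.

## Known limitations

* The complex-root fallback biases `P_w` toward the sphere's silhouette;
  frames flagged `approximated_complex` should be down-weighted in
  downstream statistics (they are counted but not excluded here).
* The fixed 12 mm radius absorbs inter-subject variation (±~0.5 mm) into
  the center estimate; this mirrors the method's own assumption.
* `validate_model` is binary; it does not localize *when* the shift
  happened beyond the window that tripped it.
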