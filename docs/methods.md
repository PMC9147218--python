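# Methods

This note documents the models implemented in `cuporient`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions. Angles are degrees at every public interface
(radians internally); lengths are millimetres.

## Anatomic angle model

The cup rim is treated as a circle of radius `r` with unit normal **n**.
Relative to an orthonormal pelvic frame (lateral **L**, anterior **A**,
superior **S**), the anatomic angles parameterize the normal as

    n = sin(AI) cos(AV) L + sin(AI) sin(AV) A + cos(AI) S

so inclination `AI` is the angle between the rim plane and the transverse
(L, A) plane, and anteversion `AV` is measured in the transverse plane from
the lateral axis to the projection of **n**. A rim plane has two normals
and a single projection cannot sign the version, so the reported pair is
made unique by an octant convention: non-negative superior component first,
then non-negative lateral component, with retroversion folded onto the
non-negative branch and flagged (`retroversion_ambiguous`). When `AI = 0`
the transverse projection of **n** vanishes and anteversion is reported as
0 with a degeneracy flag.

## 3D reference method

* **Plane fit**: total least squares — the normal is the smallest principal
  direction of the centered point cloud. Deterministic, optimal for
  isotropic noise, and exact on coplanar input.
* **Frame construction order** matters and is fixed: anterior = detector
  plane normal; provisional lateral = teardrop-to-teardrop direction;
  superior = anterior × lateral (sign matched to a cranial hint); final
  lateral = anterior × superior. The result is exactly orthonormal
  (pairwise dot products < 1e-9) even when the digitized teardrop line is
  slightly out of the detector plane; the residual tilt is absorbed by the
  lateral axis, which is the re-orthogonalized one.
* **Circle fit**: plane fit, projection into the plane, algebraic (Kåsa)
  circle fit, one Gauss–Newton step on the geometric residuals. Exact on
  exact data; at digitizing-arm noise levels (≈0.1 mm) the radius estimate
  is within its statistical tolerance `3σ/√n`.
* **Handedness**: the frame is right-handed with lateral pointing toward
  the imaged hip; mirrored (opposite-side) input is handled by negating the
  superior hint or swapping the teardrop order.

## 2D fluoroscopic method

* **Projection model**: orthographic (parallel beam). The emulated
  acquisition centers the cup in the beam to eliminate parallax, which is
  exactly the regime where the orthographic inverse is correct; the
  simulator's perspective mode exists to probe the error this assumption
  introduces off-axis.
* **Ellipse fit**: direct ellipse-specific least squares (the
  numerically stabilized two-block formulation), on coordinates centered
  and scaled to unit RMS, with the conic mapped back afterwards. Exact
  data are recovered to ~1e-12 relative error. The constrained fit always
  returns an ellipse when one is supported; degenerate input (e.g.
  collinear points) is detected by the fitted conic escaping the data scale
  and rejected. At `a = b` the major-axis angle is undefined; it is
  reported as 0 with a circular-degeneracy flag.
* **Axis transfer**: the medial–lateral axis orientation in the cup view is
  `teardrop angle + (brim angle in cup view − brim angle in full-pelvis
  view)`, all as undirected line angles in [0°, 180°). Any in-plane
  rotation between acquisitions cancels by construction, which the tests
  verify to 1e-9 degrees.
* **Angle extraction and inversion**: `RA = asin(b/a)`, `RI` = acute angle
  between major axis and transferred medial–lateral axis; then
  `AV = atan(tan RA / sin RI)` and `AI = atan2(sin RI, cos RI · cos AV)`.
  The inversion is exact on the open domain (the identity
  `1 − sin²AI sin²AV = cos²AI + sin²AI cos²AV` removes the common factor);
  limits are handled explicitly: `RA = 0` (edge-on) gives `AI = RI`,
  `RI = 90°` gives `AI = 90°, AV = RA`. A measurement with `RI < 0.1°` but
  `RA > 0` that is not a flagged circle is geometrically inconsistent and
  raises an error rather than returning a wild extrapolation.

## Simulator

The simulator regenerates the validation study structure: 9 target poses
(20/40/60° inclination × 10/25/40° anteversion), 3 occlusion conditions,
2 raters, 1 repeat session for rater 1 (81 digitized image pairs per
study). Design choices, with defaults:

| Parameter | Default | Rationale |
|---|---|---|
| Cup outer diameter | 54 mm | mid-range hemispherical cup size for 32/36 mm heads |
| Placement jitter | uniform ±5° per angle | placements are realized "to within 5 degrees" of target |
| Rim digitization σ | 0.5 mm (×1 / ×1.5 / ×2 per condition) | sub-mm click precision; the femoral head makes the rim harder to identify |
| Landmark σ | 0.5 mm | teardrop/brim click precision |
| Visible rim arc | 1.0 / 0.75 / 0.6 | geometric occlusion by no / 32 mm / 36 mm head |
| Rim clicks per image | 20 | a careful rater tracing the visible rim |
| Inter-teardrop span | 130 mm | adult pelvis scale |
| Brim segment length | ≈83 mm | digitizable tangent segment |
| Cup-view roll / shift | uniform ±10° / ±20 mm | C-arm repositioning between the two views |

Raters digitize the *same* acquired images, so the per-placement scene
(realized pose, visible arc position, inter-view roll) is drawn once and
shared, while each rater/session draws an independent digitization-noise
realization from a dedicated substream of the master seed. All outputs are
bit-reproducible under a fixed seed.

**What the simulator does not emulate**: pixel-level image content and rim
detection (inputs are digitized coordinates by construction), beam-quality
and scatter effects, patient tilt and pelvic rotation relative to the
detector, magnification calibration (orthographic projection sidesteps it),
and systematic rater idiosyncrasies (each click error is independent
isotropic Gaussian). Passing tests therefore demonstrate correctness of the
geometry and statistics under this idealized digitization model, not
clinical-image performance.

## Agreement statistics

* **ICC(2,1)** (two-way random effects, single measures, absolute
  agreement): `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` from the
  two-way ANOVA mean squares. This is the unique standard match to a
  "two-way random, single measures, absolute agreement" specification.
  Zero-variance tables yield an explicit undefined-ICC diagnostic, never a
  silent 1.0 or NaN.
* **Bootstrap CI**: non-parametric percentile interval, B = 2000 by
  default, resampling subjects (cup placements) as the exchangeable unit.
  Replicates with undefined statistics are dropped; more than 50% failures
  aborts with a diagnostic. A percentile CI occasionally fails to contain
  the point estimate; it is reported as computed.
* **Bland–Altman**: bias ± 1.96·sd of differences, sample (n−1) standard
  deviation; a t-quantile variant for small samples sits behind a flag and
  is off by default.
* **Report layout**: 2 angles × 3 conditions per analysis; the interrater
  analysis uses only the first session of the repeating rater; values are
  displayed to 3 decimals.

## Numerical conventions and tolerances

Orthonormality and exact-geometry checks use 1e-9; input-degeneracy checks
(coincident points, parallel lines) use 1e-6; radiographic degeneracy uses
0.1° on RI and 1e-9 relative on `a − b`. Noiseless simulate→measure round
trips are exact to better than 1e-6° over inclination 10–80° and
anteversion 5–60° (verified on a 1° grid). Problem sizes in the test and
acceptance runs — 100 study replicates for the error envelope, 500 outer ×
1000 bootstrap replicates for CI coverage, 1° grids for round trips — keep
every run deterministic and give Monte-Carlo error well below the margins
being tested.

## Known limitations

* **Thin-ellipse regime**: at low anteversion × low inclination (minor axis
  of the projected rim below ≈2 mm) the axis-ratio estimate is biased by
  digitization noise in a way that depends on which arc of the rim is
  visible, and the inversion amplifies anteversion error by `1/sin RI`.
  Under the default occlusion model this makes the large-head anteversion
  error envelope (limit-of-agreement half-width ≈ 8–10°, as computed by
  `scripts/acceptance.py`) substantially wider than the other five
  angle × condition cells; the effect is estimator-independent (a
  Sampson-distance geometric refinement changes the sign, not the size, of
  the bias) and is a property of the measurement physics at this noise
  level.
* Retroversion is indistinguishable from anteversion in a single
  projection; only the non-negative branch is reported.
* The orthographic inverse ignores magnification; rim-radius estimates are
  in detector-plane millimetres and are only comparable to the physical cup
  under the parallax-free assumption.
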