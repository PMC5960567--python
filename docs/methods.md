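# Methods

`noarsa` implements intensity-based nonoverlapping-area (NOA) 2D-3D
registration for model-based radiostereometric analysis (MBRSA): recovering
the six-degree-of-freedom pose of a prosthesis surface model from one
anterior-posterior (AP) and one lateral (LAT) calibrated radiograph, without
implant-attached fiducial markers and without contour detection or feature
matching.

## The model

Each view is an 11-parameter projective camera (direct linear
transformation, DLT): a 3x4 homogeneous matrix `P` mapping world millimetres
to continuous pixel coordinates, solved from >= 6 non-coplanar calibration-cage
bead correspondences by a normalized linear least-squares fit (Hartley point
normalization, smallest-singular-vector solve). Bone markers are located by
linear two-view triangulation; marker-frame poses come from orthogonal
Procrustes (Kabsch) rigid fits.

The pose `p = (rx, ry, rz, tx, ty, tz)` rotates the implant mesh about a
fixed rotation center by extrinsic X->Y->Z Euler angles (degrees) and then
translates it (mm). The rotation center defaults to the mesh centroid, which
keeps rotation-translation coupling in the optimizer small; angles are kept
in degrees so a single difference-spacing schedule covers rotational and
translational DOF alike.

Given a pose, a binary digitally reconstructed radiograph (DRR) is rendered
per view: a pixel is lit iff its center lies inside the projection of at
least one mesh triangle. The silhouette is a union over triangles, so no
depth buffer is needed and back-face culling is disabled. The fill rule is
inclusive (a pixel center exactly on an edge counts as inside), which makes
the union seam-free and deterministic; there is no antialiasing because the
metric is defined on binary pixels. The rasterizer is a vectorized
edge-function scanner compiled with numba whose semantics the test suite
pins to a brute-force per-pixel point-in-triangle oracle.

The registration objective stacks per-pixel differences over both views:

    PD(p, x, y) = DR(x, y) - DRR(p, x, y)
    NOA(p)      = sum_{x,y} PD(p, x, y)^2,   p* = argmin_p NOA_AP,LAT(p)

For binary segmentations NOA counts the discordant pixels, and the relative
form `NOA / (NOA + C)` — with `C` the number of pixels lit in both images —
is a resolution- and magnification-independent quality indicator in [0, 1].
For nonsegmented radiographs the same least-squares objective is used with
real-valued residuals (see Grayscale mode).

## Optimization

A Levenberg-Marquardt loop minimizes the stacked residual. The Jacobian is
a central finite difference of the rendered silhouettes,

    d(PD)/dp ~= -[DRR(p + eps) - DRR(p - eps)] / (2 eps),

one column per DOF (order rx, ry, rz, tx, ty, tz), two renders per view per
column. The negative sign follows from PD = DR - DRR (DR does not depend on
the pose); it is kept as a single named constant in the code because
flipping it turns the Gauss-Newton step into ascent.

Because the binary objective is piecewise constant, the difference spacing
`eps` doubles as a smoothing scale. The registration runs five successive
LM stages with eps = 10, 1, 0.1, 0.01, 0.001 (mm or degrees), each
warm-starting the next: coarse stages provide capture range, fine stages
accuracy.

Numerical choices, with rationale:

* **Damping.** `(J'J + lambda diag(J'J)) delta = -J'r` with lambda_0 =
  1e-3, x10 on a rejected step, /10 on acceptance. The diagonal
  (Marquardt) scaling is essential here: the proximodistal rotation ry has
  a J'J diagonal entry orders of magnitude below the translational ones,
  and isotropic `lambda I` damping freezes that axis (measurably worse ry
  recovery in A/B runs).
* **Monotone acceptance.** A step is taken only if it strictly reduces the
  objective, so a stage never returns a worse pose than it received.
* **Stage termination.** Relative residual reduction < 1e-6, proposed step
  norm < eps/10 (below the resolution of the stage), damping saturation
  (no descending step at any lambda), or 100 Jacobian evaluations.
* **ROI cropping.** The residual is evaluated on a region of interest
  derived once per registration from the radiographic segmentation's
  bounding box plus a margin; re-deriving it per iteration would change the
  objective mid-optimization. The margin must exceed the largest silhouette
  displacement the initial pose error can cause (the experiment harness
  sizes it as 1.3 x magnification x (b + lever*sin(b)) for an offset bound
  of b mm/degrees); the CLI default is 20 px.
* **Views are stacked unweighted**; the AP and LAT residual blocks simply
  concatenate (AP first, row-major within each ROI).

## Drop-outs

Image regions where the implant boundary is unreliable — typically the ball
head occluded by a metallic acetabular component that is not part of the
surface model — are excluded by user-supplied masks. Masked pixels are
removed from the residual vector (and from `C` in the relative NOA), so
they contribute neither value nor gradient. Because the metric is
pixel-wise and local, this needs no special handling beyond shrinking the
vector; enlarging a mask can never increase NOA.

## Grayscale mode

Nonsegmented radiographs are handled under the radiopacity assumption: the
metallic implant is the brightest structure, so after histogram
equalization its pixels sit at the top of the intensity range and the
equalized image acts as a soft segmentation. The DRR stays binary (model
rendered at maximum contrast on a zero background) and the residuals are
real-valued.

One subtlety is resolved deliberately: histogram equalization maps the
background onto [0, m], where m is the background's share of the pixel
mass, so any fixed threshold on a *full-frame* equalized image is
area-dependent. `noarsa` therefore (a) finds the ROI by thresholding the
enhanced radiograph directly (default threshold 0.5 of range), and (b)
equalizes *within the ROI crop* before computing residuals, where the
implant occupies a large, stable fraction of pixels. Relative NOA is not
reported in grayscale mode (the squared-difference sum no longer counts an
area).

An optional gamma correction stands in for detector intensity-curve
adjustment.

## The synthetic phantom

The in silico evaluation needs an implant, a calibrated stereo rig and
ground-truth radiographs; all are generated, deterministically per seed.

* **Stem mesh** — a watertight loft of elliptical cross sections, tapered
  distally, twisted 30 degrees about the proximodistal (y) axis, bowed
  laterally, ~155 mm long, plus a 28 mm ball head centered 40 mm lateral /
  16 mm proximal of the stem top (a typical femoral offset; this off-axis
  head is the dominant lever arm that makes ry observable from AP/LAT
  silhouettes). A smooth low-frequency radius variation (eight control
  values, interpolated) differentiates seeds without introducing
  unphysical surface corrugation. The default tessellation is fine
  (~24k triangles): the method is intended for undecimated high-polygon
  models, and a faceted silhouette boundary measurably degrades the
  discrete optimization. Asymmetry is verified by the test suite: the
  silhouette differs from its 180-degree-rotated counterpart by > 1%
  relative NOA in both views.
* **Stereo rig** — two pinhole cameras 90 degrees apart (principal rays
  meeting at the origin), 1000 mm source-object and 1200 mm
  source-detector distance (magnification 1.2), 300 mm square detector at
  selectable pixel spacing, plus a biplanar calibration cage of 36 beads
  on two planes with exact projections. DLT calibration from the cage
  reproduces each camera to < 1e-8 px reprojection RMS.
* **Radiographs** — binary mode renders the exact silhouette at the
  ground-truth pose; grayscale mode draws foreground ~ N(0.95, sigma) and
  background ~ N(0.20, sigma), clipped to [0, 1], emulating an enhanced
  high-contrast radiograph. The ground-truth pose is drawn uniformly in
  +/-3 mm / +/-3 degrees about the mesh centroid.
* **Drop-out scenario** — a disk grown around the projected ball-head
  center until it covers a requested fraction of the lit area, with a
  matching "acetabular" occluder disk that can be burned into the
  radiographs to corrupt them.

What the generator does **not** emulate: X-ray attenuation physics
(scatter, beam hardening, partial transparency), segmentation errors on
real detectors, calibration-bead detection noise, soft-tissue clutter, or
the true Zweymueller geometry (the evaluation mesh is synthetic, so
absolute accuracy numbers are implant-specific). In the default evaluation
the same renderer produces the ground-truth radiographs and the DRRs — an
inverse-crime setup that isolates the optimizer's accuracy from modelling
error, exactly like an in silico study and unlike any physical experiment.

## Evaluation harness and problem sizes

`run_insilico_experiment` registers the implant from random initial poses
(each DOF offset by an independent Uniform(-b, +b) draw) and reports
per-axis mean +/- SD absolute errors, iteration counts and mean relative
NOA per (pixel spacing, bound) cell; non-converged trials are recorded,
never dropped. The package's evaluation protocol uses pixel spacings 0.5,
0.35 and 0.143 mm, offsets within +/-5 mm / +/-5 degrees, and 20 trials
per cell (detector images are 600-2098 px square; a full three-spacing run
is a few minutes on one core). `scripts/acceptance.py` reruns exactly this
protocol from a seed.

Typical results (seed 1): mean absolute y-rotation error ~0.007 deg at
0.5 mm, ~0.009 deg at 0.35 mm and ~0.0009 deg at 0.143 mm spacing, with
translational means of a few microns or less and residual relative NOA
below ~0.01% everywhere — accuracy improves monotonically with detector
resolution, and the proximodistal rotation is consistently the hardest
DOF, both as expected.

## Known limitations

* The binary objective is integer-valued; at coarse pixel spacings the
  optimizer can terminate in a discrete local minimum a few hundredths of
  a degree from the optimum (single-DOF probes show no descending
  direction there). Finer pixel spacing, not more iterations, is the
  effective remedy.
* ry (proximodistal rotation) is an order of magnitude less observable
  than the other DOF from an AP/LAT pair; a third projection would fix
  this but is clinically unavailable.
* Meshes must be fully in front of both sources; clipping is unsupported.
* Absolute accuracy depends on implant shape and silhouette asymmetry;
  numbers from the synthetic stem do not transfer to other implants.
* Real radiographs require a segmentation threshold / drop-out selection
  from the user; neither is automated.
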