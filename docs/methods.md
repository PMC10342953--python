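# Methods

## Measurement plane

Root motion is measured in a plane perpendicular to the aortic centerline at
the level of the coronary ostia. Both ostium landmarks are projected onto
the centerline (resampled to equal arc length, default 0.5 mm); the plane
origin is the centerline point at the mean of the two arc-length parameters
and the normal **n** is the central-finite-difference tangent there,
oriented from root toward arch by the centerline's sample order. The
in-plane basis is made deterministic — u = normalize(n × k) with k the
global axis least parallel to n, v = n × u — so results are bit-for-bit
reproducible; the physics is basis-independent, the choice only fixes
internal coordinates.

## Slicing and planar quantities

Mesh–plane intersection collects one segment per crossing triangle, keyed by
the mesh edge each endpoint lies on; because two triangles sharing an edge
generate the identical key, stitching into closed loops is exact and needs
no distance threshold. A vertex exactly on the plane is treated as
infinitesimally on the positive side so every crossing lies strictly on an
edge. If the plane cuts several structures (it can also cross the
descending aorta), the loop whose centroid is nearest the plane origin is
kept — the origin lies inside the root lumen by construction. Contours are
oriented counterclockwise viewed down n. Area is the shoelace formula in
(u, v); the centroid is the area-weighted polygon centroid. Both are
rigid-motion invariant to ≤1e-9 relative and converge to the closed forms
for cylinders and spheres at second order in edge length (the slice polygon
is inscribed, so areas under-estimate by O(h²)).

Each contour point records its mesh edge and interpolation weight, so any
per-vertex field interpolates linearly onto the contour.

## Displacement metrics

The "mean displacement over the analysis plane" is realized as: interpolate
the vertex field onto the lumen contour, resample the contour at equal arc
length (default 256 samples, configurable), and average the sampled
vectors. Equal-arc resampling removes mesh-density bias; averaging over the
contour (rather than the enclosed area or a vertex band) measures the
motion of the wall, which is what a registration field is defined on.

The mean vector is split along the diastolic normal: axial = |d̄·n|,
in-plane = |d̄ − (d̄·n)n|. Axial displacement and aortic rotation are
reported as magnitudes, matching how cohort tables report them; signed
values (sign of d̄·n against the root→arch normal; right-handed rotation
about n) are kept on the result object for directional studies. Relative
components are the total-normalized axial and in-plane parts; they satisfy
rel_axial² + rel_inplane² = 1 whenever the total is nonzero. A zero mean
displacement leaves the relatives undefined and they are reported as NaN
(missing), never as 0.

The systolic configuration is the diastolic contour warped by the
interpolated displacements. Warped points are only approximately planar, so
a plane is fitted (mean-point origin, Newell normal, orientation matched to
the diastolic normal) and used for all systolic quantities; the contour
planarity tolerance for warped points is 0.5 mm (configurable) versus
1e-6 mm for exact slices.

- Axial tilt: angle between diastolic and systolic normals, computed by
  atan2(|n₁×n₂|, n₁·n₂) after flipping n₂ to the same hemisphere — the
  acute deviation, consistent with the ~3° values seen clinically.
- Aortic rotation: each phase's centroid-to-reference vector is projected
  onto the diastolic plane and the angle between the projections taken.
  The reference is the left coronary ostium; its systolic position is the
  diastolic one moved by the field interpolated at the 3 nearest mesh
  vertices (inverse-distance). Each vector uses its own phase's centroid,
  which makes the metric exactly translation-invariant.
- Distensibility: D = (A_sys/A_dia − 1)/PP, reported ×10³ in 10⁻³ mmHg⁻¹.
  D is linear in A_sys at fixed A_dia and PP, zero iff the areas agree, and
  halves when PP doubles.
- LV/Ao angle: planes are fitted to the aortic and mitral annulus point
  sets; the aortic normal is oriented toward the aorta and the mitral
  normal toward the LV apex; φ is the angle between the oriented normals.
  This convention puts a coaxial outflow tract at φ = 180° and clinical
  hearts near 120–140°.

All angles use atan2 of cross/dot (never bare arccos), so collinear inputs
are exact rather than NaN-prone.

## Phantom

The phantom tube runs along +z (default length 60 mm, radius 15 mm) with
radius profile r(z, θ) = R + b(z)·(1 + cos 3θ)/2, where b(z) is a Gaussian
bulge (amplitude default 4 mm, width 12% of tube length) centered at 30% of
the length — an idealized three-lobed sinus of Valsalva. Coronary ostia sit
on the surface at the sinus level, 120° apart, snapped to mesh vertices;
the centerline is the z-axis. Optional Gaussian vertex jitter (seeded, one
integer seed, no global random state) emulates segmentation noise.

The prescribed deformation composes, about the plane origin: in-plane
dilation s → twist about n → tilt about an in-plane axis → rigid
translation. The displacement is weighted by w = 1 at and below the plane
and exp(−Δz/decay) above it, so plane-level ground truth stays analytic
while motion still dies away toward the arch, as root motion transmitted
from the ventricle does. At the plane: the mean displacement equals the
rigid translation (dilation, twist and tilt average to zero over the
symmetric contour), the fitted systolic normal is the tilted normal
(tilt = prescribed tilt), the projected rotation equals the twist up to a
second-order cos(tilt) projection term (≤0.16° at the 6° tilt ceiling), and
the area ratio is exactly s². The composition order is fixed and documented;
at the motion magnitudes of interest order effects are below tolerance.

Default magnitudes (axial 5 mm, in-plane 3 mm, twist 2°, tilt 3°, dilation
1.06, PP 56 mmHg) sit at the center of the clinically reported ranges for
total/axial/in-plane root displacement (~3–7 mm), tilt (~3°), rotation
(~2°) and distensibility (~2×10⁻³ mmHg⁻¹).

What the phantom does not emulate: real lumen eccentricity and
patient-specific sinus asymmetry, registration error structure (noise here
is i.i.d. vertex jitter, not spatially correlated field error), branch
vessels, and through-plane curvature of the root axis. Passing recovery
tests therefore demonstrates correctness of the geometry and metric
pipeline, not robustness to registration failure modes.

## Cohort statistics

Kruskal–Wallis uses mid-ranks, H = 12/(N(N+1))·ΣR_g²/n_g − 3(N+1), divided
by the tie correction 1 − Σ(t³−t)/(N³−N), with p from the chi-square upper
tail on k−1 degrees of freedom. When every pooled value is identical the
statistic is 0 and p = 1. The chi-square tail is asymptotic; on an N = 8
instance the test suite compares it against the exact permutation
distribution and documents agreement within 0.05 — small-group p-values
should be read with that approximation in mind. Pairwise group comparisons
are unadjusted two-group tests by default (the per-pair convention of
box-plot annotations); Holm adjustment is available behind a flag. Group
tables report mean, sample SD (n−1), min and max. Regression is ordinary
least squares with a t-test on the slope (n−2 df) and a pointwise 95%
confidence band for the mean response, minimized at the mean abscissa.

## Registration QC

The Dice coefficient 2|A∩B|/(|A|+|B|) between the fixed diastolic and
warped systolic masks (identical grids required, geometry checked to
1e-6) is the scalar stand-in for visual dual-channel overlay inspection,
with a per-axial-slice profile to localize misalignment. Two empty masks
score 1 with a warning — vacuous agreement must not fail a pipeline on an
empty ROI. No universal pass/fail threshold is imposed; the default
warning level is 0.95.

## Numerical and scale choices

- Slicing/stitching uses exact edge keys; near-duplicate contour points
  (plane through a vertex) are merged at 1e-9 mm.
- Degenerate triangles are rejected above 1e-12 mm²; meshes need ≥4
  vertices; centerlines ≥2 distinct samples.
- Contour resampling default 256 samples; phantom default resolution
  128 (circumferential) × 64 (axial) — recovery errors are then ~1e-8
  relative for displacements and ~3e-3° for rotation, far inside the 2% /
  0.3° validation tolerances, at well under a second per subject.
- The randomized validation sweep draws 50 deformations across axial
  0–8 mm, in-plane 0–6 mm, twist 0–5°, tilt 0–6°, dilation 1.00–1.15; the
  decomposition-identity property runs 1,000 field/mesh trials at reduced
  resolution (16×16) to keep the suite fast.
- CSV/JSON writers are deterministic (repr/`%.17g` floats, sorted JSON
  keys); identical inputs and seed give byte-identical outputs.

## Known limitations

- Mesh I/O is STL/PLY; masks are NIfTI. Other formats must be converted
  upstream.
- The pipeline assumes one closed lumen contour at the analysis plane;
  open surfaces whose boundary crosses the plane will fail loudly rather
  than guess.
- Metrics from two phases only (diastole, systole); no cyclic analysis
  over more cardiac phases, and no wall strain/stress tensors.
- The systolic plane is fitted to warped contour points; with severely
  non-planar warps (>0.5 mm departure) the contour is rejected rather than
  silently projected.
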