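# Methods

## The phantom and its synthetic stand-in

The NiCl2 (T1) array of the ISMRM/NIST system phantom holds 14 spheres of
inner radius 7.5 mm whose reference T1 values — NMR-traceable, stated
uncertainty below 1.5% — run from 1955 ms down to 22 ms at 1.5 T and from
2033 ms down to 23 ms at 3 T.  `phantomt1.phantom` renders a single coronal
slice through the sphere centers, which is the geometry an analysis of this
array actually consumes.  The exact in-plane sphere coordinates of the
physical array are not published, so the generator uses a configurable
default: the ten longest-T1 spheres evenly spaced on a 45 mm circle and the
four shortest on a central square grid with 20 mm spacing.  All geometric
tests treat the generated layout as its own ground truth, so the analysis
chain is insensitive to this choice (it only has to be registered, not
guessed).

Details of the rendered scene:

* **Compartments.** Sphere interiors carry their reference T1 with unit
  proton density; a 1 mm signal-void shell around each sphere stands in for
  the polymer wall (this is what a gradient filter keys on); the water
  background is a 90 mm disc with T1 = 3000 ms, so the shortest-TI image has
  strong sphere/background contrast.
* **Partial volume.** Compartment maps are built on a 4x supersampled grid
  and block-averaged, so boundary pixels mix compartments as a real voxel
  grid does.  Hard-pixelated shells would otherwise have asymmetric lattice
  centroids that bias center refinement by over a pixel; interiors more than
  one pixel from the wall are exact model values either way.
* **Noise.** The analyzed images are magnitude images, so noise is added as
  independent Gaussians on two quadrature channels followed by the modulus
  (Rician); in a zero-signal region the mean magnitude is sigma sqrt(pi/2),
  which the tests verify by Monte Carlo.  Signal averaging (NEX) divides the
  channel sigma by sqrt(NEX); the default VFA protocol uses NEX = 4 and IR
  uses NEX = 1, as in the acquisition protocols the study prescribed.
* **B1 miscalibration.** `b1_scale` (scalar or smooth 2D map) multiplies
  every nominal flip angle before signal evaluation — th180 and th90 for IR,
  alpha for VFA.  Per-series gain changes are modeled by `series_scale`
  applied to the final magnitudes.
* **Protocol defaults.** IR: TR 4500 ms, TI = {35, 75, 100, 125, 150, 250,
  1000, 1500, 2000, 3000} ms, ideal 180/90 degree pulses (configurable).
  VFA: TR 6.6 ms, flip angles {2, 5, 10, 20, 25, 30} degrees.  250 mm FOV on
  a 256 matrix (0.977 mm pixels; the protocols print 0.98 mm).
* **Determinism.** All randomness flows from `rng_seed` through
  `numpy.random.default_rng`; identical (layout, protocol, seed) triples
  give bit-identical stacks.

What the generator does **not** emulate: slice profiles and echo-train
blurring, gradient nonlinearity, coil sensitivity, 3D partial volume across
the slice, susceptibility or motion artifacts, and any vendor-specific
reconstruction. Passing tests therefore demonstrate correctness of the
analysis chain under an idealized but noise- and bias-faithful imaging
model, not robustness to every real-world artifact.

## Segmentation

Mirrors the standard recipe for this array:

1. **Edges.** Sobel gradient magnitude, thresholded to keep the top 2% of
   pixels (the operator and threshold rule are a design choice; the
   procedure is insensitive to both because registration only needs the
   boundary rings).
2. **Rigid registration.** The transform (in-plane rotation about the image
   center, then translation) is scored by the fraction of edge pixels within
   1 pixel of any transformed sphere-boundary circle (inner and outer wall
   radii).  A coarse grid (translation +/-20 mm at 1 mm, rotation +/-15
   degrees at 1 degree) is followed by Nelder-Mead refinement of a smoothed
   score (Gaussian kernel on the boundary distance, looked up in a
   precomputed 0.25 mm distance field).  Coverage below 0.3 raises a
   registration-failure error; pure-noise edge maps reliably trip it.
   Recovery accuracy on simulated offsets is well under 0.5 mm / 0.5 deg.
3. **Center refinement.** Each sphere independently: iterate the centroid of
   (window max - intensity) over a circular window of 1.5 x inner radius
   until the update falls below 0.01 pixel (max 50 iterations).  Spheres are
   dark against the background at the shortest TI, and the signal-void wall
   is dark at every TI, so the weight concentrates on the sphere.  A sphere
   drifting more than half the inner radius from its rigid initialization is
   flagged and left at the initialization.  The fixed point of this
   iteration is the sphere center even though the uniform background
   contributes weight (its pull cancels by symmetry of the window).
4. **ROIs.** All pixels whose centers lie within 4 mm of the refined center
   — pixel-center membership, not area overlap, which reproduces the
   ~52-pixel ROI at 0.98 mm pixels (lattice counts range 45-59 over subpixel
   placements; exactly 49 when the center sits on a pixel center).  The same
   masks segmented on the shortest-TI IR image are reused unchanged for the
   VFA series of the same session, matching the acquisition constraint that
   the phantom is not repositioned between the two scans.

## T1 estimation

The IR magnitude model |A + B e^(-TI/T1)| loses differentiability where the
recovery crosses zero, so the estimator minimizes the smoothed objective
sum_k (y_k^2 - (A + B e^(-TI_k/T1))^2)^2.  For exact data the smoothed and
modulus objectives share minimizers; with noise the smoothed stationary
point is reported as the estimate (refitting the modulus model from that
point is deliberately not done).  (A, B) and (-A, -B) are equivalent under
the squared model; the physical branch with B <= 0 is reported.

Numerical scheme, both fitters:

* **Grid initialization.** T1 on 200 log-spaced points in [5, 5000] ms.
  IR: A and B each on 50 linear points spanning [-2 max|y|, +2 max|y|].
  VFA: M0 on 100 linear points in [0, 3 max z / sin(alpha_min)].  Ties
  resolve deterministically to the smallest T1.  All grids are arguments.
* **Newton refinement.** Gauss-Newton steps with Levenberg diagonal damping
  engaged only when a step fails to decrease the objective or drives T1
  nonpositive; iteration stops when the relative objective decrease falls
  below 1e-9 (i.e., changes in the residuals are orders of magnitude smaller
  than the residuals) or after 50 iterations.  The refined objective can
  never exceed the grid optimum — an invariant enforced by the result type
  and cross-checked in tests against an independent brute-force grid
  evaluator.

Noise-free recovery over the full reference T1 range (22-2033 ms, both
protocols' sampling grids) is exact to well below 0.1%.  The VFA fitter
inherits the known B1 sensitivity: with delivered angles k x nominal and a
fit at nominal, the fitted T1 is approximately k^2 T1 (verified within 3%
for k in [0.9, 1.1]); e.g. k = 0.9 turns 2000 ms into ~1616 ms.  The IR
fitter is immune to the same miscalibration because A and B absorb the
imperfect inversion and excitation.

## Statistics

* **Normalized error.** dT1 = 100 (T1 - T1_NMR)/T1_NMR, computed per sphere
  per scanner session; it is the unit of all group analyses, putting 22 ms
  and 2033 ms spheres on one scale.
* **Group summaries.** Per sphere per vendor: mean with Student-t 95% CI
  (singletons flagged, CI undefined).
* **Two-way ANOVA.** Fixed effects of vendor, field and their interaction on
  dT1, sum-to-zero contrasts with Type III sums of squares (Type II
  switchable) so unbalanced designs are handled; implemented on statsmodels
  OLS.  Simulated balanced nulls put the interaction type-I error at the
  nominal 5%.
* **Simple main effects.** With a vendor x field interaction present, fields
  are analyzed separately: per sphere, one-way ANOVA across vendors plus all
  pairwise comparisons with the Tukey-Kramer HSD adjustment (statsmodels
  `pairwise_tukeyhsd`, unequal n allowed), alpha = 0.05.
* **Bias propagation.** For a tissue with T1 = mean +/- sd and a vendor
  characterized by bias b% and dispersion d%, the expected measured range is
  [(1+(b-d)/100)(mean-sd), (1+(b+d)/100)(mean+sd)] — the bias and dispersion
  applied multiplicatively to the tissue range, the widest interval
  consistent with those two figures.  This is an interpretation of a
  range-construction rule that is not spelled out in closed form anywhere;
  it is monotone in dispersion and reduces to the tissue range at zero
  bias/dispersion.  With IR-like biases (a few percent, 7% dispersion) the
  low-grade-glioma (1355 +/- 187 ms) and glioblastoma (1863 +/- 70 ms)
  ranges stay separable; a VFA vendor at -15% +/- 10% makes them overlap.

## The synthetic multi-vendor study

`run_pipeline` simulates three vendors ("C", "D", "E") at 3 T, six scanners
per vendor (the scale of the real 3 T arm, which pooled five to seven
systems per vendor), with per-scanner flip-angle calibration drawn as
vendor value +/- 1% (s.d.) and channel noise sigma = 0.01 on a unit-signal
phantom.  Vendor D's calibration is 0.9 — a 10% under-rotation.  Each
scanner session is segmented on its shortest-TI IR image; IR and VFA are
fitted from the same ROIs; records feed the per-sphere vendor statistics.
The reproduced signature: vendor D's VFA T1 biased about -19% with the
D-involving pairwise comparisons significant across the long-T1 spheres,
IR essentially unbiased for all vendors, and the C-E comparisons null.
The b1 jitter of 1% s.d. is the study-variability knob: it produces ~2%
within-vendor T1 dispersion in VFA, comparable to the within-group spread
the real study shows for its better-behaved vendors.

## I/O conventions

Canonical storage is one 3D NIfTI volume (two spatial axes x series axis)
plus a JSON sidecar (modality, TR, series values, pixel size, vendor, field,
scale slopes, seed).  DICOM directories are an import path; images are
ordered by the inversion-time or flip-angle element, never by file name, and
Rescale slope/intercept are applied on read.  Vendor per-series scale
factors (the Philips convention) are removed by dividing stored values by
the slope; a flagged vendor without slopes is an error rather than a silent
pass-through.  Pixel coordinates: 0-based indices, pixel centers on integer
grid points, position = (index - (N-1)/2) x pixel size relative to the image
center.

## Problem sizes and tolerances in the test suite

The suite renders 256x256 single-slice series; the end-to-end study uses 18
scanner sessions (3 vendors x 6 systems x 2 modalities).  Monte-Carlo test
sizes (e.g. 120 seeds for noisy IR recovery, 1000 simulated ANOVA nulls,
50-200 Tukey simulations) were chosen so that sampling error is several
times smaller than the tested effect; tolerances on recovered parameters
come from the stated convergence constants (1e-9 relative objective change)
plus the discretization of the rendering, not from fitted slack.

## Known limitations

* 2D single-slice only; no slice profile or 3D partial volume.
* Magnitude-only fitting (no real/imaginary reconstruction path).
* No B1-map correction of VFA (deliberately: quantifying the uncorrected
  bias is the point), no Rician-likelihood fitting, no multi-component T1.
* The registration template assumes the generated layout geometry; real
  acquisitions of the physical array would need its true coordinates (or
  any surveyed layout) supplied as `geometry_overrides`.
* The bias-propagation range rule is an interpretation (see above).
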