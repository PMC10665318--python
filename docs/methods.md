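# Methods

This note documents the models and numerical choices behind the package:
what each stage assumes, which parameters matter, what the phantom
generator does and does not emulate, and where the design was genuinely
open.

## Imaging model and segmentation

Brightfield images are modelled as dark particles on a light field. The
threshold follows the midpoint rule used in static-imaging particle
analysis (consistent with ISO 13322-1 edge determination):
`T = (B + D) / 2`, with B the background intensity and D the dark
intensity at the particle borders. In auto mode B is the histogram mode
(256 bins over the intensity range) and D is the 1st percentile of
intensities inside a 2-pixel band around strong gradient ridges (ridges =
squared Sobel magnitude at or above its 90th percentile; both percentiles
configurable). A flat image raises "no contrast" rather than returning a
degenerate threshold.

Foreground is `pixels < T`, labelled 8-connected (background implicitly
4-connected, which prevents checkerboard artefacts), holes filled before
any measurement because instrument size descriptors are silhouette-based.
Contours are extracted *sub-pixel* at the threshold level set (marching
squares); pixel-boundary chains would systematically overestimate
perimeters and bias circularity and convexity downward. For a noise-free
anti-aliased disk the level-set contour recovers the continuous radius to
better than 0.5 px (asserted in the tests). Border-touching regions are
flagged and excluded by default since truncated silhouettes corrupt Feret
and perimeter measures. Regions below a minimum ECD (raster-area based)
are discarded.

Detection quality against ground truth uses greedy maximum-IoU matching.
A truth particle substantially overlapped (≥ 10 % of the smaller area) by
two or more detections counts as fragmented; a detection is
"high-resolution" when its IoU reaches a configurable bar (default 0.85)
and its truth is not fragmented. The original quality call on real
instruments is a manual inspection, so the bar is a convention: only the
*direction* of quality trends (degradation lowers the high-resolution
fraction) is treated as meaningful.

## Shape descriptors

All descriptors are computed on the sub-pixel contour polygon (or, for
ground truth, on the continuous generating polygon) scaled by the pixel
size:

- area by the shoelace formula, perimeter as polygon arc length;
- Feret diameters on the convex hull (the hull has the same support
  function as the original set): the maximum is the hull diameter, and
  the minimum width of a convex polygon is attained perpendicular to one
  of its edges, so the minimum is taken over hull-edge normals — exact
  for polygons, and cross-checked in the tests against a brute-force
  0.1°-step directional sweep;
- aspect ratio = Fmin/Fmax, elongation = 1 − aspect ratio (an exact
  identity, asserted to machine precision on every record);
- circularity uses the perimeter-ratio definition `2√(πA)/P`. Some flow
  imaging instruments report the squared form `4πA/P²`; both are emitted
  (`circularity`, `circularity_hs`) with the perimeter-ratio form
  canonical;
- convexity = hull perimeter / perimeter;
- mean intensity is averaged over the filled mask on the *original*
  (pre-threshold) image and serves as a transparency proxy.

Dimensionless descriptors are bounded by 1 up to a discretisation
allowance ε = 0.02. Summary tables round to two decimals; stored records
keep full precision.

## Phantom generator

The generator's role is statistical, not photorealistic: it produces
populations whose descriptor statistics and spectra behave like the four
laboratory particle classes, with exact per-particle ground truth.

- **Spheres** (polystyrene-standard-like): regular 256-gons rescaled so
  polygon area gives exactly the target ECD; opaque (gray 60 on a
  background of 200, 8-bit). Spheres below two pixels across are rejected
  as unresolvable.
- **Lithographic** particles (photoresist-like): a deterministic
  elliptical 256-gon with semi-axes chosen so Fmin/Fmax equals the target
  aspect ratio exactly and the ECD is exact; identical across calls at a
  fixed spec (monodisperse). This template reproduces the target aspect
  ratio/elongation and ECD but not the very low circularity (~0.25) of
  real jagged lithographic outlines, whose tortuous perimeter the smooth
  template does not imitate; no acceptance quantity depends on that
  value.
- **Flakes** (ETFE-like): star-convex polygons `r(θ) = R(1 + ρ·g(θ))`
  with g a band-limited random Fourier series (harmonics 2–8, 1/m
  weighted, normalised to max 0.95 so radii stay positive), roughness
  ρ = 0.35 by default; translucent (gray 150). Roughness → 0 recovers a
  disk (circularity → 1). Population sizes are lognormal; the lognormal
  form is an assumption (no published size law exists for these abraded
  polymer particles), with geometric SD 1.6 by default.
- **Aggregates** (proteinaceous-like): blobs grown by seeded random disk
  accretion (18 disks, radii U(0.5, 1)·r₀, each attached to a random
  parent). With probability equal to the elongation bias the growth
  direction concentrates along a fixed random axis (±N(0, 0.3)), so bias
  0 → compact habits, bias 1 → chain-like habits; mean ground-truth
  elongation rises with bias (a statistical, not per-particle,
  guarantee).

Scenes place elements by rejection sampling on bounding circles (no
overlap by default; failures raise an error listing unplaced ids), render
each polygon with 4×4 supersampled area coverage — anti-aliased edges, so
mid-level thresholding recovers the continuous geometry — then apply
optional Gaussian blur (optics) and additive Gaussian noise (sensor),
clipped to the bit range. The default pixel size is 1.25 µm. No shot
noise, diffraction, depth-of-field or flow transport is modelled; gray
levels (background 200, opaque 60, translucent 150) are configurable
conventions that preserve the opaque < translucent mean-intensity
ordering observed on real materials.

Rasterise-then-measure recovers continuous ECD within 5 % and aspect
ratio within 0.05 for particles at least 10 px across at zero noise
(asserted over 200 seeded flakes in the acceptance suite).

## Spectral model and scoring

Synthetic spectra are sums of Lorentzian bands on a 1 cm⁻¹ grid over
200–1800 cm⁻¹, plus a smooth random quadratic baseline (amplitude 0.05 of
the strongest band by default) and white Gaussian noise. Band tables:
polystyrene (8 sharp bands, 8 cm⁻¹ FWHM, dominant ring-breathing at
1000 cm⁻¹), ETFE (sharp CF₂ 835 and CH₂ 1444 cm⁻¹), protein aggregate
(broad bands, per-band widths 10–35 cm⁻¹: disulfide ~525, tryptophan 770,
phenylalanine 1003, amide III 1230, CH deformation 1340, asymmetric CH₂
1400, CH₂/CH₃ deformation 1448, and amide I 1670–1690 cm⁻¹ as the
dominant feature). The protein band list includes the CH₂/CH₃ deformation
band alongside the canonical markers because real protein spectra carry
it and it produces the observed weak-but-nonzero cross-correlation with
the ETFE reference.

Signal amplitude scales with particle geometry through
`f = min(ECD, 3)/3 × min(thickness, 3)/3` (µm): linear in each factor and
capped at 1 once both reach the 3 µm laser spot. The linear-capped form
is our formalisation of the qualitative spot-size argument; only its
monotonicity is relied upon. Spheres have thickness = diameter; flakes
and aggregates use thickness = ECD/8, a thin-flat convention chosen once
(real flakes are known to be thin relative to their in-plane extent, but
no thickness law is published). This coupling is what makes mean scores
fall across the ≥25 / 10–25 / 5–10 µm flake size tiers.

Scoring: spectra are cropped to the window (at least 16 points),
baseline-subtracted (default: a line through the 5th-percentile anchors
of the two 10 %-end segments; a rolling-minimum alternative exists) and
min–max normalised. The sample is linearly resampled onto the reference
grid, and the score is the Pearson correlation clipped to [0, 1]. The
commercial score formula is undisclosed; clipped Pearson reproduces the
[0, 1] range, the self-score of exactly 1, invariance to positive affine
intensity transforms, and the qualitative orderings — absolute
cross-material score values are therefore comparable only as orderings,
and the scoring function is isolated behind a single interface so an
alternative (e.g. squared correlation) can be swapped in. Identification
scores a spectrum against every library entry on that entry's window;
ties break by library order. Per-entry failures (e.g. zero variance in
the window) propagate as missing scores rather than aborting the batch.

The protein-aggregate reference is selected from candidate spectra as the
one maximising the summed baseline-corrected intensity integrated over
four marker windows (1000 ± 8, 1230 ± 8, 1400 ± 8, 1670–1690 cm⁻¹;
half-width configurable), ties to the first candidate.

S/N estimation: mean band height (max within ±10 cm⁻¹ of each band,
after linear baseline correction) divided by a robust noise SD taken as
1.4826·MAD of the *second difference* of the longest band-free stretch
(bands excluded ±25 cm⁻¹), scaled by √6. The second difference isolates
high-frequency noise so smooth Lorentzian tails and baseline residue do
not inflate the noise estimate; a noise-free spectrum returns a capped
sentinel (10⁶).

## Size distributions and limits

Bins are half-open `[lo, hi)` with the ≥ 25 µm class meaning `[25, ∞)`;
whether a boundary particle at exactly 25.0 µm belongs to the upper class
is a convention (we assign it upward, matching the "≥" phrasing of the
compendial classes). Percentages are reported against the in-bin total,
always summing to 100; out-of-bin particles are counted and reported
separately, and an empty record set yields a flagged undefined
distribution rather than NaNs. USP <788> checks are "at or below":
(6000, 600) passes, (6001, 601) fails. Welch's unequal-variance t-test is
provided for descriptor comparisons as reporting plumbing only; no
multiple-testing correction is applied.

## Pipeline

A run is one `RunConfig`: either synthesis parameters or input paths
(images / spectra directory / library manifest), exactly one per data
stream. Stages log counts in/out; all randomness derives from the config
seed (per-particle spectrum seeds are derived as
`seed·100003 + particle id` mod 2³¹), so reruns are byte-identical. In
synthetic mode, chemistry is joined to shape via ground-truth matching of
segmented regions (emulating per-particle spectral acquisition); with
file inputs, spectra are joined by filename stem. Particles without a
spectrum keep null chemistry fields. Stage errors abort the run with a
stage-tagged message and remove partial outputs. The per-run report
asserts the accounting identity: rows = segmented regions − border
exclusions − sub-minimum-ECD exclusions.

## Problem sizes and determinism in the test suite

The suite validates statistics at desk scale: 100 random polygons for the
Feret oracle, 300 spectra (100 per material) for classification accuracy,
30 spectra per size tier for score trends, 50 replicates for noise
scaling, 40-particle scenes across five blur/noise levels for the
degradation trend, and 4 × 50 flakes for parameter recovery. All
stochastic tests use fixed seeds; property tests run derandomised. These
sizes give stable verdicts for the assertions made (orderings,
monotonicity, bounds) while keeping the full suite under a minute on one
CPU.

## Known limitations

- Absolute particle concentration is out of scope by design: static
  imaging is percentage-based here, and per-container counts for the
  compendial check are taken as given integers.
- Touching particles are not split (no watershed); overlap is avoided at
  generation time instead.
- The phantom generator's passing tests demonstrate correctness of the
  measurement chain, not instrument realism: real particle images add
  focus error, uneven illumination, and shape families outside the four
  templates; real spectra add fluorescence backgrounds and cosmic-ray
  spikes that the smooth-baseline model does not emulate.
- Cross-material score magnitudes depend on the band templates; only
  their orderings are meaningful.
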