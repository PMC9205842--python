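# Methods

`offsetspect` simulates undersampled brain SPECT and evaluates whether a
compressed-sensing-style reconstruction (total-variation-regularized one-step-late EM)
combined with half-step *offset* dual-head sampling preserves image quality and
quantification as the number of projections drops from 120 to 8.  This note records the
models, the parameters that matter, and the design choices made where the design was
genuinely open.

## Phantoms

All phantoms are hard-mask (non-antialiased) count-density grids on a center-anchored
coordinate system: pixel (r, c) sits at x = (c − (cols−1)/2)·Δ, y = ((rows−1)/2 − r)·Δ,
with Δ = 3.2 mm and 128×128 matrices in the study conditions.  Hard masks make the
linearity references and the ground-truth specific binding ratio exact.

* **Resolution phantom** — a uniform cylinder cross-section (default radius 150 mm,
  10 counts/pixel) containing three single-pixel point sources at 800 counts/pixel,
  placed at (0, +10), (0, +100) and (+100, 0) mm.  The off-center placement of the
  100 mm sources is what lets radial and tangential widths be measured separately.
  Positions and the point diameter are config-exposed; the single-pixel default is the
  simplest model consistent with FWHM measurement.
* **Multi-cylinder phantom** — a 160 mm cylinder at 100 counts/pixel holding six 40 mm
  cylinders at {0, 200, 300, 400, 600, 800} counts/pixel on a hexagonal ring of 50 mm
  radius (clockwise from 12 o'clock, ascending count).  Cylinder discs are realized by
  nearest-pixel area matching, so every labeled area is within one pixel-area of πr².
* **Striatal digital brain phantom** — a parametric stand-in built from ellipses:
  170×130 mm parenchyma at 100 counts/pixel, a 6 mm bone shell at 20, a 30×20 mm
  central ventricle at 0, and bilateral comma-shaped striata (vertical elliptical body
  plus anterior circular head, ≈32 mm long) at 800 counts/pixel.  Only the four count
  levels and the striatum-to-parenchyma ratio of exactly 8 are fixed study conditions;
  the anatomy is illustrative.  3D stacks are uniform extrusions of the 2D
  cross-section (slice thickness = pixel size); all reported metrics use the central
  transverse slice.

## Acquisition model

A dual-head parallel-hole system rotates over 360° at a 150 mm radius.  *Onset*
(conventional) sampling uses a constant step s = 360/n; for even n opposed views are
conjugate, so only n/2 distinct modulo-180° directions are sampled.  *Offset* sampling
shifts the second head by s/2: head 1 covers {k·s}, head 2 {180 + s/2 + k·s}; for
n = 60 that is 0°–174° and 183°–357°, and the distinct directions double to n.  Odd n
(the study grid includes 15 and 45) splits ceil/floor between the heads.

Projections are generated analytically at the exact requested angles rather than by
Monte-Carlo photon transport.  The projector is pixel-driven: each square pixel projects
onto the detector axis as a strip of width Δ(|cos θ| + |sin θ|) centered at
t = x cos θ + y sin θ, distributed over 3.2 mm bins by exact box overlap
(`footprint="strip"`).  The classical two-bin linear splat (`footprint="point"`) is
also available, but it is *not* the default: its interpolation kernel barely sees
checkerboard (Nyquist) image modes, and a blur-free EM system model then amplifies them
into a strong pixel-alternation texture that corrupts FWHM profiles.  The strip
footprint, being the exact projection of the square pixel basis, suppresses that null
space.  Within one view each pixel's weights sum to 1, so view totals conserve counts
exactly; the operator is linear and the brute-force ray-sum oracle in the test suite
reproduces it to round-off.

Collimator resolution is a Gaussian with FWHM(d) = 3.8 mm + 0.047·d — an LEHR-like
response, ≈10.85 mm at the 150 mm radius — applied to the noise-free projections as a
*stationary* blur evaluated at the rotation radius (depth-dependent modeling belongs to
resolution recovery, which this pipeline deliberately omits, also in the reconstruction
system model).  Neither attenuation nor scatter is simulated, matching a pipeline with
no attenuation or scatter correction and keeping FBP a meaningful reference.

Noise: the acquisition time per view is constant, so every view is scaled to an
expected total of 75 000 counts regardless of n (total counts therefore drop
proportionally when undersampling — 120 → 8 views means 1/15 the acquisition time) and
each bin is Poisson-sampled with a caller-supplied seed.

## Reconstruction

All methods operate on 2D transverse slices; 3D sinograms are reconstructed
slice-by-slice.  Reconstruction support is the inscribed circle of the grid (pixels
outside have zero sensitivity and stay 0).

* **FBP (reference)** — ramp filtering with the band-limited spatial-domain kernel
  (h[0] = 1/(4Δ²), h[n] = −1/(πnΔ)² for odd n), zero-padded to suppress wrap-around,
  backprojected through the projector adjoint with weight πΔ²/N.  The band-limited
  kernel carries the correct DC term; a raw |ν| multiplication with a zeroed DC sample
  biases a uniform disc about 6% low.  Used as the 120-view onset reference; ramp only,
  no Butterworth.
* **ML-EM** — the multiplicative Poisson EM update
  f_i ← f_i / Σ_j C_ij · Σ_j C_ij p_j/(Σ_k C_kj f_k), 100 iterations, uniform unit
  initialization inside the support.
* **CS-IR (TV-regularized OSL-EM)** — the one-step-late scheme with the smoothed
  isotropic TV prior U_TV = Σ √((f_{k+1,l}−f_{k,l})² + (f_{k,l+1}−f_{k,l})² + ε²)
  (forward differences, replicate edge: zero difference at the last row/column, which
  keeps U_TV finite and the analytic gradient consistent).  The denominator is
  Σ_j C_ij · (1 + β ∂U_TV/∂f_i), evaluated at the previous iterate.  Weighting the
  prior by the sensitivity makes β dimensionless — invariant to the projector's
  normalization and to the number of views — which is what lets a single β = 0.001 act
  comparably from 8 to 120 views.  (With an additive denominator Σ C + β∂U, the same β
  is numerically inert: |∂U_TV| ≤ ~3 against a sensitivity of order n_views.)
  β = 0 reduces to ML-EM exactly, bit for bit.
* **CS-IR with offset** — identical code on an offset-geometry sinogram; the geometry
  enters only through its angle list.

Defaults and numerical guards: 100 iterations; β = 0.001; ε = 1e−6 counts (ε only
regularizes the square root at zero gradient; it is not a study condition and is
config-exposed); OSL denominator clamped below at 1e−12·max(sensitivity) because the
prior term can drive it toward zero for large β; the Butterworth pre-filter
(order 8, cutoff 0.5 cycles/cm, magnitude form H = [1 + (ν/νc)^{2n}]^{−1/2}, DC gain
exactly 1) is applied to the projections of the three iterative methods — along the bin
axis for 2D data and radially across bin and slice axes for 3D — and the filtered data
are clipped at 0 before EM, since filter ringing can produce small negative values.
Butterworth exponent conventions vary between vendors; the plain magnitude form is
used and exposed.

## Metrics

* **FWHM** — the line profile through the local maximum nearest the requested source
  position (peak searched within 2 pixels), sampled by bilinear interpolation at Δ/4
  steps over ±40 mm; baseline = median of the outer 25% of profile samples (the
  resolution phantom has a 10 counts/pixel pedestal); width at
  baseline + (peak − baseline)/2 by linear interpolation.  Reported resolution is the
  mean of the x- and y-axis profiles.
* **ASR** — radial/tangential FWHM at an off-center source; the radial direction points
  from the phantom center to the source.
* **Linearity** — an 80 mm² circular ROI (nearest-pixel area matching) centered on each
  cylinder; measured and assigned densities are both normalized to their maxima and
  summarized by the product-moment correlation r.
* **%CV** — 100·SD/mean in four 9×9-pixel (829 mm², nearest realizable to 900 mm²)
  square ROIs, summarized as mean ± SD over the ROIs per noise realization; the sweep
  additionally aggregates across seeds.  The ROIs sit at (±17.6, ±40) mm in the
  anterior/posterior parenchyma.  This placement was chosen once on the noise-free
  120-view reference reconstruction and frozen: ROIs placed beside the striatum or
  ventricle ride their partial-volume blur skirts and measure deterministic gradients
  (~15 %CV) instead of noise, defeating the metric.  Centers are config-exposed.
* **SBR** — (MEAN_striatum − MEAN_occipital)/MEAN_occipital, with the striatal mask
  copied from the ground-truth contour (both striata pooled) and a 2000 mm² elliptical
  occipital ROI centered at (0, −40) mm, wholly inside the parenchyma.  The phantom
  itself gives exactly (800 − 100)/100 = 7; reconstructions give less because the
  ≈15 mm effective resolution dilutes the ~15 mm-wide striata (partial volume), e.g.
  ≈4.1 at 60 views.

All metrics are invariant to positive global rescaling of the image, so the arbitrary
count scale of an EM reconstruction of renormalized views does not matter.

## What the simulation does and does not emulate

The generator reproduces the study conditions — matrix, pixel size, rotation radius,
per-view counts, angle schemes, count levels — but stands in for Monte-Carlo photon
transport with an analytic projector.  It has no septal penetration, no scatter, no
attenuation, no depth-dependent resolution, no detector intrinsic response, and the 3D
brain is an extruded 2D section.  Consequently the *absolute* numbers differ from a
physical or Monte-Carlo system: reconstructed FWHM is ≈14–16 mm (collimator blur ⊕
Butterworth roll-off ⊕ pixel footprint) rather than ≈11 mm, %CV magnitudes are
pipeline-specific, and SBR settles near 4.1 rather than ≈2.6.  The *directional*
findings are the reproducible content: FWHM and ASR stable across n for offset CS-IR
(ASR within 1.0 ± 0.1 down to 8 views); linearity r > 0.99 for every method at
n ≥ 15, degrading at 8 onset views but not at 8 offset views; %CV ordering
CS-IR-offset < CS-IR < ML-EM at 60 views; offset-CS-IR SBR flat (< 10% spread) across
n.  Passing tests demonstrate these orderings for this simulation, not calibrated
clinical performance.

At 60 views the offset-vs-onset %CV gap is small (noise-dominated; both geometries are
artifact-free there) — the dramatic offset gains appear at 8–15 views, where onset
reconstructions show streaks and patchy TV textures (noise-free background %CV 31.7
onset vs 3.7 offset at n = 8).

## Problem sizes in the test and acceptance runs

Directional checks run at the full study conditions (128×128, 100 iterations,
75 kcounts/view) with fixed seed lists, sized to keep the default suite fast: 10 noise
seeds for the ASR sweep (6 projection numbers) and the 60-view %CV ordering, 3 seeds
per projection number for the SBR curve, 2 seeds per cell for the linearity grid.  The
acceptance script re-derives its reported quantities from scratch at the same
conditions, with the 10 noise seeds spawned from the command-line seed.

## Known limitations

* The effective regularization of a count-scale OSL-EM depends on the data scale; the
  sensitivity-weighted prior makes β portable across geometries, but mapping β onto any
  particular clinical implementation requires recalibration.
* FBP is implemented for uniformly spaced 360° view sets; calling it on offset
  geometry warns and treats the angle list as-is.
* The FWHM estimator requires a detectable local maximum; on extremely undersampled
  noisy reconstructions (4 distinct directions) profile shoulders can sit above the
  half-maximum, which is reported honestly as a wide FWHM rather than rejected.
* `optimal_projection_number` documents the angular sampling theorem
  (ceil(πD/(2Δ)) directions over 180°; `span_deg=360` doubles before rounding).
  Literature conventions disagree on the factor of two, so it is descriptive, not
  normative.
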