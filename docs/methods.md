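# Methods

## Scope and model

The package quantifies expansion-microscopy z-stacks of kinetoplastid
cytoskeletons along three routes: lateral periodicity of the subpellicular
microtubule corset (Fourier analysis of projected patches), isotropy and
extent of expansion from axoneme cross-sections (segmentation → geometry),
and expansion factors as ratios of imaged to native dimensions. All image
quantities are physical: stacks carry a lateral pixel size (nm) and a z-step
(nm) from construction, and no operation defaults to pixel units.

Native reference dimensions (`ReferenceConstants`):

| constant | default | meaning |
|---|---|---|
| `axoneme_diameter_ref` | 220 nm | native axoneme cross-section diameter (transmission-EM value) |
| `corset_center_to_center_ref` | 50 nm | native corset microtubule centre-to-centre distance: 24 nm gap + ~25 nm microtubule diameter, carried as the conventional "about 50 nm" (the exact 49 nm sum is also reported by `reference_center_to_center`) |
| `lateral_blur` | 200 nm | lateral PSF FWHM of the emulated acquisitions (bead-calibrated) |
| `tilt_limit_deg` | 5° | maximum tube tilt for a cross-section window to count as perpendicular |

## Synthetic data generator

The generator emulates the three image classes the analysis consumes, each
with its ground truth recorded for parameter-recovery testing.

* **Parallel lines** (corset patches): unit-intensity lines deposited with a
  1-px triangular profile at exact sub-pixel positions, spacing and
  orientation free. `orientation_deg` is the direction of the periodic
  modulation (the wave vector); line crests run perpendicular to it, so the
  generator's orientation and the spectral band's orientation share one
  convention. Spacings below 2× the pixel size are rejected (Nyquist).
  The default line count fills the field, as microtubules fill a selected
  corset patch.
* **Tube** (axoneme cross-sections): one anti-aliased filled disc per plane;
  a tilt of θ from the optical axis displaces the centre by Δz·tan θ per
  plane along a fixed azimuth, cumulative (dx, dy) drift is added per plane,
  and `anisotropy_yx` scales the y semi-axis so the raster-level aspect
  ratio is exactly that value before blurring. A hollow-ring variant
  (`annular=True`) is available for visual realism; the analysis default is
  the filled disc, matching what a closed threshold mask of a labelled
  axoneme looks like. An error is raised if the tube leaves the field on any
  plane.
* **Filament** (whole corset in projection): a straight segment or circular
  arc of stated arc length rendered as a band of stated width (default
  150 nm) via a distance transform of the densely sampled centre line. Arcs
  subtending ≥ 360° are rejected as self-intersecting.

**PSF**: separable anisotropic Gaussian parameterized by FWHM
(σ = FWHM/2.3548); defaults 200 nm lateral (the calibrated blur above) and
500 nm axial (conventional confocal axial resolution). Blur kernels are
normalized; lateral edges use zero padding while structures that genuinely
continue beyond the field (line patterns laterally, tubes axially) use
edge replication, which is why noise-free blurred images conserve the raster
total intensity to better than 0.1 %.

**Noise**: Poisson shot noise on scaled intensity (`poisson_scale` photons
per unit intensity) followed by additive Gaussian read noise, then clipping
at zero — the standard fluorescence model. The acquisitions being emulated
state no SNR; the default used in recovery experiments
(`gaussian_sd = 0.02`, `poisson_scale = 200`) is chosen so that the
intermeans threshold separates structure from background cleanly, and is an
assumption, not a measured property. Identical parameters and seed give
bit-identical stacks.

What the generator does **not** emulate: optical aberrations,
depth-dependent signal loss, refractive-index mismatch, labelling
stochasticity, sub-structure of the microtubule wall, or whole-cell
geometry. Recovery tests therefore demonstrate correctness of the
*estimators* under a known forward model, not performance bounds on real
acquisitions.

## Fourier spacing estimation

Regions are average-projected over their stated plane interval, the mean is
subtracted, and the 2D FFT is taken without windowing by default (matching
common interactive tooling; a Hann option would suppress edge leakage but
changes band extents, so it is deliberately not silently applied). Each bin
is annotated with periodicity `pixel_size · N / radial_index` and
wave-vector orientation.

The dominant band replaces interactive oval selection with a deterministic
rule: the strongest off-DC bin inside the periodicity search range seeds an
8-connected flood fill over bins ≥ `peak_fraction` (default 0.5) of the
peak; the Hermitian mirror of the band is included. The band reports its
min/max bin periodicity, power-weighted centre, and its share of off-DC
power.

**No-band rule.** A peak must exceed the robust background
(median + 5·MAD of off-DC magnitudes) *and* the band must carry at least
`min_band_power_fraction` (default 0.02) of the off-DC power. The second
condition is required because the maximum of tens of thousands of
Rayleigh-distributed noise magnitudes routinely exceeds a median + 5·MAD
threshold by extreme-value statistics; a noise maximum, however, is a 1–2
bin "band" carrying ~10⁻⁴ of the power, while a genuine line pattern
concentrates orders of magnitude more. White-noise images are rejected
reliably; line patterns at realistic noise are not.

**Reconstruction.** Inverse FFT keeping only in-band (or only out-of-band)
coefficients. The DC term is excluded from peak search and power accounting
and is assigned once — to the in-band reconstruction — so the in-band and
complement images sum exactly to the input and brightness is preserved in
the in-band image. `signal_fraction` (Pearson correlation) quantifies how
much of the original signal a reconstruction retains.

Aggregation over regions: mean ± sd of lower band boundaries, of upper band
boundaries, and the mean of per-region band centres; regions with no
detectable band are excluded and logged.

## Axoneme isotropy pipeline

* **Threshold**: iterative intermeans (ISODATA variant) computed on float
  intensities directly — the fixed point t = (mean ≤ t + mean > t)/2 — which
  makes the mask exactly invariant under positive affine intensity maps.
  The histogram-based scikit-image implementation serves as an independent
  cross-check in the tests, not as the implementation.
* **Closing**: 3×3 square structuring element, one iteration (configurable
  in principle; fixed here for reproducibility).
* **Centroid**: area centroid of the largest 8-connected component; smaller
  specks are noise and are ignored rather than failing the plane.
* **Perpendicularity**: a 5-plane window passes iff the xy distance between
  its first and fifth centroid is ≤ 4·Δz/tan(90° − tilt_limit), numerically
  identical to 4·Δz·tan(tilt_limit); ~35.0 nm at Δz = 100 nm and the 5°
  default. A distance exactly at the threshold passes. Windows overlap with
  stride 1. The first-vs-fifth reading (rather than all intermediate pairs)
  follows the procedure being reproduced.
* **Registration**: translation by subpixel phase correlation
  (upsampling ×20) plus a bounded rotation grid search (±10°, 0.5° step)
  scored by the phase-correlation residual. Because an axoneme cross-section
  is nearly circular, rotation is close to degenerate; among angles within
  5 % of the best residual the smallest |angle| is chosen, which keeps the
  recovered translations clean. Shifts beyond ¼ of the field raise a
  divergence error.
* **Ellipse**: the moment-equivalent ellipse of the re-thresholded sum of
  the five registered planes — same area, centroid and second central
  moments as the component (full axes 4·√λ of the coordinate covariance).
  The equivalent-circle diameter is 2·√(area/π).
* **Blur correction**: the exact arithmetic used by the original
  measurement is not stated and cannot be back-solved uniquely from its
  printed values (the printed diameters already reproduce the printed
  factors with no correction). Three conventions are therefore provided —
  `none` (default), `quadrature` (√(d² − b²), appropriate for Gaussian
  blur of a Gaussian-ish profile) and `linear` (d − b) — and the mode is
  recorded in every output row. On synthetic discs blurred at FWHM 200 nm,
  `quadrature` recovers generating diameters to ~1 %, `none` to ~2 %.

## Corset length

Intermeans threshold → largest component → skeleton → longest geodesic path
between skeleton endpoints (Dijkstra over 8-connected skeleton pixels,
diagonal weight √2) → path length. The path length is computed by summing
chords between every 5th path pixel rather than counting raster steps: the
step-count estimator overestimates smooth curves by up to ~8 % (staircase
effect), while chord summation is exact on straight segments and
underestimates a circular arc only by O((chord/radius)²). Straight 90 µm
and semicircular (π·20 µm) synthetic filaments are recovered to ~0.2 %.
A closed-loop skeleton (no endpoints) or a featureless projection raises a
measurement error. Skeleton end-shortening (~half the band width per end)
is below 0.5 % at corset-like aspect ratios and is not corrected.

## Expansion-factor arithmetic

* Length ratios use range midpoints — an interpretation, flagged in the
  output notes, chosen because it reproduces the conventionally quoted
  factors (90/20 = 4.5; 45/9.75 ≈ 4.6) exactly.
* The spacing reference is stored as the stated "about 50 nm", not the
  exact 49 nm sum, because downstream reporting (300/50 = 6.0) uses the
  rounded value; both are available.
* Rounding for reported one-decimal factors is half-up (4.65 → 4.7), with
  full precision always retained alongside; a pre-round at 10⁻⁹ guards the
  half-up boundary against float representation noise.
* Gel expansion is the arithmetic mean ± sample sd of replicate factors.

## Problem sizes and numerical choices

Recovery experiments in the tests and the acceptance script use 256-px line
fields at 70 nm pixels, 96–128-px tube fields at 50–70 nm pixels with 5–15
planes and a 100 nm z-step, and filaments up to 90 µm at 70 nm pixels —
sizes at which every stage is exercised end-to-end (10-region spacing
aggregation, 11-window axoneme runs) while a full suite completes in well
under a minute of compute per module. Pixel sizes sit inside the calibrated
range of the emulated acquisitions (52–97 nm). Seeds are fixed in tests;
the acceptance script derives all stream seeds from its `--seed` argument.

Degenerate inputs are explicit errors, not silent results: constant images
(threshold, spectrum), empty masks, 1-px-wide components, sub-Nyquist
spacings, tubes leaving the field, closed-loop skeletons, and blur
corrections that would produce non-positive diameters.

## Known limitations

* The spacing estimator assumes a single dominant periodicity per region;
  two overlapping corsets in one patch would merge into one band.
* The isotropy pipeline assumes a single axoneme in the analysed ROI; there
  is no instance segmentation.
* Perpendicularity is inferred from centroid displacement only; a tube
  bending symmetrically within a window could pass while not being straight.
* Synthetic recovery bounds do not transfer directly to real acquisitions
  (see the generator's non-goals above); deconvolution, aberration and
  depth-dependent loss are out of scope.
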