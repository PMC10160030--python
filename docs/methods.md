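# Methods

## The measurement being modeled

DESI-MSI rasters a charged solvent spray across a thin tissue section on a
glass slide; each full scan is one pixel of an image. Rows of the raster
are stage steps (one instrument file per row in the original acquisitions);
columns follow the lateral scan direction, so the pixel width is the
product of the stage's lateral speed and the scan cycle time, while the
pixel height is the vertical step size. The package carries both published
acquisition geometries: 114.6 × 130 µm at 120.37 µm/s (low resolution) and
72.6 × 80 µm at 53.69 µm/s (high resolution, the default for the synthetic
generator). Intensities are in arbitrary counts; spectra are centroided,
with m/z stored at 64-bit precision (ppm windows need it) and intensities
at 32-bit.

## Ion images and normalization

An ion image maps each pixel to the summed intensity inside an inclusive
relative window `mz·(1 ± ppm·1e-6)`; the default tolerance is ±5 ppm,
matching orbitrap mass accuracy. %TIC normalization divides each pixel's
window sum by that pixel's total ion current and multiplies by 100; pixels
with zero TIC map to 0. TIC is the sum over the pixel's full acquired
range, not over a target list, and the per-pixel (not per-image) convention
is assumed — the standard %TIC definition. Because TIC normalization is
susceptible to matrix effects, the unnormalized image is a first-class
mode, not a debugging aid: distribution patterns should be checked in both.

Ratio images divide two same-mode images pixel by pixel. Pixels whose
denominator is at or below a floor (default 0) are masked rather than
inflated by an epsilon — masking is transparent, an epsilon would bias
small denominators. Stored values are never clipped; the display scale cap
(default 11) applies only at render time. Rendered PNGs use viridis
(deep purple = least intense, yellow = most intense) but are decorative;
the delimited numeric grid is the contract surface.

## Axis profiles and per-position statistics

A profile line is drawn through the root center (coordinates are supplied
numerically; automatic axis detection is out of scope). At each of
`n_samples` equally spaced points the image is averaged over a
perpendicular band, nearest-pixel sampling, no interpolation — this mirrors
raster-pixel line-width averaging and keeps the brute-force oracle exact.
A band width of ten pixels samples the line point plus five pixels on each
side. Band points beyond the image edge are dropped with a warning.

Each section's profile is scaled to its own maximum (so a global intensity
rescale of a section is a no-op), then replicate sections are averaged
pointwise: mean and sample s.d. (ddof = 1, hence ≥ 2 sections). Sections of
unequal physical length are aligned by fractional position along the axis
and linearly resampled to the longest section's sample count — the minimal
assumption when averaging sections that differ slightly in length.

Two metabolites' profiles are compared position by position with a
two-tailed, two-sample, equal-variance Student's *t*-test on the
per-section scaled values. Raw p-values are flagged at α = 0.05 by default,
matching per-point asterisk conventions; a Bonferroni option exists but is
off. The implementation handles the degenerate zero-variance cases
deterministically (identical groups: t = 0, p = 1; unequal constant
groups: p = 0) and is cross-checked against `scipy.stats.ttest_ind` in the
tests. Which pair of ions is compared is the caller's choice; the package
compares two named profiles (succinate vs aconitate in the examples).

## Lateral resolution (80–20% rule)

A single-ion chromatogram along one raster row (distance = column × pixel
width) crosses the tissue boundary twice. The baseline is the mean of the
eight off-tissue points on the edge's own side (leading for rising,
trailing for falling — the same off-tissue convention as the zone spectra);
the amplitude is the chromatogram maximum minus baseline. The fit gathers
the points strictly between 20% and 80% of the amplitude, walking outward
from the edge's 50% crossing (first crossing for rising, last for falling)
while the signal keeps changing monotonically in the edge's direction. The
monotone stop is a deliberate numerical choice: with multiplicative
per-pixel intensity drift the chromatogram maximum is an inflated plateau
outlier, the entire plateau then sits strictly inside the 20–80% band, and
an unrestricted "all interior points" rule fits a near-flat line with
absurd resolution values; stopping when the signal stops rising confines
the fit to the edge itself.

An ordinary least-squares line through those points (points, plural — not a
two-point secant) is solved via the point-slope formula for the x
coordinates of exactly 20% and 80% of the amplitude; the resolution is
|x₈₀ − x₂₀|. Degenerate cases: with a single interior point its two
bracketing neighbors join the fit; with none, the two samples straddling
the 50% level are used (for a hard step this yields 0.6 × pitch, correctly
below one pixel); a perfectly flat fallback raises an error carrying the
pixel width as the upper bound. Closed forms used as oracles: a linear
ramp of width L gives 0.6·L; a Gaussian-blurred edge of scale σ gives
(z₀.₈ − z₀.₂)·σ ≈ 1.683·σ.

Rising and falling estimates are aggregated over several rows per section
and several sections (4 rows × 10 sections → n = 40 per edge in the
reference design; n counts measurements, not sections) and compared with
the same equal-variance *t*-test; symmetric blur should accept the null.
Any longitudinal biological gradient in the chosen ion broadens the
estimate, so the generator can disable gradients for calibration runs, and
the default resolution target is the constant-profile lipid peak.

## Zone spectra

Centroid positions jitter scan to scan, so averaging uses a shared
log-spaced axis with 5 ppm bins (consistent with the imaging tolerance),
anchored at the acquisition's low m/z limit; a bin's average divides its
summed intensity by the number of scans selected, whether or not each scan
contributed a peak. The background spectrum — eight off-tissue scans per
row by default; which side of the tissue is user-specified — is subtracted
bin-wise from the on-tissue average, flooring negatives at zero (average
intensities are non-negative by definition; the floor can be disabled for
diagnostics). Two spectra binned with different anchors or widths cannot
be aligned and raise. Centroid-binned averaging approximates what profile
data averaging would give; window sums can differ slightly between
representations.

## Expression enrichment

From a table of per-gene FPKM in the meristem, elongation and
differentiation zones, a gene's enrichment is the ratio of its mean
transformed expression in the meristem to that in the differentiation
zone, with the transform log₁₀(3 × max(FPKM, ⅓)). Base 10 and the ⅓ floor
are explicit choices (the floor makes zero-FPKM genes map to exactly 0 and
keeps the log finite); both are configurable because the ratio of logs is
materially sensitive to them. A raw-FPKM-ratio mode is provided since
"enrichment" is ambiguous between ratio-of-transformed-means and
ratio-of-raw-means; the two are one flag apart. A zero differentiation
mean flags the score undefined rather than raising. Gene sets are
arbitrary caller-supplied lists.

## The synthetic generator

The generator stands in for deposited raw imaging data and defines the
study conditions for every test:

- **Geometry**: 40 rows × 150 columns at 72.6 × 80 µm by default.
- **Tissue**: a tapered capsule — quarter-ellipse tip rounding over 25
  columns, maximum half-width 12 rows, a flat cut at the shank end —
  leaving ≥ 8 off-tissue columns on each side for backgrounds and edges.
- **Gradients** (fractions of the tissue axis, tip = 0): succinate as a
  Gaussian bump centered at 0.15 (meristem), amplitude 3000; aconitate
  logistic rising shankward around 0.5, amplitude 2500; fumarate logistic
  shankward around 0.55, amplitude 1500; malate constant at 20000 so one
  dominant ion carries the TIC and %TIC normalization is exercised
  non-trivially; a constant phosphatidylglycerol at 5000 as the
  strong lipid-range ion near the tissue edge for resolution work.
- **Background**: one matrix peak present on and off tissue at equal
  level (amplitude 600), so background subtraction has something real to
  remove.
- **Noise**: Poisson counting noise per peak; per-pixel multiplicative
  lognormal TIC drift (s.d. 0.15); uniform m/z jitter within ±2 ppm —
  inside the ±5 ppm windows, so window sums see jitter but do not lose
  peaks.
- **Edges**: the binary capsule is rasterized on a 5× subsampled grid, a
  signed Euclidean distance to the boundary (corrected for the half-cell
  offset of the distance transform) is pushed through a normal CDF at
  scale σ (default 110 µm ≈ 1.5 pixel widths), and averaged over each
  pixel's footprint — a straight boundary therefore shows an erf edge with
  20–80% width ≈ 1.683 σ plus a small (< 2%) pixel-integration widening.
- **Reproducibility**: every pixel draws from a generator seeded with
  (master seed, row, column), so growing the grid never changes earlier
  pixels' draws and a fixed seed reproduces the imzML byte for byte (the
  ibd UUID is derived from the payload digest rather than drawn at
  random). Replicate sections split per-section seeds from the master and
  vary the section length by a few columns to exercise profile resampling.

What it deliberately does not emulate: realistic lipid/benzoxazinoid
chemistry or full spectra (each pixel holds one sparse centroid list with
one peak per configured species), spray-dynamics of the desorption spot,
3-D sectioning effects, or correlated (structured) noise. Tests passing on
this generator therefore demonstrate that the pipeline's arithmetic and
statistics recover programmed signals under realistic counting noise and
drift — not that any particular biological claim holds on real tissue.

## Problem sizes and runtime

Default test problem sizes: one 40 × 150 section simulates in well under a
second; recovery suites use 10 sections, 60 profile samples, 2,000
replicate positions for the type-I-error calibration and 100 replicates
for the edge-symmetry null check. The full test suite runs in tens of
seconds on one CPU.

## Known limitations

- Rectangular rasters only; partial/missing coordinates are an error, not
  interpolated.
- The profile line is straight; curved (spline) axes are out of scope.
- Profile-mode (non-centroided) spectra are accepted and passed through
  without re-centroiding; window sums on profile data may differ slightly
  from centroided sums.
- The deprotonation convention uses the proton mass and ignores the
  electron mass elsewhere (~0.0005 Da, far inside ±5 ppm windows).
- Citrate and isocitrate are isobaric and share one registry entry; mass
  spectrometry alone cannot separate them.
- imzML compression support covers none/zlib only.
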