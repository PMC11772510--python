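# Methods

This note documents the models, defaults, numerical choices and known
limitations of `duomsi`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Data model and conventions

Two modalities of one physical section share the pipeline:

* **Spectral modality** (`SpectralImage`): a complete pixel grid of
  centroided spectra, each an ordered list of (m/z, intensity ≥ 0)
  pairs. Missing pixels are empty spectra, never absent entries, so a
  reader can never silently drop pixels.
* **Elemental modality** (`ElementalStack`): co-gridded per-element
  rasters, each carrying its own unit (`counts_per_second` or
  `mg_per_kg`). Quantified and unquantified channels coexist. Missing
  values are NaN — deliberately distinct from 0, which is a valid ion
  count.

Coordinates are 0-based, `col = x`, `row = y`, origin top-left, pixel
centers at integer coordinates. imzML stores 1-based positions; the
shift happens only at the I/O boundary. Units are never inferred from
value magnitudes.

imzML support is implemented in-package (stdlib XML + numpy binary I/O)
for processed- and continuous-mode centroided data with no or zlib
compression. Profile-mode data are rejected with an explicit error
rather than resampled: peak picking is out of scope and silently
resampling profile data would fabricate centroids. The `.ibd` file UUID
is derived from the data (SHA-1), so writing the same image twice gives
byte-identical files — this is what makes simulated datasets and
re-runs reproducible at the file level.

## Ion images

* **ppm window**: two-sided, relative to the target, inclusive bounds —
  half-width = target × tol × 10⁻⁶. Peaks are summed, not maxed.
  Default tolerance 10 ppm.
* **TIC normalisation**: each pixel divided by its own total ion
  current (sum over the full mass range). Zero-TIC pixels map to 0.
  The result is a pure ratio with no rescaling by the mean TIC: every
  downstream statistic used here (Pearson r, display scaling) is
  invariant to a constant factor.
* **Hot-spot clipping** (default q = 0.99): threshold is the
  linear-interpolation quantile of the *nonzero* pixel values (zeros
  are off-tissue background and would deflate the threshold; the
  all-pixel pool is available via `nonzero_only=False`, and the choice
  is recorded in the image metadata). Values above the threshold are
  set to it. Clipping an already-clipped image is a no-op by contract:
  recomputing an interpolated quantile on a clipped distribution walks
  the threshold down slightly on every pass, so idempotence is enforced
  through the recorded `clipped_at` value.
* **Recalibration**: a single global multiplicative m/z factor — the
  simplest model consistent with calibrating against known endogenous
  lipid masses. Each reference is paired with the nearest mean-spectrum
  peak within `search_ppm` (default 20 ppm); the factor is the
  intensity-weighted mean of theoretical/observed ratios; unmatched
  references are skipped and reported. A fitted factor beyond ±100 ppm
  raises — that indicates mis-pairing, not miscalibration.
* **Mean spectrum**: peaks pooled on a geometric (ppm-constant) bin
  grid; per-bin intensity-weighted mean m/z and mean intensity per
  pixel (pixels without a peak contribute 0); empty bins dropped.

## Elemental quantification

* **Rasterization**: along-line position = timestamp × scan speed;
  readings in `[k·px, (k+1)·px)` average into pixel k (half-open
  intervals, so every reading lands in exactly one pixel). Averaging,
  not interpolation: a 30 µm beam at 750 µm/s yields several ICP
  readings per pixel and the mean is the natural pixel estimate. Rows
  are ordered by y-offset; short lines pad with NaN; duplicate offsets
  are an error.
* **Calibration**: ordinary least squares of per-standard mean
  counts/s on nominal mg/kg. The intercept is fitted, not forced
  through zero — blank gelatine has a nonzero background and the
  0 mg/kg standard carries it. The per-standard summary statistic is
  the mean by default with a median option (`stat="median"`). r² and n
  are reported per curve; a non-positive slope flags the curve instead
  of raising, and a flagged curve refuses to quantify.
* **Application**: counts → (counts − intercept)/slope, unit mg/kg.
  Channels without a requested curve pass through bit-identical in
  counts/s (mirroring practice for elements with high endogenous
  gelatine background). Negative concentrations are kept, not clamped —
  clamping would bias region means and correlations — and the affected
  pixel count is recorded in the stack metadata as a QC flag.

## Registration

The transform maps moving-grid (elemental) pixel coordinates into the
fixed (spectral) frame. Families: translation (mean offset), similarity
(Umeyama closed form via scikit-image), affine (ordinary least squares
via `lstsq`). The affine family is deliberately *not* delegated to
scikit-image's estimator, which solves the homogeneous DLT system
(total least squares) and diverges from ordinary least squares on noisy
correspondences; the plain LS solution is the documented contract here
and is verified against an explicit normal-equations oracle in the
tests.

`family="auto"` picks the richest family the landmark count supports
(affine ≥ 3 non-collinear, similarity ≥ 2, translation ≥ 1). Collinear
landmarks with an explicit affine request raise an error naming the
points. Non-rigid models are excluded by design: both acquisitions
image the same physical section, so there is no deformation to model.

Resampling is inverse (pull) mapping at pixel centers, nearest or
bilinear. Bilinear is missing-aware: NaN or out-of-bounds neighbours
are dropped and the remaining weights renormalised; an all-missing
neighbourhood yields NaN. The fixed frame defaults to the spectral
grid (lipid imaging first defines the reference frame); both grids here
use 30 µm pixels, and because landmarks are expressed in each
modality's own pixel coordinates, the similarity/affine families absorb
any pixel-size mismatch.

## Correlation

Pearson r per (lipid, element) pair over the shared mask (TIC > 0 and
all elemental channels present), with **pairwise-complete** deletion per
cell — each cell uses every pixel where *its two* channels are present,
which is exactly a pixel-to-pixel comparison of two images at a time and
maximises usable pixels. The per-cell pixel count is reported.

Cells with fewer than two complete pixels or a constant channel are
**undefined** (NaN, serialized `NA`) — never 0, which would fabricate
"no correlation". Lipid inputs are TIC-normalised, *unclipped* images;
hot-spot clipping is a display operation and applying it before
correlation (available via `clip_before_correlation`) changes the
statistic. Whether elements enter as counts/s or mg/kg is immaterial:
quantification is affine and Pearson r is affine-invariant (asserted in
the tests). No significance testing or multiple-testing machinery:
the output is the coefficient table.

Composites: each channel independently clipped at its own 99% quantile,
scaled to [0, 1] by its maximum, tinted (red/blue or magenta/cyan),
additively blended with saturation at white; masked-out pixels black.

## Synthetic phantoms — the stated world

The generator emulates a brain-like section imaged by both modalities.
All defaults below are the stated world of the test suite; they are
configurable but the defaults are fixed once.

* **Geometry**: nested ellipses on a 640 × 480 grid of 30 µm pixels —
  outer tissue ellipse ("cortex"), inner ellipse ("white matter"),
  elliptical annulus ("hippocampal ring"). The scene is analytic:
  region membership is an ellipse inequality evaluated at continuous
  coordinates, so the misaligned modality is an exact point sample of
  the same geometry, not a resampled bitmap.
* **Channels**: five positive-mode lipids (theoretical [M+H]⁺ masses
  from the bundled database) and four elements. Region means are
  specified as lipid shares of a regional TIC (columns sum to 1) times
  a TIC level, with between-region contrast ≥ 6× per channel — the
  scale of real gray/white-matter lipid contrast.
* **Noise**: lipid intensities `max(0, Normal(μ, 0.15 μ))`
  (truncated-Gaussian multiplicative, empirical MALDI pixel
  variability); an independent per-pixel TIC factor uniform in
  [0.5, 2] multiplying all peaks — the explicit mechanism that makes
  TIC normalisation consequential in tests; elemental counts Poisson
  around region means (ICP counting statistics), all means ≥ 400 so
  relative shot noise is small; optional global m/z shift for
  recalibration tests.
* **Misalignment**: 5° rotation about the grid center plus a
  (+4.5, −3.2) px translation; six fiducial landmarks near the slide
  corners/edges mapped through the true transform with σ = 0.5 px
  Gaussian jitter. Corner placement keeps the fitted transform
  interpolating over the whole tissue rather than extrapolating, as
  recommended landmark placement does in practice.
* **Analytic oracle**: `expected_correlation` is the population Pearson
  coefficient over the tissue mask computed from region areas and the
  noiseless per-pixel mean images the pipeline sees — i.e. the
  *TIC-normalised* lipid signal (regional share of TIC) against element
  means. Everything is deterministic given the seed (seeded
  `numpy.random.Generator` streams per stage).

### What a green end-to-end test establishes — and what it does not

The recovery test asserts that the measured matrix is within ±0.05 of
the analytic value for every pair at default noise. Two deterministic
biases consume part of that band: (i) partial-volume pixels at region
boundaries after resampling blend neighbouring region values, and (ii)
per-pixel noise attenuates |r| toward 0 by
`1/sqrt((1+v_x)(1+v_y))` with `v = noise var / signal var`. The
640 × 480 default grid keeps boundary pixels at ~2% of tissue and the
≥ 6× region contrast keeps attenuation at the percent level; both
design choices follow from this arithmetic, done up front, so the
stated noise settings sit inside the recovery band with margin. At
much smaller grids (e.g. 160 × 120) the boundary bias alone approaches
the band. The phantom does not emulate ion suppression, matrix
application physics, analyte delocalisation, ablation-depth effects,
within-region texture, or spatially correlated noise — so a green test
demonstrates correctness of the computation, not robustness to every
real-data pathology.

## Pipeline defaults and provenance

Zero-flag runs use: 10 ppm extraction tolerance, TIC normalisation on,
hot-spot quantile 0.99, annotation tolerance 5 ppm, affine-auto
transform family, bilinear interpolation. Every stage writes a
provenance JSON (command, config hash, package and numpy versions,
seed, effective parameters) sufficient to reproduce deterministic
stages byte-identically. Stages communicate through files so each is
independently runnable and testable; the extract stage writes both the
display product (clipped CSV + PNG) and the analysis product
(unclipped, TIC-normalised CSV) plus a manifest tying labels to files.

## Lipid database

`src/duomsi/data/lipid_db.csv` is a 20-record stand-in computed from
molecular formulas with CODATA/AME monoisotopic atomic masses
(`scripts/build_lipid_db.py` is the pre-build step). It covers common
positive-mode brain species, including the isobaric pair
PE 36:1 / PC 34:1-CH3 at m/z 746.5694, so ambiguous annotation is
exercised. It is not a curated reference list; users supply their own
CSV (`name, adduct, theoretical_mz`) for real analyses. Ambiguity is
first-class: the best match is the smallest |ppm error|, but all
candidates are exported slash-joined.

## Known limitations

* No drift or internal-standard correction, no isobaric-interference
  correction, no detection limits for the elemental channel.
* No peak picking, isotope-pattern handling, or ion-mobility dimension
  on the spectral side.
* No deformable registration and no intensity-based (automatic)
  registration — landmarks are required.
* Pearson only; no spatially aware statistics (Moran's I, variograms)
  and no colocalization metrics beyond r.
* The imzML writer emits processed mode only (reading handles
  continuous too); compression variants beyond none/zlib are not
  supported.
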