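# duomsi

Dual-modality mass spectrometry imaging analysis: combine **lipid MALDI
imaging** (imzML, a centroided spectrum per pixel) with **elemental
LA-ICP-MS imaging** (per-element ion-count rasters) of the *same* tissue
section, and quantify how lipid and element distributions co-localise.

Multimodal MSI studies image one section twice — soft laser
desorption/ionisation for intact lipids, then laser ablation into an ICP
mass spectrometer for metals — and ask which molecular species track
which elements across anatomy. `duomsi` provides the complete
computational side of that workflow for analysts who have the two raw
datasets and want reproducible, scriptable numbers instead of a chain of
GUI tools:

1. **Ion images** — per-target extraction with a symmetric ppm window
   (default 10 ppm), total-ion-current (TIC) normalisation, 99%-quantile
   hot-spot clipping for display, global mass-axis recalibration against
   known endogenous lipid masses, ppm-binned mean spectra, and
   accurate-mass sum-composition annotation (default 5 ppm) against a
   local lipid database.
2. **Elemental quantification** — rasterization of time-resolved line
   scans (along-line position = time × scan speed; e.g. 30 µm pixels at
   750 µm/s → 0.04 s per pixel) and external calibration against spiked
   gelatine standards: ordinary least squares of mean counts/s on
   nominal mg/kg, inverted per pixel, with unquantified channels passed
   through as raw counts/s.
3. **Registration** — a 2-D transform (translation / similarity /
   affine, least squares) estimated from paired landmark coordinates,
   then missing-aware pull-resampling of the elemental stack onto the
   MALDI grid.
4. **Correlation** — masked pixel-to-pixel Pearson coefficients between
   every TIC-normalised lipid image and every element channel
   (pairwise-complete; undefined cells are reported as `NA`, never 0),
   exported as a CSV table, a diverging heatmap, and two-channel
   false-colour composites (red/blue or magenta/cyan).

For each lipid image \(L\) and element channel \(E\) over the tissue
mask \(M\) (TIC > 0 and all elements present):

```
r(L, E) = Σ_{p∈M} (L_p − L̄)(E_p − Ē) / sqrt( Σ (L_p − L̄)² · Σ (E_p − Ē)² )
```

Pearson's r is affine-invariant, so it is identical whether the element
enters as counts/s or quantified mg/kg.

A first-class synthetic-data module generates paired two-modality
phantoms — nested-ellipse brain-like regions, per-channel region means,
truncated-Gaussian multiplicative lipid noise plus a per-pixel TIC
factor, Poisson elemental counts, and a known similarity misalignment
with jittered fiducial landmarks — for which the population correlation
of every channel pair is computable in closed form. Every pipeline
stage is tested against that analytic ground truth.

## Worked example

```python
import duomsi

phantom = duomsi.generate_phantom(seed=0)          # known ground truth
img = duomsi.render_spectral(phantom)              # MALDI-like modality
stack, landmarks, _ = duomsi.render_elemental(phantom)  # LA-ICP-MS-like

ions = []
for label, mz in phantom.config.lipids:
    ion = duomsi.extract_ion_image(img, mz, tolerance_ppm=10.0)
    ion.label = label
    ions.append(duomsi.tic_normalize(ion, img))

t = duomsi.estimate_transform(landmarks)
print(f"{t.family} transform, residual RMSE {t.residual_rmse:.2f} px")
registered = duomsi.resample_to_fixed(stack, t, (img.height, img.width))
mask = duomsi.build_mask(img.tic_image(), registered)
cm = duomsi.pearson_matrix(ions, registered, mask)
```

Output:

```
affine transform, residual RMSE 0.40 px
                23Na    31P   56Fe   66Zn
PE 34:1        0.686  0.789 -0.487 -0.249
PE 36:1        0.322  0.167 -0.547  0.961
PE 38:4        0.716  0.810 -0.526 -0.197
PE 40:6        0.369  0.217 -0.588  0.969
HexCer 42:2;2 -0.974 -0.928  0.992 -0.664
```

The landmarks localise the elemental grid on the MALDI grid to
sub-pixel accuracy (0.40 px RMSE against 0.5 px jitter on the
fiducials). The matrix reads like its real-data counterparts:
HexCer 42:2;2 is concentrated in the white-matter-like region, so it
correlates strongly with the white-matter-enriched element (⁵⁶Fe,
r = 0.99) and anti-correlates with gray-matter elements; the ring-region
lipids (PE 36:1, PE 40:6) track the ring-enriched ⁶⁶Zn (r ≈ 0.96). On
this phantom every coefficient is within 0.031 of the analytic
population value.

## Command line

The same pipeline as file-to-file stages, each writing a provenance
record (config hash, versions, seed, effective parameters):

```sh
duomsi simulate  --out data --seed 1 --width 160 --height 120
duomsi extract   --imzml data/spectral.imzML --targets data/targets.csv --out run
duomsi quantify  --elements data/elements --standards standards.csv --out run
duomsi register  --landmarks data/landmarks.tsv --out run
duomsi correlate --elements data/elements --landmarks data/landmarks.tsv --out run
# or everything at once on a dataset directory:
duomsi run-all   --dataset data --out run
```

With no parameter flags the run uses the standard settings for this
kind of data: 10 ppm extraction window, TIC normalisation, 99% quantile
hot-spot clip, 5 ppm annotation tolerance.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch: it simulates a phantom dataset,
runs the full file-based pipeline (extract → quantify → correlate) on
it, repeats the analysis in memory at the default phantom scale, logs
the recovered registration accuracy and the agreement between measured
and analytic correlation matrices, and writes the target-value JSON to
`--out`.

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, and known limitations.
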