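# Methods

## The mapping model

`specmap` treats a hyperspectral acquisition as a linear measurement of the
spectral irradiance reaching the sensor. The source system (push-broom
style) has bands narrow enough — FWHM of a few nm — that its per-band
response is modelled as a Dirac delta at the nominal band centre: a raw
source value is the irradiance sample at that wavelength scaled by the
sensor's quantum efficiency (QE). Dividing raw counts by QE therefore
recovers irradiance up to a wavelength-independent constant, which later
cancels in flat-field calibration. QE values at or below 0.01 are refused
(the division would amplify noise without bound); within the 440–900 nm
effective range a working sensor sits far above this floor.

The target system illuminates the scene one band at a time through tunable
filters, so its effective per-band response is the measured emission
spectrum of that band — inherently including the light source and optics.
The response matrix `SR` stacks these spectra (dense wavelengths × bands),
restricted to the effective range and min-max scaled per band. The per-band
scaling discards absolute radiometric information on purpose: the same
scaling ambiguity affects the raw, white and dark cubes identically, and
`(raw − dark) / (white − dark)` divides it out. A test verifies this
cancellation numerically.

The projection is a plain mode-3 tensor–matrix contraction of the dense
irradiance cube against `SR`. A Riemann-sum variant weighted by the dense
grid spacing is selectable (`project(..., weight_by_spacing=True)`); on a
uniform grid the two differ by a per-band constant that calibration also
removes, so the unweighted product is the default.

### Band geometry

The VIS filter covers 420–730 nm, the NIR filter 650–1100 nm; both are
sampled at 5 nm. In the overlap, bands below 710 nm come from the VIS path
and bands at or above it from the NIR path, where the combined source power
and transmittance is higher — so the stitched grid has 137 bands, exactly
one per centre. The source sensor is reliable over 440–900 nm, leaving 93
mapped bands. One characterization campaign measures 63 VIS bands in each of
three bandwidth modes plus 91 NIR bands: 280 captures.

The source grids are `source_band_grid("full")` — 826 bands spanning
400–1000 nm (~0.73 nm sampling) — and `source_band_grid("selected")` — 128
bands spanning 440–900 nm (~3.6 nm). The selected grid is defined to span
the effective range exactly (step 460/127 ≈ 3.62 nm): a 128-band grid at the
nominal 3.61 nm step starting anywhere in 400–1000 nm cannot cover the
effective range and the full range simultaneously, so the package pins it to
the interval the mapping actually uses.

### Numerical choices

- Interpolation (irradiance → dense grid, emissions → dense grid, QE at
  band centres) is piecewise linear. Extrapolation is always an error: the
  instruments carry no information outside their support.
- The dense grid defaults to 1 nm. The response matrix integrates over
  ~10–50 nm wide bands, and refining the grid from 1 nm changes band values
  at the 1e-6 level, far below every tolerance used here.
- Calibrated reflectance is clipped to [0, 1] after flat-fielding; noise and
  saturation can push isolated elements outside.
- Flat-field elements where `white − dark ≤ 1e-6` of the white dynamic range
  are set to 0 and counted; more than 1% such elements means the references
  are invalid and is an error.
- Per-pixel min-max normalization maps constant (degenerate) spectra to
  all-zero and flags them instead of failing — flat spectra occur in real
  background regions.
- The SAM cosine is clamped to [−1, 1] before `arccos`; spectral-derivative
  operators are unnormalized adjacent differences (Pearson correlation is
  invariant to the constant 1/Δλ factor a true derivative would add).
  Undefined metric values (flat rows after differencing, all-zero spectra)
  become NaN, are excluded from summary means, and are counted.

## The benchmark

Labelled pixels (normal, tumour, blood vessel, background) are calibrated,
per-pixel min-max normalized, and classified with six models at fixed
hyperparameters: SVM-linear (cost 24), SVM-RBF (cost 24, gamma 20), random
forest (50 trees), KNN with Euclidean and cosine distance (k = 20), and an
MLP with one 100-unit ReLU hidden layer trained at learning rate 0.01 for up
to 200 epochs. The printed values "cost 24" and "gamma 20" are used
literally; a reading of 2⁴ and 2⁰ is expressible through
`ClassifierConfig` overrides. Normalisation ahead of the MLP's hidden layer
is provided by input standardisation, which for a single hidden layer
normalises exactly the activations a batch-norm layer at the input of the
hidden layer would. No inner validation loop exists because no
hyperparameter is tuned.

Cross-validation is grouped by patient: patients are shuffled
deterministically and dealt round-robin into 5 folds, so folds are balanced
by patient count and a patient's pixels never appear in both training and
test. Scores are macro F1 plus per-class precision/recall. Two modalities
are compared fold-by-fold with two-sided paired t-tests; Holm–Bonferroni is
applied over the full classifier × metric family (the most conservative
family choice). Constant paired differences carry no distributional
evidence and are reported as p = 1.

## The synthetic-data generator

The generator defines the study conditions; its defaults are not tuned per
experiment.

- **Forward model.** raw = reflectance × illumination × QE (source) or the
  band-integral of reflectance × illumination against `SR` (target). The
  white reference reflects 95% of incident light; the dark reference is read
  noise only. Noise is additive Gaussian with sd proportional to the local
  signal (`noise_sd` × clean value) plus a read floor of one tenth of the
  proportional coefficient at the white level, clipped at zero counts.
  "1% noise" therefore means 1% relative noise on bright and dark regions
  alike. Shot-noise statistics, spatial PSF and stray light are not
  modelled.
- **Illumination and QE** are smooth analytic curves (broadband source
  peaking near 680 nm; unimodal QE in [0.1, 0.6] over 400–1000 nm). Their
  exact shapes are irrelevant to every result: flat-field calibration
  divides the illumination out, and QE compensation inverts the QE exactly.
- **Phantoms.** The calibration-standard phantom is spatially uniform with
  6–10 narrow Gaussian absorption dips on a bright baseline (a rare-earth
  oxide standard analogue). The plastic phantom tiles 16 materials: near-flat
  dark, near-flat bright, edge-sloped coloured and band-peaked coloured
  spectra. The brain phantom has four regions — background frame, two wiggly
  vessel stripes, a tumour ellipse, normal bulk — with smooth tissue-like
  spectra: a haemoglobin-style double dip near 542/577 nm and a reflectance
  edge into the NIR for both tissues, a strong short-wavelength absorber for
  vessels, a dark near-flat background. These are generic templates with
  controlled separation, not literature chromophore spectra: the benchmark
  tests the pipeline, not tissue optics.
- **Patient structure.** Each patient draws template perturbations once
  (spectral edge shifts of sd 9 nm, dip-depth and amplitude factors); images
  of the same patient share them up to a small per-image jitter. The edge
  shift sd is deliberately comparable to the 10 nm normal/tumour template
  separation, so classes overlap across patients and held-out-patient
  classification is realistically imperfect (macro F1 ≈ 0.75–0.95 depending
  on classifier) rather than saturated.
- **Scale.** Default experiment scenes are 22 × 22 pixels with ~64 labelled
  pixels per class per image; the benchmark cohort is 20 patients / 30
  images (~2,000 labelled pixels per class), and round-trip phantoms are
  12 × 12. These sizes keep every spectrum and class well represented while
  the whole pipeline remains a desk-scale computation.

## What the synthetic results do and do not show

Passing round-trip tests show that the implementation of the five mapping
steps is internally consistent with the band-limited forward model and
numerically accurate (noise-free mean SAM ~1e-4 rad, dominated by linear
interpolation of narrow phantom features between source samples; 1e-3 rad is
the accepted bound). They do not show that real cross-system artefacts —
illumination mismatch between setups, specular reflections, out-of-band
filter leakage, motion — are handled; the mapper deliberately models none of
these. Benchmark parity on synthetic cohorts shows the mapping preserves the
discriminative structure the generator put in; transfer to real tissue
contrast is a property of the real data, not of this package.

## Known limitations

- The source response is a pure Dirac model; finite source bandwidth is not
  convolved (appropriate only when source FWHM ≪ target FWHM).
- No spatial processing: spatial resolutions of the two systems are left
  untouched, and no PSF or registration is modelled.
- Out-of-band leakage, polarization and temperature drift of the tunable
  filters are out of scope, as is absolute radiometry.
- The annotation model assumes one class per labelled pixel and one
  white/dark reference set per capture.
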