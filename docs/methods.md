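# Methods

`phycoscope` quantifies the four overlapping photosynthetic pigment
emitters of *Synechocystis* sp. PCC 6803 — phycocyanin (PC), allophycocyanin
(APC), and chlorophyll *a* in photosystem II and photosystem I — in single
cells from hyperspectral confocal fluorescence image cubes, and implements
the companion bulk absorbance analysis. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic benchmark does and does not demonstrate.

## The measurement model

A hyperspectral frame is a cube `D(x, y, λ)` of fluorescence counts on a
calibrated emission wavelength axis (default 500–800 nm, 128 channels;
pixel pitch 0.12 µm, 210 × 210 pixels = 44,100 spectra per frame). Each
pixel spectrum is modelled as a non-negative linear mixture

    d ≈ Σ_j c_j s_j ,  c_j ≥ 0, s_j ≥ 0,

over six components: PC (~650 nm), APC (~662 nm), Chl–PSII (~685 nm),
Chl–PSI (~722 nm), a broad cellular autofluorescence band (~600 nm, strong
in dead cells), and a flat instrument offset. Spectra are kept at unit
Euclidean length; all scale lives in the abundances `c`.

## MCR-ALS (`phycoscope.mcr`)

The pure spectra are learned from the data by multivariate curve resolution:
alternating least squares on the pooled pixel × wavelength matrix of all
conditions, with non-negativity on both factors. Each half-step is an
exactly solved non-negative least squares problem. For k ≤ 12 components
the NNLS solver enumerates all passive sets and takes the feasible
candidate with the lowest objective, fully vectorised over pixels; this is
exactly optimal (the true solution's support is always among the candidate
sets) and is verified against `scipy.optimize.nnls` in the tests. Because
both half-steps are exact minimisations, the residual norm is
non-increasing; the iteration stops when its relative change falls below
`tol` (default 1e-6) or at `max_iter` (default 500). Non-convergence is
flagged in the provenance and the result still returned.

**Pixel selection.** MCR runs on pixels above background. Two automatic
criteria are provided: an Otsu threshold computed in the log domain (the
raw histogram is dominated by the dim background class, which skews a
linear-domain Otsu), and a background-statistics criterion
(median + z·MAD of the total-intensity image, z = 5). The pipeline pools
pixels with the latter: it keeps the dim partial-coverage pixels at cell
rims, where the offset dominates the spectrum, and without which the flat
offset component is poorly determined.

**Initialisation.** Purest-pixel (default): the first row seeds the flat
offset (it appears in every pixel, so no pure pixel exists for it); the
remaining rows are found by successive projections on unit-normalised pixel
spectra — normalisation makes the selection purity-driven rather than
brightness-driven — with each pick refined by averaging its most similar
pixels to suppress shot noise, and deflation by both the refined direction
and the picked pixel so no vertex is selected twice. A seeded random
initialisation is available as a fallback. If a component collapses during
ALS it is re-seeded from the worst-reconstructed pixel with its abundances
zeroed, which preserves residual monotonicity.

**Labelling and offset pinning.** With k = 6, components are labelled by
rules: lowest-variance row → offset; broadest remaining row → autofluorescence;
the four others → PC, APC, Chl–PSII, Chl–PSI by ascending peak wavelength.
Ties raise an ambiguity error naming both candidates. After labelling, the
pipeline replaces the offset row by an exactly flat unit spectrum
(`pin_offset`). This is necessary because the non-negative factorisation is
degenerate in the offset direction: subtracting α·s_pigment from the flat
row while adding a constant floor α·c_offset to that pigment's abundances
changes nothing in the fit while the row stays non-negative, and ALS
systematically drifts toward such "dented" offsets because the abundance
floor gives clamped noise more room. The dent translates into a constant
additive bias in the CLS maps — fatal for pigments measured near zero —
and restoring the known flat shape removes it.

**Diagnostics.** Variance explained is `1 − ‖D − C·S‖²_F / ‖D‖²_F`
(uncentred, clipped to [0, 1]); on default synthetic scenes the
six-component model explains ≥ 99.9 %.

## CLS unmixing (`phycoscope.cls`)

With the spectral model fixed, per-pixel abundances are ordinary least
squares through the pseudoinverse of `S` — deterministic, linear in the
data, and exact on noiseless mixtures. Non-negativity clamping is available
behind a flag but off by default: constrained estimates are biased upward
for components near zero, and the per-cell statistics need unbiased means
more than they need sign-clean single pixels. A rank check rejects
collinear models, naming the most collinear component pair. Overlays render
red = Chl–PSI, green = Chl–PSII, blue = PC + APC, linearly scaled by
per-channel maxima shared across the whole comparison set so that colors
are comparable between conditions.

## Segmentation and QC (`phycoscope.segmentation`)

Cells are segmented from the summed four-pigment abundance image:
log-domain Otsu foreground threshold on the raw image (thresholding a
smoothed image would dilate the foreground by the blur halo), Euclidean
distance transform smoothed by `smoothing_sigma` (default 1 px), h-maxima
markers (`h_depth`, default 2 px), marker-controlled watershed, then an
area filter (0.8–10 µm²) and consecutive relabelling.

Dead, dying or severely compromised cells are flagged by population-outlier
rules computed per condition (not pooled): autofluorescence above the
population mean + 3 SD, or PC above 3× the population mean. The statistics
include the candidate cells themselves; populations under 3 cells skip
flagging with a warning; a zero SD flags nothing; and the PC fold rule is
applied only when the population mean is positive (a near-zero PC
population can average slightly negative under unconstrained CLS, which
would otherwise flag every cell). Flags are recorded, not deleted —
exclusion happens in the statistics layer.

## Per-cell statistics (`phycoscope.cellstats`)

Per-cell abundance is the *mean* of a component's map over the cell's
pixels, making it independent of cell area. Population summaries report
mean, SD and SE = SD/√n per component, excluding flagged cells.
Percent-of-original divides a condition's mean by its own arm's t = 0 mean
(×100) with first-order delta-method propagation of the two SEs — the
"±" we report is this propagated SE, stated explicitly since printed
tables rarely say which uncertainty they carry. Pigment ratios are ratios
of population means, optionally normalised by the same ratio in a control
population. Scatter exports provide per-cell (x, y) tables after QC.

## Bulk absorbance (`phycoscope.bulk`)

Spectra (400–800 nm) are blank-corrected against cell-free medium and read
at the nearest grid channel to each named wavelength (plate-reader grids
are instrument-specific; at 1 nm spacing the nearest-channel error is
negligible). Pigment concentrations use the classical two-point equations —
phycobilin `0.139(A620−A730) − 0.0355(A678−A730)` mg/mL, chlorophyll
`14.96(A678−A730) − 0.616(A625−A730)` µg/mL — exactly as printed, including
the A620/A625 asymmetry between them; negative results are flagged, not
clipped. Molarity uses molar masses 586.67802 g/mol (phycobilin) and
893.48898 g/mol (chlorophyll *a*); per-cell content divides by A730, the
standard cell-number proxy; fold changes are reported with direction labels.

## The synthetic benchmark (`phycoscope.synthetic`)

The generator emulates the study conditions end to end with known ground
truth. Defaults are the study conditions, not tuning knobs:

- **Conditions.** Seven populations (0/24/48 h ±N, 24 h replete). Per-cell
  mean multipliers relative to the t = 0 +N control: the 24 h −N population
  holds the measured depletion fractions (PC 0.03, APC 0.09, Chl–PSII 0.38,
  Chl–PSI 0.43) and the replete population the repletion fractions
  (0.88, 0.87, 0.95, 0.80); +N controls drift up ×1.3/×1.7 over 24/48 h
  (self-shading); t = 0 −N equals the control (sampled minutes after the
  medium swap). Between-cell abundances are log-normal with CV 0.25 (only
  SEs are published; log-normal is the standard positive-support choice).
- **Cells.** Disks of diameter 1.5–2.5 µm on a 0.12 µm grid; a peripheral
  annulus (outer 30 % of the radius) carries 80 % of the pigment mass
  (thylakoid membranes); 0–3 punctate foci 0.5–0.7 µm wide; per-pigment
  membrane patches and independent per-pixel log-normal jitter (sd 0.5)
  model the PSI-rich/PSII-rich patches and pixel-scale heterogeneity seen
  in real frames; the outermost ~1 px ramps to zero (partial pixel coverage
  at a diffraction-limited edge — no optical PSF is simulated).
  Autofluorescence is uniform per cell with mild jitter; the offset
  (300 counts, EMCCD bias scale) covers the whole frame. Per-cell means are
  renormalised after all modulation, so the truth table is exact.
- **Compromised cells.** 5 % of cells, exactly realised, in two kinds:
  dead (autofluorescence ×10, pigments ×0.05 — cells that are mostly
  breakdown-product fluorescence) and dying (PC/APC ×4, autofluorescence ×2
  — cells that lost energy transfer to the reaction centres). Both trip the
  QC rules; the dead kind also supplies the autofluorescence-dominated
  pixels that make that component identifiable.
- **Noise.** Poisson shot noise on counts. The photon budget (control-cell
  mean abundances 3000/2600/2000/1800/300 count units) gives bright
  thylakoid pixels peak channel counts in the low thousands; at this budget
  the six-component model explains ≥ 99.9 % of the variance.
- **Bulk spectra.** A flat medium blank, a gentle scattering baseline
  anchored at the target OD730, and phycobilin (625 nm) / chlorophyll
  (678 nm red + 435 nm Soret) bands whose amplitudes are solved from the
  concentration equations so the injected per-OD contents are recovered
  exactly before noise (Gaussian, sd 5e-4 AU). Injected kinetics:
  phycobilin per OD falls 6.5-fold over 24 h −N and rises 12-fold on
  repletion; chlorophyll falls 1.8-fold and rises 2.4-fold.

**What passing tests show — and don't.** The generator produces ideal
linear mixtures of its own reference spectra with pure Poisson noise. Real
cubes add detector read noise and gain structure, wavelength-calibration
drift, out-of-focus light, touching and overlapping cells, and emitters not
in the model; the published line shapes are not available, so the skewed-
Gaussian bands (PC 650/13/18, APC 662/12/20, Chl–PSII 685/11/25, Chl–PSI
722/18/30, autofluorescence 600/65/75 nm peak/left-σ/right-σ) reproduce
peak order and overlap, not true shapes. Recovery results on the benchmark
therefore demonstrate the correctness and internal consistency of the
algorithms, not instrument-level performance. Blind MCR on these scenes is
identifiable because cells exhibit pixel-scale compositional diversity and
because dead cells and cell rims expose the autofluorescence and offset
directions; on data without such diversity the rotational ambiguity of
non-negative factorisation returns, and a fixed published spectral model
with CLS alone would be the right tool.

**Measured accuracy at the defaults.** With 20-cell scenes the pipeline's
percent-of-original estimates track the configured depletion fractions to
within a few points per run; seed-to-seed scatter is dominated by the
20-cell sampling of a CV-0.25 population. Mean PC at 3 % of original sits
near the noise floor; its slight under-estimation after unmixing makes the
control-normalised APC/PC ratio read high (≈3.5–4.5 against the configured
3.0) — the benchmark reports what the pipeline measures, not the configured
value.

## Determinism

Every stochastic step takes an explicit seed (`numpy.random.Generator`
discipline; per-condition streams derived via CRC-based keys so results are
stable across processes). Identical seeds and configuration yield
bit-identical cubes, CSV outputs and manifests; cube writers emit
byte-identical files (`track_times=False` for HDF5).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the same code paths at sizes
chosen to exercise them fully: 28-cell frames across all seven conditions
(~200 cells) for the joint-model fit, five independent 20-cell runs of the
depleted arm for the percent-of-original table, and 10,000-cell draws for
distributional checks.
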