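# phycoscope

Single-cell hyperspectral pigment analysis for cyanobacteria.

Nitrogen-starved cyanobacteria dismantle their phycobilisome (PBS) antenna —
phycocyanin (PC) rods first, then the allophycocyanin (APC) core — while
chlorophyll bound to the two photosystems declines more slowly. Bulk
absorbance can only report culture averages of this process; hyperspectral
confocal fluorescence microscopy (HCFM) records a full emission spectrum in
every pixel and makes the degradation quantifiable cell by cell, if the four
heavily overlapping emitters (PC ~650 nm, APC ~662 nm, Chl–PSII ~685 nm,
Chl–PSI ~722 nm) can be unmixed. `phycoscope` implements that analysis as a
tested, reusable Python package for *Synechocystis* sp. PCC 6803-style data:

- **`synthetic`** — a ground-truth-annotated scene generator emulating the
  seven study conditions (0/24/48 h ±N and 24 h repletion): disk-shaped
  cells with a thylakoid annulus, punctate foci, pigment patches, dead/dying
  cells, Poisson shot noise; plus matching bulk absorbance spectra.
- **`mcr`** — multivariate curve resolution by alternating least squares
  (MCR-ALS) with non-negativity on both factors: `D ≈ C·Sᵀ`, `C, S ≥ 0`,
  rows of `S` unit length. A scikit-learn style estimator (`MCRALS`) with
  purest-pixel initialisation, exact batched NNLS half-steps, variance
  explained diagnostics, and rule-based component labelling.
- **`cls`** — classical least squares unmixing (`CLSUnmixer`) of cubes
  against a fixed spectral model, concentration maps, pseudocolor overlays
  (red Chl–PSI, green Chl–PSII, blue PC+APC) on a shared color scale.
- **`segmentation`** — marker-controlled watershed on the total-pigment
  image plus the population-outlier QC rules for dead/dying cells
  (autofluorescence > mean + 3 SD, or PC > 3× the population mean).
- **`cellstats`** — per-cell abundances, population means ± standard error,
  percent-of-original tables with delta-method uncertainty, pigment ratios,
  scatter exports.
- **`bulk`** — absorbance workflow: blank correction, A730 normalization,
  phycobilin `0.139(A620−A730) − 0.0355(A678−A730)` mg/mL and chlorophyll
  `14.96(A678−A730) − 0.616(A625−A730)` µg/mL, molarity conversion,
  per-OD730 content and fold changes.
- **`pipeline` / CLI** — `phycoscope run-all` orchestrates
  generate → joint MCR → CLS → segment → quantify → report with a manifest.

## Worked example

```python
import numpy as np
import pandas as pd
import phycoscope as pp
from phycoscope.mcr import MCRALS, background_mask, identify_components, pin_offset
from phycoscope.cls import CLSUnmixer
from phycoscope.segmentation import segment_cells, flag_compromised_cells
from phycoscope.cellstats import (per_cell_abundance, summarize_population,
                                  percent_of_initial)

ref = pp.make_reference_spectra()
conds = ("T0-N", "T24-N")
scenes = {c: pp.simulate_scene(c, n_cells=20, seed=3, reference=ref) for c in conds}

# joint MCR on all above-background pixels
X = np.vstack([cube.pixel_matrix()[background_mask(cube, method="background").ravel()]
               for cube, _ in scenes.values()])
est = MCRALS(n_components=6).fit(X)
model = pin_offset(identify_components(est.to_model(ref.wavelengths)))
print(f"variance explained: {est.variance_explained_:.4f}")

# unmix, segment, quantify
unmixer = CLSUnmixer().fit(model)
records = []
for cond, (cube, _) in scenes.items():
    maps = unmixer.unmix_cube(cube)
    records.append(per_cell_abundance(maps, segment_cells(maps), condition=cond))
cells = flag_compromised_cells(pd.concat(records, ignore_index=True))
summ = {c: summarize_population(cells[cells.condition == c], components=pp.PIGMENTS)
        for c in conds}
print(percent_of_initial(summ["T24-N"], summ["T0-N"]).round(1))
```

Output:

```
variance explained: 0.9994
          percent  se_percent
PC            2.3         0.2
APC           8.5         0.8
Chl-PSII     41.9         3.8
Chl-PSI      44.1         4.5
```

Six components (four pigments, broad autofluorescence, flat instrument
offset) explain 99.94 % of the pooled spectral variance. The
percent-of-original table is read against the nitrogen-depleted arm's own
t = 0 population: after 24 h without nitrogen these 20-cell scenes retain
~2 % of their PC and ~9 % of their APC — the rods go before the core —
while both chlorophyll pools keep roughly 40 % (single-scene numbers
scatter around the generator's configured 3/9/38/43 % by a few points;
averaging seeds converges on them). The `± ` column is the delta-method
standard error propagated from the two population SEs.

The same analysis, for all seven conditions with overlays, label images, QC
and bulk reports, is one command:

```bash
phycoscope run-all --seed 1 --out runs/demo
```

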