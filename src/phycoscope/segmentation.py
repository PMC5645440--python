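"""Watershed cell segmentation and compromised-cell QC flagging.

Cells are segmented from the summed pigment abundance image: Gaussian
smoothing, Otsu foreground threshold, Euclidean distance transform,
h-maxima markers, then marker-controlled watershed to split touching
cells, followed by an area filter.  Dead, dying or severely compromised
cells are flagged by the population-outlier rules used for single-cell QC:
autofluorescence more than z standard deviations (default 3) above the
population mean, or PC content more than a fold-threshold (default 3×)
above the population mean.  Flagged cells stay in the table; exclusion
happens downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import relabel_sequential, watershed

from .cls import ConcentrationMaps

__all__ = ["QcCriteria", "segment_cells", "flag_compromised_cells"]


@dataclass(frozen=True)
class QcCriteria:
    """Thresholds for dead/dying/compromised-cell flagging and cell size."""

    autofluorescence_z: float = 3.0  # SD above population mean
    pc_fold: float = 3.0  # × population mean PC
    min_area_um2: float = 0.8
    max_area_um2: float = 10.0

    def __post_init__(self) -> None:
        if self.autofluorescence_z <= 0 or self.pc_fold <= 0:
            raise ValueError("QC thresholds must be positive")


def segment_cells(
    maps: ConcentrationMaps,
    smoothing_sigma: float = 1.0,
    h_depth: float = 2.0,
    criteria: QcCriteria | None = None,
) -> np.ndarray:
    """Label individual cells in a set of concentration maps.

    Returns an int32 label image (0 = background, labels consecutive).
    *smoothing_sigma* (pixels) smooths the total-pigment image before
    thresholding; *h_depth* (pixels) is the h-maxima depth used to seed
    one marker per cell on the distance transform.
    """
    criteria = criteria or QcCriteria()
    total = maps.total_pigment()
    if np.ptp(total) == 0:
        warnings.warn("empty foreground; no cells segmented")
        return np.zeros(total.shape, dtype=np.int32)
    # Threshold the raw image (smoothing first would dilate the foreground
    # with a blur halo); Otsu in the log domain because cell brightness
    # spans orders of magnitude (dim starved cells next to very bright
    # dying ones), which skews a linear-domain threshold.
    log_total = np.log1p(np.clip(total, 0.0, None))
    foreground = total > np.expm1(threshold_otsu(log_total))
    if not foreground.any():
        warnings.warn("empty foreground; no cells segmented")
        return np.zeros(total.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(foreground)
    distance = gaussian(distance, sigma=max(smoothing_sigma, 1e-6), preserve_range=True)
    peaks = h_maxima(distance, h_depth)
    markers, _ = ndi.label(peaks)
    labels = watershed(-distance, markers, mask=foreground)

    # Area filter in µm².
    px_area = maps.pixel_size**2
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    bad = ids[
        (counts * px_area < criteria.min_area_um2)
        | (counts * px_area > criteria.max_area_um2)
    ]
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def flag_compromised_cells(
    cell_table: pd.DataFrame,
    criteria: QcCriteria | None = None,
    population_col: str | None = "condition",
) -> pd.DataFrame:
    """Flag dead/dying/compromised cells by population-outlier rules.

    A cell is flagged iff its autofluorescence exceeds the population mean
    by more than ``autofluorescence_z`` standard deviations, or its PC
    abundance exceeds ``pc_fold`` times the population mean.  Statistics
    are computed on the cell's own condition population (all cells,
    candidates included) when *population_col* is present; populations of
    fewer than 3 cells are skipped with a warning (SD undefined).  A zero
    population SD never produces autofluorescence flags.

    Returns a copy of the table with ``qc_flag`` and ``qc_reason`` columns;
    flagging is idempotent and order-independent.
    """
    criteria = criteria or QcCriteria()
    out = cell_table.copy()
    out["qc_flag"] = False
    out["qc_reason"] = ""

    if population_col is not None and population_col in out.columns:
        groups = [g for _, g in out.groupby(population_col, sort=False)]
    else:
        groups = [out]

    for group in groups:
        idx = group.index
        if len(group) < 3:
            warnings.warn(
                "population of fewer than 3 cells; QC flagging skipped"
            )
            continue
        af = group["autofluorescence"].to_numpy(dtype=float)
        pc = group["PC"].to_numpy(dtype=float)
        af_mean, af_sd = af.mean(), af.std(ddof=1)
        pc_mean = pc.mean()

        af_flag = (af_sd > 0) & (af > af_mean + criteria.autofluorescence_z * af_sd)
        # The fold rule needs a meaningful (positive) population mean;
        # near-zero PC populations can average slightly negative after
        # unconstrained CLS, which would otherwise flag every cell.
        pc_flag = (pc > criteria.pc_fold * pc_mean) if pc_mean > 0 else np.zeros_like(af_flag)
        reasons = np.select(
            [af_flag & pc_flag, af_flag, pc_flag],
            ["autofluorescence+PC", "autofluorescence", "PC"],
            default="",
        )
        out.loc[idx, "qc_flag"] = af_flag | pc_flag
        out.loc[idx, "qc_reason"] = reasons
    return out
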