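"""Per-cell pigment abundances and population statistics.

Per-cell abundance is the mean of a component's concentration map over the
cell's pixels (area-independent by construction).  Population summaries
carry the mean, SD and standard error (SD/√n) per component;
percent-of-original tables compare a condition to its own arm's t = 0
population with first-order (delta-method) uncertainty propagation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cls import ConcentrationMaps
from .spectra import PIGMENTS

__all__ = [
    "per_cell_abundance",
    "summarize_population",
    "percent_of_initial",
    "pigment_ratio",
    "scatter_export",
]


def per_cell_abundance(
    maps: ConcentrationMaps,
    labels: np.ndarray,
    condition: str | None = None,
    expected_labels=None,
) -> pd.DataFrame:
    """One record per labelled cell: area (µm²) and mean abundance per component.

    *expected_labels*, when given, is checked against the label image;
    missing labels are skipped with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.data.shape[:2]:
        raise ValueError("label image and maps are not spatially aligned")
    present = np.unique(labels[labels > 0])
    if expected_labels is not None:
        missing = sorted(set(expected_labels) - set(present.tolist()))
        if missing:
            warnings.warn(f"labels absent from image, skipped: {missing}")
    if present.size == 0:
        cols = ["cell_id", "condition", "area_um2", *maps.labels]
        return pd.DataFrame(columns=cols)

    px_area = maps.pixel_size**2
    areas = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, present)
    table = {
        "cell_id": present,
        "condition": condition,
        "area_um2": areas * px_area,
    }
    for name in maps.labels:
        table[name] = ndi.mean(maps.get(name), labels, present)
    return pd.DataFrame(table)


def summarize_population(
    records: pd.DataFrame,
    components=None,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Population mean, SD and standard error per component.

    Flagged (dead/dying/compromised) cells are excluded by default.
    Returns a DataFrame indexed by component with columns
    ``n, mean, sd, se``.
    """
    if exclude_flagged and "qc_flag" in records.columns:
        records = records[~records["qc_flag"].astype(bool)]
    if len(records) < 1:
        raise ValueError("population summary needs at least one cell")
    components = list(components) if components is not None else [
        c for c in records.columns if c in set(PIGMENTS) | {"autofluorescence", "offset"}
    ]
    rows = {}
    n = len(records)
    for name in components:
        values = records[name].to_numpy(dtype=float)
        sd = values.std(ddof=1) if n > 1 else 0.0
        rows[name] = {"n": n, "mean": values.mean(), "sd": sd, "se": sd / np.sqrt(n)}
    return pd.DataFrame(rows).T[["n", "mean", "sd", "se"]]


def percent_of_initial(
    summary_t: pd.DataFrame, summary_t0: pd.DataFrame
) -> pd.DataFrame:
    """Percent of original abundance per component, with propagated SE.

    ``percent = 100 · mean_t / mean_t0``; the uncertainty combines the two
    standard errors to first order:
    ``se% = percent · sqrt((se_t/mean_t)² + (se_t0/mean_t0)²)``.
    """
    shared = [c for c in summary_t.index if c in summary_t0.index]
    if not shared:
        raise ValueError("summaries share no component labels")
    rows = {}
    for name in shared:
        m_t, se_t = summary_t.loc[name, "mean"], summary_t.loc[name, "se"]
        m_0, se_0 = summary_t0.loc[name, "mean"], summary_t0.loc[name, "se"]
        if m_0 == 0:
            raise ValueError(f"zero t0 mean for {name}; percent undefined")
        percent = 100.0 * m_t / m_0
        if m_t == 0:
            se = 100.0 * se_t / m_0
        else:
            se = abs(percent) * np.sqrt((se_t / m_t) ** 2 + (se_0 / m_0) ** 2)
        rows[name] = {"percent": percent, "se_percent": se}
    return pd.DataFrame(rows).T[["percent", "se_percent"]]


def pigment_ratio(
    summary: pd.DataFrame,
    numerator: str,
    denominator: str,
    control_summary: pd.DataFrame | None = None,
) -> float:
    """Ratio of population mean abundances, optionally control-normalized.

    With *control_summary* given, the condition's ratio is divided by the
    control population's ratio of the same two components.
    """
    for name in (numerator, denominator):
        if name not in summary.index:
            raise ValueError(f"component {name!r} missing from summary")
    den = summary.loc[denominator, "mean"]
    if den == 0:
        raise ValueError(f"zero denominator mean for {denominator!r}")
    ratio = summary.loc[numerator, "mean"] / den
    if control_summary is not None:
        ratio /= pigment_ratio(control_summary, numerator, denominator)
    return float(ratio)


def scatter_export(
    records: pd.DataFrame,
    x_component: str,
    y_component: str,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Per-cell (x, y) abundance table for scatter comparisons."""
    for name in (x_component, y_component):
        if name not in records.columns:
            raise ValueError(f"component {name!r} missing from records")
    out = records
    if exclude_flagged and "qc_flag" in out.columns:
        out = out[~out["qc_flag"].astype(bool)]
    cols = {}
    if "condition" in out.columns:
        cols["condition"] = out["condition"]
    if "cell_id" in out.columns:
        cols["cell_id"] = out["cell_id"]
    cols["x"] = out[x_component]
    cols["y"] = out[y_component]
    return pd.DataFrame(cols).reset_index(drop=True)
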