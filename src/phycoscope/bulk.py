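"""Bulk absorbance pigment quantification.

Implements the standard absorbance workflow for cyanobacterial cultures:
blank correction against cell-free medium, A730 normalization for display,
phycobilin and chlorophyll *a* concentrations from the classical two-point
equations

    phycobilin  [mg/mL] = 0.139·(A620 − A730) − 0.0355·(A678 − A730)
    chlorophyll [µg/mL] = 14.96·(A678 − A730) − 0.616·(A625 − A730)

molarity conversion via the pigment molar masses, per-OD730 content (OD730
as the cell-number proxy) and fold changes between conditions.  Absorbance
values at named wavelengths are taken from the nearest grid channel; the
phycobilin equation uses A620 while the chlorophyll equation uses A625,
exactly as the equations are conventionally printed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHYCOBILIN_MOLAR_MASS",
    "CHLOROPHYLL_MOLAR_MASS",
    "AbsorbanceSpectrum",
    "blank_correct",
    "normalize_a730",
    "phycobilin_concentration",
    "chlorophyll_concentration",
    "to_molar",
    "per_od_content",
    "fold_change",
    "pigment_report",
]

PHYCOBILIN_MOLAR_MASS = 586.67802  # g/mol
CHLOROPHYLL_MOLAR_MASS = 893.48898  # g/mol


@dataclass
class AbsorbanceSpectrum:
    """Bulk absorbance vs wavelength (nm), optionally blank-corrected."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths[0] > 620 or self.wavelengths[-1] < 730:
            raise ValueError("spectrum must cover at least 620–730 nm")

    def at(self, wavelength: float) -> float:
        """Absorbance at the grid channel nearest *wavelength*."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.absorbance[idx])


def blank_correct(sample: AbsorbanceSpectrum, blank: AbsorbanceSpectrum) -> AbsorbanceSpectrum:
    """Subtract the cell-free medium blank pointwise."""
    if not np.array_equal(sample.wavelengths, blank.wavelengths):
        raise ValueError("sample and blank wavelength grids differ")
    return AbsorbanceSpectrum(
        sample.wavelengths.copy(),
        sample.absorbance - blank.absorbance,
        blank_corrected=True,
    )


def normalize_a730(spectrum: AbsorbanceSpectrum) -> AbsorbanceSpectrum:
    """Divide the spectrum by its value at 730 nm (nearest channel)."""
    a730 = spectrum.at(730.0)
    if a730 <= 0:
        raise ValueError(f"A730 must be positive to normalize (got {a730})")
    return AbsorbanceSpectrum(
        spectrum.wavelengths.copy(),
        spectrum.absorbance / a730,
        blank_corrected=spectrum.blank_corrected,
    )


def _warn_if_negative(value: float, what: str) -> float:
    if value < 0:
        warnings.warn(f"negative {what} ({value:.4g}); check blanks/baseline")
    return value


def phycobilin_concentration(a620: float, a678: float, a730: float = 0.0) -> float:
    """Phycobilin mass concentration in mg/mL from blank-corrected absorbances."""
    value = 0.139 * (a620 - a730) - 0.0355 * (a678 - a730)
    return _warn_if_negative(value, "phycobilin concentration")


def chlorophyll_concentration(a678: float, a625: float, a730: float = 0.0) -> float:
    """Chlorophyll *a* mass concentration in µg/mL from blank-corrected absorbances."""
    value = 14.96 * (a678 - a730) - 0.616 * (a625 - a730)
    return _warn_if_negative(value, "chlorophyll concentration")


def to_molar(mass_concentration: float, pigment: str) -> float:
    """Convert a mass concentration to millimolar.

    Phycobilin concentrations are in mg/mL (= g/L) and chlorophyll in µg/mL
    (= mg/L), matching the units of the two concentration equations.
    """
    if pigment == "phycobilin":
        grams_per_liter = mass_concentration
        molar_mass = PHYCOBILIN_MOLAR_MASS
    elif pigment == "chlorophyll":
        grams_per_liter = mass_concentration / 1000.0
        molar_mass = CHLOROPHYLL_MOLAR_MASS
    else:
        raise ValueError(f"unknown pigment {pigment!r}")
    return grams_per_liter / molar_mass * 1000.0  # mol/L -> mmol/L


def per_od_content(concentration: float, a730: float) -> float:
    """Concentration per OD730 (per-cell proxy)."""
    if a730 <= 0:
        raise ValueError(f"A730 must be positive (got {a730})")
    return concentration / a730


def fold_change(value_a: float, value_b: float) -> float:
    """value_a / value_b; > 1 is an increase, < 1 a 1/N-fold decrease."""
    if value_b == 0:
        raise ValueError("fold change undefined for zero reference value")
    return value_a / value_b


def describe_fold(fold: float) -> str:
    """Human-readable direction label for a fold change."""
    if fold >= 1:
        return f"{fold:.2g}-fold increase"
    return f"{1.0 / fold:.2g}-fold decrease"


def pigment_report(
    spectra: dict[str, AbsorbanceSpectrum],
    blank: AbsorbanceSpectrum,
    reference: str | None = None,
) -> pd.DataFrame:
    """Full per-sample pigment report from raw spectra plus a medium blank.

    Columns: key absorbances, mass concentrations, millimolar values,
    per-OD730 contents, phycobilin:chlorophyll ratio, and (when *reference*
    names one of the samples) per-OD fold changes versus that sample.
    """
    rows = []
    for name, spec in spectra.items():
        corr = spec if spec.blank_corrected else blank_correct(spec, blank)
        a620, a625, a678, a730 = (corr.at(w) for w in (620.0, 625.0, 678.0, 730.0))
        phyc = phycobilin_concentration(a620, a678, a730)
        chl = chlorophyll_concentration(a678, a625, a730)
        rows.append(
            {
                "sample": name,
                "A620": a620,
                "A625": a625,
                "A678": a678,
                "A730": a730,
                "phycobilin_mg_ml": phyc,
                "chlorophyll_ug_ml": chl,
                "phycobilin_mM": to_molar(phyc, "phycobilin"),
                "chlorophyll_mM": to_molar(chl, "chlorophyll"),
                "phycobilin_per_od": per_od_content(phyc, a730),
                "chlorophyll_per_od": per_od_content(chl, a730),
            }
        )
    df = pd.DataFrame(rows).set_index("sample")
    df["phycobilin_chl_ratio_per_od"] = (
        df["phycobilin_mM"] / df["chlorophyll_mM"]
    )
    if reference is not None:
        for col in ("phycobilin_per_od", "chlorophyll_per_od"):
            df[f"{col}_fold_vs_{reference}"] = df[col] / df.loc[reference, col]
    return df
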