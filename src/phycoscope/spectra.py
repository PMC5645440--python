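"""Reference emission spectra for the six-component spectral model.

The model comprises the four overlapping photosynthetic pigment emitters of
*Synechocystis* sp. PCC 6803 — phycocyanin (PC, ~650 nm), allophycocyanin
(APC, ~662 nm), chlorophyll *a* in photosystem II (~685 nm) and in
photosystem I (~722 nm) — plus a broad cellular autofluorescence band
(~600 nm) and a flat instrument offset.  Published line shapes are not
available, so each band is modelled as a two-sided (skewed) Gaussian whose
peak position and widths are configurable; only peak ordering and
separability matter downstream.  All spectra are non-negative and normalised
to unit Euclidean length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COMPONENTS",
    "PIGMENTS",
    "ReferenceSpectra",
    "default_wavelengths",
    "make_reference_spectra",
]

#: Canonical component order used throughout the package.
COMPONENTS: tuple[str, ...] = (
    "PC",
    "APC",
    "Chl-PSII",
    "Chl-PSI",
    "autofluorescence",
    "offset",
)

#: The four photosynthetic pigment components, in ascending peak order.
PIGMENTS: tuple[str, ...] = COMPONENTS[:4]

# (peak nm, left sigma nm, right sigma nm) for each band component.
_BAND_PARAMS: dict[str, tuple[float, float, float]] = {
    "PC": (650.0, 13.0, 18.0),
    "APC": (662.0, 12.0, 20.0),
    "Chl-PSII": (685.0, 11.0, 25.0),
    "Chl-PSI": (722.0, 18.0, 30.0),
    "autofluorescence": (600.0, 65.0, 75.0),
}


def default_wavelengths(n_channels: int = 128) -> np.ndarray:
    """Default emission wavelength grid: 500–800 nm, 128 channels."""
    return np.linspace(500.0, 800.0, n_channels)


def _skewed_gaussian(
    wavelengths: np.ndarray, peak: float, sigma_left: float, sigma_right: float
) -> np.ndarray:
    sigma = np.where(wavelengths < peak, sigma_left, sigma_right)
    return np.exp(-0.5 * ((wavelengths - peak) / sigma) ** 2)


@dataclass
class ReferenceSpectra:
    """Unit-length pure component emission spectra on a common grid."""

    wavelengths: np.ndarray
    spectra: np.ndarray  # (k, channels), rows unit L2 norm
    labels: tuple[str, ...] = COMPONENTS

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (len(self.labels), self.wavelengths.size):
            raise ValueError("spectra shape must be (n_labels, n_wavelengths)")
        if np.any(self.spectra < 0):
            raise ValueError("reference spectra must be non-negative")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.spectra[self.labels.index(label)]

    def peak_wavelength(self, label: str) -> float:
        return float(self.wavelengths[int(np.argmax(self[label]))])


def make_reference_spectra(
    wavelengths: np.ndarray | None = None,
    band_params: dict[str, tuple[float, float, float]] | None = None,
) -> ReferenceSpectra:
    """Build the six-component reference model on *wavelengths*.

    The grid must be strictly increasing, span at least 600–750 nm and have
    at least 16 channels.  Band shapes may be overridden through
    *band_params* (``label -> (peak, sigma_left, sigma_right)``).
    """
    if wavelengths is None:
        wavelengths = default_wavelengths()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size < 16:
        raise ValueError("wavelength grid too coarse: need at least 16 channels")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if wavelengths[0] > 600.0 or wavelengths[-1] < 750.0:
        raise ValueError("wavelength grid must span at least 600–750 nm")

    params = dict(_BAND_PARAMS)
    if band_params:
        params.update(band_params)

    rows = []
    for label in COMPONENTS:
        if label == "offset":
            row = np.ones_like(wavelengths)
        else:
            row = _skewed_gaussian(wavelengths, *params[label])
        rows.append(row / np.linalg.norm(row))
    return ReferenceSpectra(wavelengths, np.vstack(rows))
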