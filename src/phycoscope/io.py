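"""Hyperspectral cube containers and I/O.

A :class:`SpectralCube` holds fluorescence counts indexed ``(row, col,
channel)`` together with a calibrated wavelength axis in nanometres and the
lateral pixel size in micrometres.  Two on-disk containers are supported:

* multi-page TIFF (one page per wavelength channel) with a JSON sidecar
  ``<stem>.json`` holding ``wavelengths_nm`` and ``pixel_size_um``;
* HDF5 with datasets ``/cube`` and ``/wavelengths_nm`` and a root attribute
  ``pixel_size_um``.

Pixel indices are row-major and 0-based with ``(0, 0)`` at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = ["SpectralCube", "CubeFormatError", "read_cube", "write_cube"]


class CubeFormatError(ValueError):
    """Raised when an on-disk cube violates the container contract."""


@dataclass
class SpectralCube:
    """Counts cube ``(rows, cols, channels)`` with a wavelength axis in nm."""

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_size: float = 0.12  # µm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, channels)")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise CubeFormatError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"channel count {self.data.shape[2]}"
            )
        if self.wavelengths.size < 2:
            raise CubeFormatError("a cube needs at least two spectral channels")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise CubeFormatError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_spectra(self) -> int:
        """Number of per-pixel spectra in the frame (rows × cols)."""
        return self.data.shape[0] * self.data.shape[1]

    def pixel_matrix(self) -> np.ndarray:
        """Flatten to an ``(n_pixels, channels)`` matrix (row-major order)."""
        return self.data.reshape(-1, self.data.shape[2])

    def saturated_mask(self, ceiling: float) -> np.ndarray:
        """Boolean image of pixels with any channel at or above *ceiling*.

        Saturation is flagged, never clipped.
        """
        return np.any(self.data >= ceiling, axis=2)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(cube: SpectralCube, path: str | Path, format: str = "tiff") -> Path:
    """Write *cube* to *path* in ``"tiff"`` or ``"h5"`` format.

    Returns the path written.  Writing is deterministic: the same cube
    always produces byte-identical payload pages.
    """
    path = Path(path)
    if format == "tiff":
        pages = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0))
        tifffile.imwrite(path, pages, photometric="minisblack")
        meta = {
            "wavelengths_nm": [float(w) for w in cube.wavelengths],
            "pixel_size_um": float(cube.pixel_size),
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif format == "h5":
        with h5py.File(path, "w") as fh:
            # track_times=False keeps writes byte-deterministic
            fh.create_dataset("cube", data=cube.data, track_times=False)
            fh.create_dataset(
                "wavelengths_nm", data=cube.wavelengths, track_times=False
            )
            fh.attrs["pixel_size_um"] = float(cube.pixel_size)
    else:
        raise ValueError(f"unknown cube format {format!r} (use 'tiff' or 'h5')")
    return path


def read_cube(path: str | Path, format: str | None = None) -> SpectralCube:
    """Read a cube written by :func:`write_cube`.

    *format* is inferred from the suffix when omitted.  Raises
    :class:`CubeFormatError` on a missing or non-monotone wavelength axis or
    on a channel-count mismatch between payload and metadata.
    """
    path = Path(path)
    if format is None:
        format = "h5" if path.suffix in {".h5", ".hdf5"} else "tiff"
    if format == "tiff":
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise CubeFormatError(f"missing wavelength sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
        if wavelengths.size != pages.shape[0]:
            raise CubeFormatError(
                f"sidecar lists {wavelengths.size} wavelengths for a "
                f"{pages.shape[0]}-page TIFF"
            )
        data = np.moveaxis(pages, 0, 2)
        return SpectralCube(data, wavelengths, float(meta.get("pixel_size_um", 0.12)))
    if format == "h5":
        with h5py.File(path, "r") as fh:
            data = fh["cube"][()]
            if "wavelengths_nm" not in fh:
                raise CubeFormatError("HDF5 cube lacks /wavelengths_nm dataset")
            wavelengths = fh["wavelengths_nm"][()]
            pixel_size = float(fh.attrs.get("pixel_size_um", 0.12))
        return SpectralCube(data, wavelengths, pixel_size)
    raise ValueError(f"unknown cube format {format!r}")
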