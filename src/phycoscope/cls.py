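"""Classical least squares (CLS) unmixing against a fixed spectral model.

Each pixel spectrum ``d`` is decomposed as ``d ≈ S^T c`` where the rows of
``S`` are the pure component spectra from MCR; the abundances ``c`` solve
the ordinary least-squares problem per pixel (via the pseudoinverse of
``S``), optionally clamped non-negative.  Unconstrained CLS is the default:
non-negativity belongs to the MCR model-building step, while CLS is a plain
linear projection, so it is exactly linear in the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import SpectralCube
from .mcr import SpectralModel
from .nnls import nnls_multiple
from .spectra import PIGMENTS

__all__ = [
    "ConcentrationMaps",
    "CLSUnmixer",
    "cls_unmix",
    "render_overlay",
    "shared_scale",
]


@dataclass
class ConcentrationMaps:
    """Per-pixel component abundance images from CLS."""

    data: np.ndarray  # (rows, cols, k)
    labels: tuple[str, ...]
    pixel_size: float = 0.12
    model_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.labels):
            raise ValueError("maps must be (rows, cols, k) with one label per plane")

    def get(self, label: str) -> np.ndarray:
        return self.data[:, :, self.labels.index(label)]

    def total_pigment(self) -> np.ndarray:
        """Summed abundance of the four pigment components."""
        return sum(self.get(name) for name in PIGMENTS)

    def save(self, path: str | Path) -> None:
        """32-bit multi-page TIFF, one page per component, labels in metadata."""
        path = Path(path)
        pages = np.ascontiguousarray(
            np.moveaxis(self.data.astype(np.float32), 2, 0)
        )
        meta = {
            "labels": list(self.labels),
            "pixel_size_um": self.pixel_size,
            "model_id": self.model_id,
        }
        tifffile.imwrite(path, pages, description=json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ConcentrationMaps":
        with tifffile.TiffFile(path) as fh:
            pages = fh.asarray()
            meta = json.loads(fh.pages[0].description)
        return cls(
            np.moveaxis(pages, 0, 2),
            tuple(meta["labels"]),
            float(meta.get("pixel_size_um", 0.12)),
            meta.get("model_id", ""),
        )


class CLSUnmixer(BaseEstimator, TransformerMixin):
    """Per-pixel linear unmixing against fixed pure spectra.

    Parameters
    ----------
    nonneg : clamp abundances non-negative by solving NNLS per pixel
        instead of ordinary least squares (default off).

    Fit against a :class:`~phycoscope.mcr.SpectralModel` (or a raw spectra
    matrix); ``transform`` accepts a pixel matrix or a
    :class:`~phycoscope.io.SpectralCube`.
    """

    def __init__(self, nonneg: bool = False):
        self.nonneg = nonneg

    def fit(self, model: SpectralModel | np.ndarray, y=None, labels=None) -> "CLSUnmixer":
        if isinstance(model, SpectralModel):
            S = model.spectra
            labels = model.labels or tuple(
                f"component_{i}" for i in range(model.n_components)
            )
            self.wavelengths_ = model.wavelengths
        else:
            S = check_array(model, dtype=float)
            labels = tuple(labels) if labels else tuple(
                f"component_{i}" for i in range(S.shape[0])
            )
            self.wavelengths_ = None
        k = S.shape[0]
        if np.linalg.matrix_rank(S) < k:
            gram = S @ S.T
            norms = np.sqrt(np.diag(gram))
            cos = gram / np.outer(norms, np.where(norms == 0, 1.0, norms))
            np.fill_diagonal(cos, 0.0)
            i, j = np.unravel_index(np.argmax(np.abs(cos)), cos.shape)
            raise ValueError(
                f"spectral model is rank deficient; components "
                f"{labels[i]!r} and {labels[j]!r} are collinear "
                f"(|cos| = {abs(cos[i, j]):.4f})"
            )
        self.components_ = S
        self.labels_ = labels
        self.pinv_ = np.linalg.pinv(S)  # (channels, k)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        if isinstance(X, SpectralCube):
            return self.unmix_cube(X).data
        X = check_array(X, dtype=float)
        if self.nonneg:
            S = self.components_
            return nnls_multiple(S @ S.T, S @ X.T).T
        return X @ self.pinv_

    def unmix_cube(self, cube: SpectralCube, model_id: str = "") -> ConcentrationMaps:
        check_is_fitted(self, "components_")
        if self.wavelengths_ is not None and not np.allclose(
            self.wavelengths_, cube.wavelengths
        ):
            raise ValueError("cube wavelength grid does not match the model grid")
        if cube.shape[2] != self.components_.shape[1]:
            raise ValueError("cube channel count does not match the model")
        C = self.transform(cube.pixel_matrix())
        rows, cols, _ = cube.shape
        return ConcentrationMaps(
            C.reshape(rows, cols, -1), self.labels_, cube.pixel_size, model_id
        )


def cls_unmix(
    cube: SpectralCube, model: SpectralModel, nonneg: bool = False
) -> ConcentrationMaps:
    """One-shot CLS unmixing of a cube against a spectral model."""
    return CLSUnmixer(nonneg=nonneg).fit(model).unmix_cube(cube)


def shared_scale(maps_list) -> dict[str, float]:
    """Per-display-channel maxima over a whole comparison set of maps.

    Using one shared scale keeps colors comparable across images.
    """
    red = max(float(m.get("Chl-PSI").max()) for m in maps_list)
    green = max(float(m.get("Chl-PSII").max()) for m in maps_list)
    blue = max(float((m.get("PC") + m.get("APC")).max()) for m in maps_list)
    return {"red": red, "green": green, "blue": blue}


def render_overlay(
    maps: ConcentrationMaps, scale: dict[str, float] | None = None
) -> np.ndarray:
    """Pseudocolor RGB image: red Chl–PSI, green Chl–PSII, blue PC + APC.

    *scale* holds per-channel maxima (use :func:`shared_scale` so a whole
    comparison set shares one color scale); defaults to this image's own
    maxima.  Returns a uint8 (rows, cols, 3) array.
    """
    for name in PIGMENTS:
        if name not in maps.labels:
            raise ValueError(f"maps lack required pigment component {name!r}")
    channels = {
        "red": maps.get("Chl-PSI"),
        "green": maps.get("Chl-PSII"),
        "blue": maps.get("PC") + maps.get("APC"),
    }
    if scale is None:
        scale = {k: float(v.max()) for k, v in channels.items()}
    rgb = np.zeros(maps.data.shape[:2] + (3,), dtype=np.uint8)
    for i, name in enumerate(("red", "green", "blue")):
        denom = scale[name] if scale[name] > 0 else 1.0
        rgb[:, :, i] = np.clip(channels[name] / denom, 0.0, 1.0) * 255.0
    return rgb
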