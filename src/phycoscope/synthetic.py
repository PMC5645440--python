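"""Synthetic hyperspectral scenes and bulk absorbance spectra.

This module emulates the study system end to end so the analysis pipeline is
testable with full ground truth: *Synechocystis* 6803 cells imaged by
hyperspectral confocal fluorescence microscopy under seven nitrogen
conditions, and the matching bulk absorbance measurements.

The generator's condition profiles ARE the study conditions: per-cell mean
abundance multipliers for the 24 h nitrogen-depleted population default to
the measured depletion fractions (PC 0.03, APC 0.09, Chl–PSI 0.43,
Chl–PSII 0.38 of the t = 0 values) and the 24 h-replete population to the
repletion fractions (0.88, 0.87, 0.80, 0.95).  Bulk spectra are calibrated
so phycobilin per OD730 falls 6.5-fold over 24 h of depletion and rises
12-fold on repletion.

Cells are rendered as 2-D disks (diameter 1.5–2.5 µm) whose pigment signal
is concentrated in a peripheral annulus standing in for the thylakoid
membranes (~80 % of pigment mass), with 0–3 punctate foci of dense thylakoid
packing; autofluorescence is uniform across the cell and a flat instrument
offset covers the whole frame.  Per-pixel spectra are linear mixtures of the
unit-length reference spectra with optional Poisson shot noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bulk import AbsorbanceSpectrum
from .io import SpectralCube
from .spectra import COMPONENTS, PIGMENTS, ReferenceSpectra, make_reference_spectra

__all__ = [
    "BASE_ABUNDANCE",
    "CONDITIONS",
    "ConditionProfile",
    "SceneGeometry",
    "SceneTruth",
    "make_population",
    "render_scene",
    "simulate_scene",
    "make_bulk_spectrum",
    "bulk_targets",
]

#: Mean per-cell abundance (count units) of the t = 0 +N reference
#: population.  Chosen to give EMCCD-like count levels: bright thylakoid
#: pixels reach a few thousand counts per channel-peak in control cells.
BASE_ABUNDANCE: dict[str, float] = {
    "PC": 3000.0,
    "APC": 2600.0,
    "Chl-PSII": 2000.0,
    "Chl-PSI": 1800.0,
    "autofluorescence": 300.0,
}

#: Flat instrument offset amplitude applied to every pixel in the frame
#: (EMCCD bias/dark baseline scale).
OFFSET_LEVEL: float = 300.0


@dataclass(frozen=True)
class ConditionProfile:
    """Population-level truth for one experimental condition.

    ``multipliers`` scale the :data:`BASE_ABUNDANCE` means (i.e. they are
    relative to the t = 0 +N control).  ``cv`` is the between-cell
    coefficient of variation of the log-normal abundance distribution and
    ``dead_fraction`` the expected fraction of dead/dying cells.
    ``bimodal_fraction`` > 0 switches on the optional second sub-population
    (reduced PC and Chl–PSII) seen in replete cultures.
    """

    condition: str
    multipliers: dict[str, float]
    cv: float = 0.25
    dead_fraction: float = 0.05
    bimodal_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name, m in self.multipliers.items():
            if m < 0:
                raise ValueError(f"negative abundance multiplier for {name}: {m}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")


def _profile(cond, pc, apc, psii, psi, autofl=1.0, **kw) -> ConditionProfile:
    return ConditionProfile(
        cond,
        {
            "PC": pc,
            "APC": apc,
            "Chl-PSII": psii,
            "Chl-PSI": psi,
            "autofluorescence": autofl,
        },
        **kw,
    )


#: The seven experimental conditions.  −N multipliers at t = 0 are 1.0 (the
#: t = 0 −N sample is imaged minutes after the medium swap); the T24−N row
#: holds the depletion fractions and T24replete the repletion fractions, so
#: percent-of-original against the arm's own t = 0 reproduces them directly.
#: +N controls drift slowly upward (self-shading response, ×1.7 by 48 h).
CONDITIONS: dict[str, ConditionProfile] = {
    "T0+N": _profile("T0+N", 1.0, 1.0, 1.0, 1.0),
    "T24+N": _profile("T24+N", 1.3, 1.3, 1.2, 1.2),
    "T48+N": _profile("T48+N", 1.7, 1.7, 1.4, 1.4),
    "T0-N": _profile("T0-N", 1.0, 1.0, 1.0, 1.0),
    "T24-N": _profile("T24-N", 0.03, 0.09, 0.38, 0.43, autofl=1.2),
    "T48-N": _profile("T48-N", 0.02, 0.05, 0.45, 0.50, autofl=1.3),
    "T24replete": _profile("T24replete", 0.88, 0.87, 0.95, 0.80),
}


def make_population(
    profile: ConditionProfile,
    n_cells: int,
    seed: int | np.random.Generator = 0,
    base: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw per-cell true abundances for one condition.

    Abundances are log-normal with mean ``base × multiplier`` and the
    profile's CV.  Dead cells (flagged at ``dead_fraction``) carry 10× the
    population-mean autofluorescence and 4× the population-mean
    phycobiliprotein (PC, APC) abundance, so the downstream QC rules fire.
    Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = dict(BASE_ABUNDANCE if base is None else base)

    table: dict[str, np.ndarray] = {}
    for name in ("PC", "APC", "Chl-PSII", "Chl-PSI", "autofluorescence"):
        mean = base[name] * profile.multipliers.get(name, 1.0)
        if mean == 0.0 or profile.cv == 0.0:
            values = np.full(n_cells, mean)
        else:
            sigma2 = np.log1p(profile.cv**2)
            mu = np.log(mean) - sigma2 / 2.0
            values = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_cells)
        table[name] = values

    # Compromised cells come in two kinds, mirroring what dying cultures
    # show: dead cells dominated by broad autofluorescence from pigment
    # breakdown products (pigments largely gone), and dying cells that have
    # lost energy transfer to the reaction centres and so show strongly
    # elevated phycobiliprotein fluorescence.
    n_dead = int(round(n_cells * profile.dead_fraction))
    which = rng.permutation(n_cells)[:n_dead]
    dead = np.zeros(n_cells, dtype=bool)
    dead[which] = True
    af_dominated = np.zeros(n_cells, dtype=bool)
    af_dominated[which[: (n_dead + 1) // 2]] = True
    pbs_elevated = dead & ~af_dominated
    if dead.any():
        af_mean = base["autofluorescence"] * profile.multipliers.get(
            "autofluorescence", 1.0
        )
        table["autofluorescence"][af_dominated] = 10.0 * af_mean
        for name in ("PC", "APC", "Chl-PSII", "Chl-PSI"):
            table[name][af_dominated] *= 0.05
        for name in ("PC", "APC"):
            mean = base[name] * profile.multipliers.get(name, 1.0)
            table[name][pbs_elevated] = (
                4.0 * mean if mean > 0 else 4.0 * 0.03 * base[name]
            )
        table["autofluorescence"][pbs_elevated] *= 2.0

    if profile.bimodal_fraction > 0:
        second = rng.random(n_cells) < profile.bimodal_fraction
        table["PC"][second & ~dead] *= 0.45
        table["Chl-PSII"][second & ~dead] *= 0.7

    df = pd.DataFrame(table)
    df.insert(0, "cell_id", np.arange(1, n_cells + 1))
    df.insert(1, "condition", profile.condition)
    df["offset"] = OFFSET_LEVEL
    df["dead"] = dead
    df["dead_kind"] = np.select(
        [af_dominated, pbs_elevated], ["autofluorescence", "pbs"], default=""
    )
    return df


@dataclass(frozen=True)
class SceneGeometry:
    """Frame geometry; defaults match the instrument's raster scan."""

    shape: tuple[int, int] = (210, 210)
    pixel_size: float = 0.12  # µm per pixel
    radius_um: tuple[float, float] = (0.75, 1.25)  # cell radius range
    margin_px: float = 2.0  # minimum gap between cell rims
    annulus_fraction: float = 0.30  # outer fraction of the radius = thylakoid ring
    annulus_mass: float = 0.80  # pigment mass carried by the ring
    max_foci: int = 3
    focus_fwhm_um: tuple[float, float] = (0.5, 0.7)
    # Pixel-scale compositional heterogeneity: pigment-specific membrane
    # patches (PSI-rich / PSII-rich regions, PBS-dense spots) and
    # independent log-normal pixel jitter per pigment.  Per-cell mean
    # abundances are renormalised afterwards, so the truth table is exact.
    max_patches: int = 3
    patch_amplitude: float = 3.0
    pigment_jitter_sd: float = 0.5


@dataclass
class SceneTruth:
    """Ground truth accompanying a rendered scene."""

    labels: np.ndarray  # int32 cell-id image, 0 = background
    table: pd.DataFrame  # per-cell truth abundances, dead flag, geometry
    concentrations: np.ndarray  # (rows, cols, 6) true per-pixel abundances
    pixel_size: float


def _place_cells(
    n: int, geometry: SceneGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disk centres and radii (pixels)."""
    rows, cols = geometry.shape
    r_lo, r_hi = (r / geometry.pixel_size for r in geometry.radius_um)
    centers = np.empty((n, 2))
    radii = np.empty(n)
    placed = 0
    for _ in range(20000):
        if placed == n:
            break
        r = rng.uniform(r_lo, r_hi)
        cy = rng.uniform(r + 1, rows - r - 1)
        cx = rng.uniform(r + 1, cols - r - 1)
        d = np.hypot(centers[:placed, 0] - cy, centers[:placed, 1] - cx)
        if np.all(d > radii[:placed] + r + geometry.margin_px):
            centers[placed] = (cy, cx)
            radii[placed] = r
            placed += 1
    if placed < n:
        raise RuntimeError(
            f"could not place {n} non-overlapping cells in a "
            f"{rows}x{cols} frame (placed {placed})"
        )
    return centers, radii


def _cell_weight_map(
    dist: np.ndarray,
    radius: float,
    geometry: SceneGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Normalised pigment weight over a cell's pixels (mean exactly 1)."""
    inside = dist <= radius
    ring = inside & (dist >= (1.0 - geometry.annulus_fraction) * radius)
    core = inside & ~ring
    w = np.zeros_like(dist)
    n_ring, n_core = int(ring.sum()), int(core.sum())
    if n_ring and n_core:
        w[ring] = geometry.annulus_mass / n_ring
        w[core] = (1.0 - geometry.annulus_mass) / n_core
    else:  # degenerate tiny cell: uniform
        w[inside] = 1.0 / max(int(inside.sum()), 1)

    n_foci = int(rng.integers(0, geometry.max_foci + 1))
    for _ in range(n_foci):
        w[inside] *= 1.0 + 2.0 * _bump(inside, geometry, rng)

    w[inside] /= w[inside].mean()  # per-cell mean abundance stays exact
    return w


def _bump(inside: np.ndarray, geometry: SceneGeometry, rng: np.random.Generator):
    """Gaussian bump of focus-like width centred on a random in-cell pixel,
    evaluated at the in-cell pixels."""
    yy, xx = np.nonzero(inside)
    j = int(rng.integers(0, yy.size))
    fwhm = rng.uniform(*geometry.focus_fwhm_um) / geometry.pixel_size
    sigma = fwhm / 2.3548
    d2 = (yy - yy[j]) ** 2.0 + (xx - xx[j]) ** 2.0
    return np.exp(-0.5 * d2 / sigma**2)


def _pigment_field(
    w: np.ndarray,
    inside: np.ndarray,
    geometry: SceneGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pigment-specific weight over in-cell pixels: shared base weight times
    0–``max_patches`` pigment-specific patches and per-pixel log-normal
    jitter, renormalised to mean 1 over the cell."""
    field = w[inside].copy()
    n_patches = int(rng.integers(0, geometry.max_patches + 1))
    for _ in range(n_patches):
        field *= 1.0 + geometry.patch_amplitude * _bump(inside, geometry, rng)
    if geometry.pigment_jitter_sd > 0:
        sd = geometry.pigment_jitter_sd
        field *= rng.lognormal(-0.5 * np.log1p(sd**2), np.sqrt(np.log1p(sd**2)), field.size)
    return field / field.mean()


def render_scene(
    truth: pd.DataFrame,
    reference: ReferenceSpectra | None = None,
    geometry: SceneGeometry | None = None,
    noise: bool = True,
    seed: int | np.random.Generator = 0,
    noise_seed: int | np.random.Generator | None = None,
) -> tuple[SpectralCube, SceneTruth]:
    """Render a per-cell truth table into a hyperspectral cube.

    Each pixel's spectrum is the non-negative linear mixture of the
    reference spectra weighted by the true component abundances; Poisson
    shot noise on counts is applied when *noise* is enabled.  With noise
    off the cube equals the truth concentrations times the spectra exactly.
    *noise_seed* draws the shot noise from a separate stream, so repeated
    renders of one layout can differ only in noise.
    """
    reference = reference or make_reference_spectra()
    geometry = geometry or SceneGeometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = len(truth)
    centers, radii = _place_cells(n, geometry, rng)
    rows, cols = geometry.shape
    k = len(COMPONENTS)
    conc = np.zeros((rows, cols, k))
    labels = np.zeros((rows, cols), dtype=np.int32)
    conc[:, :, COMPONENTS.index("offset")] = truth["offset"].iloc[0] if n else OFFSET_LEVEL

    grid_r = np.arange(rows)[:, None]
    grid_c = np.arange(cols)[None, :]
    for i in range(n):
        rec = truth.iloc[i]
        cy, cx = centers[i]
        radius = radii[i]
        dist = np.hypot(grid_r - cy, grid_c - cx)
        inside = dist <= radius
        labels[inside] = int(rec["cell_id"])
        # Partial coverage at the rim (the outermost ~1 px ramps from full
        # to zero signal), matching the soft cell edges that the
        # diffraction-limited spot produces in real frames.
        coverage = np.clip(radius - dist[inside], 0.0, 1.0)
        w = _cell_weight_map(dist, radius, geometry, rng)
        for name in PIGMENTS:
            field = _pigment_field(w, inside, geometry, rng) * coverage
            field /= field.mean()
            conc[:, :, COMPONENTS.index(name)][inside] += float(rec[name]) * field
        af_geometry = replace(geometry, max_patches=0, pigment_jitter_sd=0.3)
        af_field = _pigment_field(np.ones_like(w), inside, af_geometry, rng) * coverage
        af_field /= af_field.mean()
        conc[:, :, COMPONENTS.index("autofluorescence")][inside] += (
            float(rec["autofluorescence"]) * af_field
        )

    clean = conc.reshape(-1, k) @ reference.spectra
    if noise:
        noise_rng = rng
        if noise_seed is not None:
            noise_rng = (
                noise_seed
                if isinstance(noise_seed, np.random.Generator)
                else np.random.default_rng(noise_seed)
            )
        data = noise_rng.poisson(clean).astype(np.float64)
    else:
        data = clean
    cube = SpectralCube(
        data.reshape(rows, cols, reference.wavelengths.size),
        reference.wavelengths,
        geometry.pixel_size,
    )

    table = truth.copy()
    table["center_row"] = centers[:, 0]
    table["center_col"] = centers[:, 1]
    table["radius_um"] = radii * geometry.pixel_size
    return cube, SceneTruth(labels, table, conc, geometry.pixel_size)


def simulate_scene(
    condition: str,
    n_cells: int = 20,
    seed: int = 0,
    geometry: SceneGeometry | None = None,
    noise: bool = True,
    reference: ReferenceSpectra | None = None,
    profile: ConditionProfile | None = None,
) -> tuple[SpectralCube, SceneTruth]:
    """Population draw plus rendering for one named condition."""
    profile = profile or CONDITIONS[condition]
    cond_key = zlib.crc32(condition.encode()) % (2**31)  # stable across runs
    ss = np.random.SeedSequence([seed, cond_key])
    pop_rng, render_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    truth = make_population(profile, n_cells, pop_rng)
    return render_scene(truth, reference, geometry, noise, render_rng)


# ---------------------------------------------------------------------------
# Bulk absorbance spectra
# ---------------------------------------------------------------------------

#: Per-condition bulk calibration: (phycobilin mg/mL per OD730,
#: chlorophyll µg/mL per OD730, OD730).  Ratios encode the measured
#: kinetics: phycobilin per OD falls 6.5-fold over 24 h −N and rises
#: 12-fold on repletion; chlorophyll falls 1.8-fold and rises 2.4-fold;
#: +N controls rise ×1.7 (phycobilin) over 48 h.
_BULK_TARGETS: dict[str, tuple[float, float, float]] = {
    "T0+N": (0.120, 3.0, 0.40),
    "T24+N": (0.156, 3.6, 0.60),
    "T48+N": (0.204, 4.2, 0.85),
    "T0-N": (0.120, 3.0, 0.40),
    "T24-N": (0.120 / 6.5, 3.0 / 1.8, 0.50),
    "T48-N": (0.016, 1.75, 0.52),
    "T24replete": (12.0 * 0.120 / 6.5, 2.4 * 3.0 / 1.8, 0.62),
}

_MEDIUM_BASELINE = 0.046  # flat cell-free BG-11 absorbance (AU)


def bulk_targets(condition: str) -> tuple[float, float, float]:
    """Return the injected (phycobilin/OD, chlorophyll/OD, OD730) triple."""
    return _BULK_TARGETS[condition]


def _gauss(w: np.ndarray | float, mu: float, sigma: float) -> np.ndarray | float:
    return np.exp(-0.5 * ((np.asarray(w, dtype=float) - mu) / sigma) ** 2)


def make_bulk_spectrum(
    condition: str,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 5e-4,
) -> AbsorbanceSpectrum:
    """Synthesize a bulk absorbance spectrum (400–800 nm, 1 nm grid).

    ``condition="blank"`` returns the flat cell-free medium baseline.  For
    cultures, the spectrum is medium + a gentle scattering baseline anchored
    at the target OD730 + phycobilin (625 nm) and chlorophyll (678 nm red,
    435 nm Soret) bands whose amplitudes are solved so that the standard
    absorbance concentration equations return exactly the injected
    per-condition pigment concentrations (before noise).
    """
    wavelengths = np.arange(400.0, 801.0, 1.0)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(0 if seed is None else seed)
    )
    noise = rng.normal(0.0, noise_sd, wavelengths.size) if noise_sd > 0 else 0.0

    if condition == "blank":
        a = np.full_like(wavelengths, _MEDIUM_BASELINE) + noise
        return AbsorbanceSpectrum(wavelengths, a)

    phyc_per_od, chl_per_od, od730 = _BULK_TARGETS[condition]
    scatter = od730 * (730.0 / wavelengths) ** 0.4  # mild scattering slope
    d = {w: float(od730 * ((730.0 / w) ** 0.4 - 1.0)) for w in (620.0, 625.0, 678.0)}

    phi = {w: float(_gauss(w, 625.0, 22.0)) for w in (620.0, 625.0, 678.0, 730.0)}
    chi = {w: float(_gauss(w, 678.0, 12.0)) for w in (620.0, 625.0, 678.0, 730.0)}

    # Solve the two band amplitudes so the printed equations recover the
    # injected concentrations exactly (band tails at 730 nm included).
    def delta(band, w):
        return band[w] - band[730.0]

    m = np.array(
        [
            [
                0.139 * delta(phi, 620.0) - 0.0355 * delta(phi, 678.0),
                0.139 * delta(chi, 620.0) - 0.0355 * delta(chi, 678.0),
            ],
            [
                14.96 * delta(phi, 678.0) - 0.616 * delta(phi, 625.0),
                14.96 * delta(chi, 678.0) - 0.616 * delta(chi, 625.0),
            ],
        ]
    )
    rhs = np.array(
        [
            phyc_per_od * od730 - (0.139 * d[620.0] - 0.0355 * d[678.0]),
            chl_per_od * od730 - (14.96 * d[678.0] - 0.616 * d[625.0]),
        ]
    )
    p_amp, c_amp = np.linalg.solve(m, rhs)

    a = (
        _MEDIUM_BASELINE
        + scatter
        + p_amp * _gauss(wavelengths, 625.0, 22.0)
        + c_amp * _gauss(wavelengths, 678.0, 12.0)
        + 1.1 * c_amp * _gauss(wavelengths, 435.0, 20.0)  # Soret, cosmetic
        + noise
    )
    return AbsorbanceSpectrum(wavelengths, a)
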