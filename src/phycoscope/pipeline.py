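"""End-to-end orchestration: generate → decompose → unmix → segment → quantify.

Mirrors the study's analysis flow: representative images from every
condition are pooled into one pixel matrix for a single joint MCR fit, the
resulting spectral model is applied per image by CLS, cells are segmented
and QC-flagged per condition, and population statistics (percent-of-original
table, pigment ratios, scatter exports) plus the bulk absorbance report are
written to a run directory together with a manifest capturing the full
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import bulk as bulk_mod
from .cellstats import (
    per_cell_abundance,
    percent_of_initial,
    pigment_ratio,
    scatter_export,
    summarize_population,
)
from .cls import CLSUnmixer, render_overlay, shared_scale
from .io import write_cube
from .mcr import MCRALS, background_mask, identify_components, pin_offset
from .segmentation import QcCriteria, flag_compromised_cells, segment_cells
from .spectra import PIGMENTS, make_reference_spectra
from .synthetic import CONDITIONS, SceneGeometry, make_bulk_spectrum, simulate_scene

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("phycoscope.pipeline")

#: (condition, its arm's t=0 reference) pairs for the percent-of-original table.
_PERCENT_PAIRS = (("T24-N", "T0-N"), ("T24replete", "T0-N"))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (recorded in the manifest)."""

    seed: int = 0
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    n_cells: int = 20
    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    n_components: int = 6
    mcr_init: str = "purest"
    mcr_max_iter: int = 500
    mcr_tol: float = 1e-6
    cls_nonneg: bool = False
    smoothing_sigma: float = 1.0
    h_depth: float = 2.0
    qc: QcCriteria = field(default_factory=QcCriteria)
    noise: bool = True
    save_cubes: bool = False
    cube_format: str = "tiff"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["geometry"]["shape"] = list(self.geometry.shape)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "geometry" in raw:
            geo = raw["geometry"]
            for key in ("shape", "radius_um", "focus_fwhm_um"):
                if key in geo:
                    geo[key] = tuple(geo[key])
            raw["geometry"] = SceneGeometry(**geo)
        if "qc" in raw:
            raw["qc"] = QcCriteria(**raw["qc"])
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    Outputs per condition: (optionally) the generated cube, concentration
    maps (32-bit TIFF), label image (16-bit TIFF), overlay PNG on a shared
    color scale, cell records CSV with QC flags; plus the joint spectral
    model, population summaries, percent-of-original table, pigment ratios,
    scatter tables, the bulk pigment report and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    counts: dict[str, dict] = {}

    ref = make_reference_spectra()
    root_ss = np.random.SeedSequence(config.seed)

    # --- generate ---------------------------------------------------------
    t0 = time.time()
    scenes = {}
    for cond in config.conditions:
        cube, truth = simulate_scene(
            cond,
            n_cells=config.n_cells,
            seed=config.seed,
            geometry=config.geometry,
            noise=config.noise,
            reference=ref,
        )
        scenes[cond] = (cube, truth)
        if config.save_cubes:
            suffix = "h5" if config.cube_format == "h5" else "tif"
            write_cube(cube, out / f"cube_{cond}.{suffix}", config.cube_format)
        tifffile.imwrite(
            out / f"truth_labels_{cond}.tif", truth.labels.astype(np.uint16)
        )
        _write_csv(truth.table, out / f"truth_cells_{cond}.csv")
    timings["generate"] = time.time() - t0
    log.info("generated %d scenes in %.1fs", len(scenes), timings["generate"])

    # --- joint MCR --------------------------------------------------------
    t0 = time.time()
    pooled = []
    for cond in config.conditions:
        cube, _ = scenes[cond]
        mask = background_mask(cube, method="background")
        pooled.append(cube.pixel_matrix()[mask.ravel()])
    X = np.vstack(pooled)
    est = MCRALS(
        n_components=config.n_components,
        init=config.mcr_init,
        max_iter=config.mcr_max_iter,
        tol=config.mcr_tol,
        random_state=config.seed,
    ).fit(X)
    model = pin_offset(identify_components(est.to_model(ref.wavelengths)))
    model.save(out / "spectral_model.csv")
    timings["mcr"] = time.time() - t0
    counts["mcr"] = {
        "n_pixels": int(est.n_pixels_),
        "n_iter": int(est.n_iter_),
        "converged": bool(est.converged_),
        "variance_explained": float(est.variance_explained_),
    }
    log.info(
        "joint MCR: %d pixels, variance explained %.4f (%.1fs)",
        est.n_pixels_, est.variance_explained_, timings["mcr"],
    )

    # --- CLS, segmentation, per-cell stats --------------------------------
    t0 = time.time()
    unmixer = CLSUnmixer(nonneg=config.cls_nonneg).fit(model)
    all_maps, records = {}, []
    for cond in config.conditions:
        cube, _ = scenes[cond]
        maps = unmixer.unmix_cube(cube, model_id="joint_mcr")
        maps.save(out / f"maps_{cond}.tif")
        all_maps[cond] = maps
        labels = segment_cells(
            maps, config.smoothing_sigma, config.h_depth, config.qc
        )
        tifffile.imwrite(out / f"labels_{cond}.tif", labels.astype(np.uint16))
        cells = per_cell_abundance(maps, labels, condition=cond)
        records.append(cells)
        counts[cond] = {"cells_found": int(labels.max())}
    scale = shared_scale(list(all_maps.values()))
    for cond, maps in all_maps.items():
        iio.imwrite(out / f"overlay_{cond}.png", render_overlay(maps, scale))

    cell_table = pd.concat(records, ignore_index=True)
    cell_table = flag_compromised_cells(cell_table, config.qc)
    _write_csv(cell_table, out / "cell_records.csv")
    flagged = cell_table[cell_table["qc_flag"]]
    _write_csv(
        flagged[["condition", "cell_id", "qc_reason"]], out / "qc_report.csv"
    )
    for cond in config.conditions:
        counts[cond]["cells_flagged"] = int(
            (flagged["condition"] == cond).sum()
        )
    timings["unmix_segment_quantify"] = time.time() - t0

    # --- population statistics -------------------------------------------
    t0 = time.time()
    summaries = {
        cond: summarize_population(
            cell_table[cell_table["condition"] == cond], components=PIGMENTS
        )
        for cond in config.conditions
    }
    summary_rows = []
    for cond, summ in summaries.items():
        s = summ.reset_index(names="component")
        s.insert(0, "condition", cond)
        summary_rows.append(s)
    _write_csv(pd.concat(summary_rows, ignore_index=True), out / "population_summary.csv")

    percent_frames = []
    for cond, ref_cond in _PERCENT_PAIRS:
        if cond in summaries and ref_cond in summaries:
            pct = percent_of_initial(summaries[cond], summaries[ref_cond])
            pct = pct.reset_index(names="component")
            pct.insert(0, "condition", cond)
            pct.insert(1, "reference", ref_cond)
            percent_frames.append(pct)
    if percent_frames:
        table1 = pd.concat(percent_frames, ignore_index=True)
        _write_csv(table1, out / "percent_of_original.csv")
        lines = ["percent of original abundance (± propagated SE)"]
        for _, row in table1.iterrows():
            lines.append(
                f"{row['condition']:>12s} vs {row['reference']:<6s} "
                f"{row['component']:<9s} {row['percent']:6.1f} ± {row['se_percent']:.1f} %"
            )
        (out / "percent_of_original.txt").write_text("\n".join(lines) + "\n")

    ratios = {}
    if "T24-N" in summaries:
        control = summaries.get("T24+N")
        if control is None:
            control = summaries.get("T0+N")
        ratios["APC_PC_T24-N_control_normalized"] = pigment_ratio(
            summaries["T24-N"], "APC", "PC", control_summary=control
        )
    for x, y in (("PC", "Chl-PSII"), ("PC", "APC")):
        _write_csv(
            scatter_export(cell_table, x, y), out / f"scatter_{x}_vs_{y}.csv"
        )
    timings["stats"] = time.time() - t0

    # --- bulk absorbance ---------------------------------------------------
    t0 = time.time()
    bulk_rng = np.random.default_rng(root_ss.spawn(1)[0])
    blank = make_bulk_spectrum("blank", seed=bulk_rng)
    spectra = {
        cond: make_bulk_spectrum(cond, seed=bulk_rng)
        for cond in config.conditions
        if cond in CONDITIONS
    }
    bulk_ref = "T0-N" if "T0-N" in spectra else next(iter(spectra))
    report = bulk_mod.pigment_report(spectra, blank, reference=bulk_ref)
    _write_csv(report.reset_index(), out / "bulk_pigments.csv")
    timings["bulk"] = time.time() - t0

    # --- manifest ----------------------------------------------------------
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": config_hash,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "counts": counts,
        "ratios": ratios,
        "total_runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("pipeline complete in %.1fs -> %s", time.time() - t_start, out)
    return out
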