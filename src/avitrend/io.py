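"""Readers and writers for the interchange formats.

Tabular data travel as UTF-8 comma-separated files with "." decimals and a
provenance comment header (lines starting with ``#``).  Rasters use the
ESRI ASCII grid dialect (plain text, one file per covariate-year), chosen
so fixtures survive text-only archiving; the grid header carries the
georeferencing that a GeoTIFF would.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import BufferStack, CovariateRaster

DETECTION_COLUMNS = [
    "grid_id",
    "year",
    "species",
    "distance_m",
    "minute",
    "observer_experienced",
]
SURVEY_COLUMNS = [
    "grid_id",
    "year",
    "n_points",
    "ordinal_date",
    "mean_min_since_sunrise",
    "observer_experienced",
    "bcr_id",
    "easting",
    "northing",
]

MIN_SURVEY_YEARS = 3
MIN_YEAR_FRACTION = 2.0 / 3.0  # the "67%" rule, read as two-thirds


def provenance(seed=None, config=None) -> dict:
    p = {"package": "avitrend", "version": __version__}
    if seed is not None:
        p["seed"] = int(seed)
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        p["config_sha1"] = hashlib.sha1(blob).hexdigest()[:12]
    return p


def write_table(frame: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in provenance(seed, config).items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"{path.name}: missing column(s) {missing}")
    return frame


# ---------------------------------------------------------------------------
# detections / surveys with the survey-design filters


def filter_detections(frame: pd.DataFrame, drop_unknown: bool = True,
                      drop_flyovers: bool = True, drop_migrants: bool = True,
                      drop_incomplete: bool = True):
    """Survey-protocol filters; returns (kept frame, counts log)."""
    counts = {"input": len(frame)}
    out = frame
    if drop_unknown and "species" in out.columns:
        keep = out["species"].str.lower() != "unknown"
        counts["unknown_species"] = int((~keep).sum())
        out = out[keep]
    if drop_flyovers and "flyover" in out.columns:
        keep = out["flyover"].fillna(0).astype(int) == 0
        counts["flyovers"] = int((~keep).sum())
        out = out[keep]
    if drop_migrants and "migrant" in out.columns:
        keep = out["migrant"].fillna(0).astype(int) == 0
        counts["migrants"] = int((~keep).sum())
        out = out[keep]
    if drop_incomplete:
        core = [c for c in DETECTION_COLUMNS if c in out.columns]
        keep = out[core].notna().all(axis=1)
        counts["incomplete"] = int((~keep).sum())
        out = out[keep]
    counts["kept"] = len(out)
    return out.reset_index(drop=True), counts


def grid_inclusion_filter(surveys: pd.DataFrame):
    """Keep grids surveyed >= 3 years and >= 67% of the years between the
    first and last survey year (inclusive span)."""
    keep_grids = []
    for gid, grp in surveys.groupby("grid_id"):
        yrs = sorted(grp["year"].unique())
        span = yrs[-1] - yrs[0] + 1
        if len(yrs) >= MIN_SURVEY_YEARS and len(yrs) / span >= MIN_YEAR_FRACTION:
            keep_grids.append(gid)
    kept = surveys[surveys["grid_id"].isin(keep_grids)].reset_index(drop=True)
    log = {
        "grids_in": surveys["grid_id"].nunique(),
        "grids_kept": len(keep_grids),
    }
    return kept, log


def read_detections(path, apply_filters: bool = True):
    frame = read_table(path, required=DETECTION_COLUMNS[:2] + ["distance_m", "minute"])
    bad = frame["distance_m"].apply(lambda v: not np.isfinite(v) if pd.notna(v) else False)
    if bad.any():
        line = int(frame.index[bad][0]) + 2
        raise ValueError(f"unparseable distance at data line {line}")
    if apply_filters:
        frame, counts = filter_detections(frame)
        return frame, counts
    return frame, {"input": len(frame), "kept": len(frame)}


def read_surveys(path, apply_inclusion: bool = True):
    frame = read_table(path, required=SURVEY_COLUMNS[:5])
    if apply_inclusion:
        return grid_inclusion_filter(frame)
    return frame, {"grids_in": frame["grid_id"].nunique(), "grids_kept": frame["grid_id"].nunique()}


# ---------------------------------------------------------------------------
# ascii-grid rasters


def write_raster(raster: CovariateRaster, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nrow, ncol = raster.shape
    west, north = raster.origin
    yll = north - nrow * raster.cell_size
    vals = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {west}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, vals, fmt="%.6g")


def read_raster(path, name: str | None = None, year: int | None = None) -> CovariateRaster:
    path = Path(path)
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    cell = header["cellsize"]
    north = header["yllcorner"] + header["nrows"] * cell
    if name is None or year is None:
        stem = path.stem  # "<covariate>_<year>" (year optional)
        parts = stem.rsplit("_", 1)
        if year is None:
            year = int(parts[1]) if len(parts) == 2 and parts[1].isdigit() else 0
        if name is None:
            name = parts[0] if len(parts) == 2 and parts[1].isdigit() else stem
    return CovariateRaster(
        name=name,
        year=year,
        values=values,
        cell_size=cell,
        origin=(header["xllcorner"], north),
        nodata=header.get("nodata_value", -9999.0),
    )


# ---------------------------------------------------------------------------
# buffer stacks, posteriors, configs


def write_stack(stack: BufferStack, path, seed=None) -> None:
    write_table(stack.to_tidy(), path, seed=seed)
    if stack.center:
        meta = Path(path).with_suffix(".meta.json")
        with open(meta, "w") as fh:
            json.dump({"center": stack.center, "scale": stack.scale}, fh)


def read_stack(path) -> BufferStack:
    stack = BufferStack.from_tidy(read_table(path))
    meta = Path(path).with_suffix(".meta.json")
    if meta.exists():
        with open(meta) as fh:
            d = json.load(fh)
        stack.center, stack.scale = d["center"], d["scale"]
    return stack


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_density_surface(surface, out_dir, stem: str = "density") -> dict:
    """Write the value band and both mask bands as ascii grids."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    bands = {
        stem: np.where(np.isfinite(surface.density), surface.density, surface.nodata),
        f"{stem}_disturbance_mask": surface.disturbance_mask.astype(float),
        f"{stem}_qa_mask": surface.qa_mask.astype(float),
    }
    for key, vals in bands.items():
        r = CovariateRaster(
            name=key, year=0, values=vals,
            cell_size=surface.cell_size, origin=surface.origin,
            nodata=surface.nodata,
        )
        p = out_dir / f"{key}.asc"
        write_raster(r, p)
        paths[key] = str(p)
    return paths


# ---------------------------------------------------------------------------
# whole synthetic studies


def write_study(study, out_dir, seed=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config.to_manifest()
    write_table(study.surveys, out / "surveys.csv", seed=seed, config=cfg)
    write_table(study.detections, out / "detections.csv", seed=seed, config=cfg)
    write_stack(study.stack, out / "stack.csv", seed=seed)
    for cov, by_year in study.rasters.items():
        for yr, rast in by_year.items():
            write_raster(rast, out / "rasters" / f"{cov}_{yr}.asc")
    manifest = {
        "provenance": provenance(seed, cfg),
        "config": cfg,
        "truth": _jsonify_truth(study.truth),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_study(path):
    from .simulate import SimConfig, SyntheticStudy

    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SimConfig.from_manifest(manifest["config"])
    surveys = read_table(path / "surveys.csv")
    detections = read_table(path / "detections.csv")
    stack = read_stack(path / "stack.csv")
    rasters: dict = {}
    rdir = path / "rasters"
    if rdir.exists():
        for p in sorted(rdir.glob("*.asc")):
            r = read_raster(p)
            rasters.setdefault(r.name, {})[r.year] = r
    truth = {k: np.asarray(v) if isinstance(v, list) else v
             for k, v in manifest["truth"].items()}
    return SyntheticStudy(surveys, detections, rasters, stack, truth, config)


def _jsonify_truth(truth: dict) -> dict:
    out = {}
    for k, v in truth.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, dict):
            out[k] = {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv) for kk, vv in v.items()}
        else:
            out[k] = v
    return out
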