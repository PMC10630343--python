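"""Configuration and raster/table I/O.

Config files are YAML with explicit units embedded in the key names
(``D0_m2_per_s`` rather than a bare ``D0``) to keep unit mistakes loud.
Unknown keys are rejected with their location; omitted keys fall back to
the default-simulation values and the fallback is logged. DTM rasters are
read and written as ESRI ASCII grids or single-band GeoTIFFs; skeletons are
written as GeoJSON-like line features with per-point attributes and
statistics as CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import GridSpec, GradientSpec, ModelParams
from .simulator import RunConfig
from .network import DTMRaster, NetworkStats, Skeleton

__all__ = [
    "load_config",
    "save_config",
    "config_hash",
    "read_dtm",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_geotiff",
    "write_geotiff",
    "skeleton_to_geojson",
    "write_skeleton",
    "stats_to_frame",
]

logger = logging.getLogger(__name__)

# config key <-> ModelParams attribute, with units in the key names
_PARAM_KEYS = {
    "dt_s": "dt",
    "phi_s": "phi",
    "t_end_yr": "t_end_years",
    "D0_m2_per_s": "D0",
    "DB_m2_per_s": "DB",
    "DU_m2_per_s": "DU",
    "ES_s_per_m2": "ES",
    "EB_s_per_m2": "EB",
    "g_m_per_s2": "g",
    "H0_m": "H0",
    "Hc_m": "Hc",
    "Hin_m_per_s": "Hin",
    "k_per_m2": "k",
    "nb_s_per_m13": "nb",
    "nv_s_per_m13": "nv",
    "pD": "pD",
    "pE": "pE",
    "pest": "pest",
    "Qq_m": "Qq",
    "Qs_m": "Qs",
    "rho_kg_per_m3": "rho",
    "r_per_s": "r",
    "Sin_m_per_s": "Sin",
}
_GRID_KEYS = {"nx": "n_x", "ny": "n_y", "dx_m": "dx", "dy_m": "dy"}
_RUN_KEYS = ("seed", "snapshot_every_yr", "veg_dynamics", "advection",
             "engine", "checkpoint_path")
_GRADIENT_KEYS = {"D0_min_m2_per_s": "D0_min", "D0_max_m2_per_s": "D0_max",
                  "axis": "axis"}


def _check_unknown(section: dict, allowed, where: str) -> None:
    unknown = sorted(set(section) - set(allowed))
    if unknown:
        raise ValueError(
            f"unknown config key(s) at {where}: {', '.join(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a run configuration; missing keys fall back to
    the defaults (logged), unknown keys are rejected with their section."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_unknown(raw, ("grid", "params", "run", "gradient"), str(path))

    grid_raw = raw.get("grid", {}) or {}
    _check_unknown(grid_raw, _GRID_KEYS, f"{path}:grid")
    grid_kwargs = {attr: grid_raw[key]
                   for key, attr in _GRID_KEYS.items() if key in grid_raw}
    grid = GridSpec(**grid_kwargs)

    params_raw = raw.get("params", {}) or {}
    _check_unknown(params_raw, _PARAM_KEYS, f"{path}:params")
    param_kwargs = {}
    for key, attr in _PARAM_KEYS.items():
        if key in params_raw:
            param_kwargs[attr] = float(params_raw[key])
        else:
            logger.info("config %s: %s not given, using default", path, key)
    params = ModelParams(**param_kwargs)

    run_raw = raw.get("run", {}) or {}
    _check_unknown(run_raw, _RUN_KEYS, f"{path}:run")
    run_kwargs = {}
    if "seed" in run_raw:
        run_kwargs["seed"] = int(run_raw["seed"])
    if "snapshot_every_yr" in run_raw:
        run_kwargs["snapshot_every_years"] = float(run_raw["snapshot_every_yr"])
    for key in ("veg_dynamics", "advection", "engine", "checkpoint_path"):
        if key in run_raw:
            run_kwargs[key] = run_raw[key]

    gradient = None
    if "gradient" in raw and raw["gradient"]:
        grad_raw = raw["gradient"]
        _check_unknown(grad_raw, _GRADIENT_KEYS, f"{path}:gradient")
        gradient = GradientSpec(**{attr: grad_raw[key]
                                   for key, attr in _GRADIENT_KEYS.items()
                                   if key in grad_raw})

    cfg = RunConfig(grid=grid, params=params, gradient=gradient, **run_kwargs)
    return cfg.validate()


def _config_dict(cfg: RunConfig) -> dict:
    out = {
        "grid": {key: getattr(cfg.grid, attr)
                 for key, attr in _GRID_KEYS.items()},
        "params": {key: getattr(cfg.params, attr)
                   for key, attr in _PARAM_KEYS.items()},
        "run": {
            "seed": cfg.seed,
            "snapshot_every_yr": cfg.snapshot_every_years,
            "veg_dynamics": cfg.veg_dynamics,
            "advection": cfg.advection,
            "engine": cfg.engine,
            "checkpoint_path": cfg.checkpoint_path,
        },
    }
    if cfg.gradient is not None:
        out["gradient"] = {key: getattr(cfg.gradient, attr)
                           for key, attr in _GRADIENT_KEYS.items()}
    return out


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config that :func:`load_config` reads back to identical
    values (floats round-trip bit-for-bit through their repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a configuration (embedded in output
    artifacts together with the seed for provenance)."""
    canon = json.dumps(_config_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

def write_esri_ascii(dtm: DTMRaster, path: str | Path,
                     nodata_value: float = -9999.0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    elev = dtm.elevation.copy()
    if dtm.nodata is not None:
        elev[dtm.nodata] = nodata_value
    n_r, n_c = elev.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {n_c}\n"
                 f"nrows {n_r}\n"
                 f"xllcorner 0.0\n"
                 f"yllcorner 0.0\n"
                 f"cellsize {dtm.pixel_size!r}\n"
                 f"NODATA_value {nodata_value!r}\n")
        np.savetxt(fh, elev, fmt="%.10g")


def read_esri_ascii(path: str | Path) -> DTMRaster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "xllcenter", "yllcenter", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {req}")
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = None
    if "nodata_value" in header:
        nodata = data == header["nodata_value"]
        if not nodata.any():
            nodata = None
    return DTMRaster(data, header["cellsize"], nodata)


def write_geotiff(dtm: DTMRaster, path: str | Path) -> None:
    import tifffile
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # resolution tag stores pixels per unit
    res = 1.0 / dtm.pixel_size
    tifffile.imwrite(path, dtm.elevation.astype(np.float64),
                     resolution=(res, res))


def read_geotiff(path: str | Path,
                 pixel_size: float | None = None) -> DTMRaster:
    """Read a single-band GeoTIFF; the pixel size is taken from the
    resolution tag unless given explicitly."""
    import tifffile
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if pixel_size is None:
            tag = page.tags.get("XResolution")
            if tag is None:
                raise ValueError(
                    f"{path}: no resolution tag; pass pixel_size explicitly")
            num, den = tag.value
            pixel_size = den / num
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single elevation band, got "
                         f"shape {data.shape}")
    return DTMRaster(np.asarray(data, dtype=float), float(pixel_size))


def read_dtm(path: str | Path,
             pixel_size: float | None = None) -> DTMRaster:
    """Dispatch on file suffix: .asc/.txt ESRI ASCII, .tif/.tiff GeoTIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt"):
        return read_esri_ascii(path)
    if suffix in (".tif", ".tiff"):
        return read_geotiff(path, pixel_size)
    raise ValueError(f"unsupported DTM format: {path}")


# ---------------------------------------------------------------------------
# Skeletons and statistics tables
# ---------------------------------------------------------------------------

def skeleton_to_geojson(skel: Skeleton) -> dict:
    """GeoJSON-like FeatureCollection of section centerlines with per-point
    attributes (x alongshore-column, y row, both in metres)."""
    feats = []
    for sec in skel.sections:
        coords = [[float(c * skel.pixel_size), float(r * skel.pixel_size)]
                  for r, c in sec.points]
        props = {
            "section": sec.id,
            "start_node": sec.start_node,
            "end_node": sec.end_node,
            "length_m": sec.length,
            "hack_order": sec.order,
            "subbasin": sec.subbasin,
        }
        for attr, name in [("upstream_max_length", "upstream_max_length_m"),
                           ("upstream_total_length",
                            "upstream_total_length_m"),
                           ("area", "watershed_area_m2")]:
            val = getattr(sec, attr)
            if val is not None:
                props[name] = [float(x) for x in val]
        feats.append({"type": "Feature",
                      "geometry": {"type": "LineString",
                                   "coordinates": coords},
                      "properties": props})
    return {"type": "FeatureCollection", "features": feats}


def write_skeleton(skel: Skeleton, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(skeleton_to_geojson(skel), fh)


def stats_to_frame(stats: NetworkStats) -> pd.DataFrame:
    """One-row summary table of the scalar network statistics."""
    row = {
        "max_hack_order": stats.max_order,
        "total_length_m": stats.total_length,
        "basin_area_m2": stats.basin_area,
        "drainage_density_per_m": stats.drainage_density,
        "n_area_samples": stats.area_samples.size,
        "n_upl_samples": stats.upl_samples.size,
    }
    for i, n in enumerate(stats.stream_counts, start=1):
        row[f"n_order_{i}"] = int(n)
    for i, r in enumerate(stats.bifurcation_ratios, start=1):
        row[f"r_{i}"] = float(r)
    return pd.DataFrame([row])
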