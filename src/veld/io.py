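"""Readers/writers and run manifests.

Gridded fields travel as CF-style NetCDF (classic format via the scipy
backend: coordinate variables, units and long names on every field), so
any generic NetCDF tool can read them.  Per-cell summaries and binned
tables export to CSV.  A run manifest (JSON) snapshots the experiment
configuration, seed and package version — enough to re-run
bit-identically — plus per-cell convergence flags and field checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .climate import ClimateGrid, summarize_climate
from .experiments import ExperimentConfig, RunResult
from .vegetation import C3G, C4G, TREE

__all__ = [
    "grid_to_dataset", "dataset_to_grid", "write_climate", "read_climate",
    "summaries_to_csv", "run_to_dataset", "write_run_outputs", "field_checksum",
]

_ENGINE = "scipy"   # classic NetCDF; self-describing and dependency-light

_FIELD_ATTRS = {
    "tas": {"units": "degC", "long_name": "near-surface air temperature"},
    "pre": {"units": "mm/month", "long_name": "precipitation total"},
    "wet": {"units": "days", "long_name": "wet days per month"},
    "sun": {"units": "1", "long_name": "fractional sunshine"},
}

_DEFAULT_UNITS = {v["units"] for v in _FIELD_ATTRS.values()}


def grid_to_dataset(grid: ClimateGrid) -> xr.Dataset:
    """ClimateGrid -> CF-style xarray Dataset (month, lat, lon)."""
    coords = {
        "month": ("month", np.arange(1, 13), {"long_name": "climatological month"}),
        "lat": ("lat", grid.lat, {"units": "degrees_north", "standard_name": "latitude"}),
        "lon": ("lon", grid.lon, {"units": "degrees_east", "standard_name": "longitude"}),
    }
    data = {name: (("month", "lat", "lon"), getattr(grid, name), _FIELD_ATTRS[name])
            for name in _FIELD_ATTRS}
    attrs = {"Conventions": "CF-1.8", "variant_id": grid.variant_id}
    if grid.seed is not None:
        attrs["seed"] = int(grid.seed)
    return xr.Dataset(data, coords=coords, attrs=attrs)


def dataset_to_grid(ds: xr.Dataset) -> ClimateGrid:
    """xarray Dataset -> ClimateGrid, tolerant of foreign files.

    Requires a 12-long month dimension and the four monthly fields;
    missing units attributes produce a warning and the documented
    defaults are assumed.
    """
    if "month" not in ds.dims or ds.sizes["month"] != 12:
        raise ValueError("dataset must have a 'month' dimension of length 12")
    missing = [n for n in _FIELD_ATTRS if n not in ds]
    if missing:
        raise ValueError(f"dataset lacks required fields: {missing}")
    for name, attrs in _FIELD_ATTRS.items():
        units = ds[name].attrs.get("units")
        if units is None:
            warnings.warn(f"field {name!r} has no units attribute; "
                          f"assuming {attrs['units']!r}", stacklevel=2)
    grid = ClimateGrid(
        lat=np.asarray(ds["lat"].values, dtype=float),
        lon=np.asarray(ds["lon"].values, dtype=float),
        tas=np.asarray(ds["tas"].transpose("month", "lat", "lon").values, dtype=float),
        pre=np.asarray(ds["pre"].transpose("month", "lat", "lon").values, dtype=float),
        wet=np.asarray(ds["wet"].transpose("month", "lat", "lon").values, dtype=float),
        sun=np.asarray(ds["sun"].transpose("month", "lat", "lon").values, dtype=float),
        variant_id=str(ds.attrs.get("variant_id", "unknown")),
        seed=int(ds.attrs["seed"]) if "seed" in ds.attrs else None,
    )
    grid.validate()
    return grid


def write_climate(grid: ClimateGrid, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid_to_dataset(grid).to_netcdf(path, engine=_ENGINE)
    return path


def read_climate(path) -> ClimateGrid:
    try:
        with xr.open_dataset(path, engine=_ENGINE) as ds:
            return dataset_to_grid(ds.load())
    except (OSError, TypeError, ValueError) as e:
        if isinstance(e, ValueError) and ("dimension" in str(e) or "fields" in str(e)):
            raise
        raise ValueError(f"cannot parse climate file {path}: {e}") from e


def summaries_to_csv(grid: ClimateGrid, path) -> Path:
    """Per-cell annual summaries (MAT, MAP, seasonality...) to CSV."""
    s = summarize_climate(grid)
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    df = pd.DataFrame({
        "lat": lat2.ravel(), "lon": lon2.ravel(),
        "mat": s.mat.ravel(), "map": s.map_.ravel(),
        "t_coldest": s.t_coldest.ravel(), "t_warmest": s.t_warmest.ravel(),
        "t_peak_rain": s.t_peak_rain.ravel(),
        "concentration": s.concentration.ravel(),
        "phase_month": s.phase_month.ravel(),
    })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def run_to_dataset(run: RunResult) -> xr.Dataset:
    """RunResult cover fields -> CF-style Dataset."""
    coords = {
        "lat": ("lat", run.grid.lat, {"units": "degrees_north"}),
        "lon": ("lon", run.grid.lon, {"units": "degrees_east"}),
    }
    fpc_attr = {"units": "1", "long_name": "foliage projective cover (run-mean)"}
    ds = xr.Dataset(
        {
            "fpc_tree": (("lat", "lon"), run.fpc[TREE], fpc_attr),
            "fpc_c3_grass": (("lat", "lon"), run.fpc[C3G], fpc_attr),
            "fpc_c4_grass": (("lat", "lon"), run.fpc[C4G], fpc_attr),
            "grass_share_c4": (("lat", "lon"), run.grass_share_c4,
                               {"units": "1", "long_name": "C4 share of grass cover"}),
            "burned_frac": (("lat", "lon"), run.burned_frac,
                            {"units": "1/yr", "long_name": "annual burned fraction"}),
            "converged": (("lat", "lon"), run.converged.astype("i1"),
                          {"long_name": "spin-up convergence flag"}),
        },
        coords=coords,
        attrs={"Conventions": "CF-1.8", "label": run.label, "co2_ppm": run.co2,
               "fire": "on" if run.fire_on else "off", "variant": run.variant},
    )
    return ds


def field_checksum(arrays) -> str:
    """Deterministic SHA-256 over a sequence of float arrays."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=np.float64)).tobytes())
    return h.hexdigest()


def write_run_outputs(runs: dict[str, RunResult], out_dir,
                      config: ExperimentConfig | None = None) -> Path:
    """Write one NetCDF per run, a CSV summary table and a JSON manifest.

    Returns the manifest path.  Re-running the same configuration and
    seed reproduces every file bit-identically (checksums in the
    manifest make that checkable).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    manifest: dict = {
        "package_version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config) if config is not None else None,
        "runs": {},
    }
    for label, run in runs.items():
        path = out / f"{label}.nc"
        run_to_dataset(run).to_netcdf(path, engine=_ENGINE)
        manifest["runs"][label] = {
            "file": path.name,
            "checksum": field_checksum([run.fpc, run.burned_frac]),
            "cells_converged": int(run.converged.sum()),
            "cells_total": int(run.converged.size),
        }
        rows.append({
            "label": label, "co2": run.co2,
            "fire": "on" if run.fire_on else "off", "variant": run.variant,
            "mean_fpc_tree": float(run.fpc[TREE].mean()),
            "mean_fpc_c3": float(run.fpc[C3G].mean()),
            "mean_fpc_c4": float(run.fpc[C4G].mean()),
            "mean_burned_frac": float(run.burned_frac.mean()),
        })
    if rows:
        pd.DataFrame(rows).to_csv(out / "run_summary.csv", index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
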