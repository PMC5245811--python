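"""Forcing readers/writers and run-output serialization.

netCDF (through xarray's scipy backend) for gridded fields, CSV for site
series and tabular output.  Units are carried as attributes and coerced at
the boundary: internally NPP is always mg C m^-2 d^-1 and temperature degC.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .ecology import Forcing
from .simulator import RunResult

__all__ = ["read_forcing", "write_forcing_netcdf", "write_annual_csv", "write_provenance"]

_NPP_CONVERSIONS = {
    "mg c m-2 d-1": 1.0,
    "mg c m^-2 d^-1": 1.0,
    "g c m-2 yr-1": 1000.0 / 365.25,
    "g c m^-2 yr^-1": 1000.0 / 365.25,
}


def _npp_factor(units: str | None) -> float:
    if units is None:
        raise ValueError("npp variable is missing a 'units' attribute")
    key = units.strip().lower()
    if key not in _NPP_CONVERSIONS:
        raise ValueError(
            f"unsupported npp units {units!r}; expected one of {sorted(_NPP_CONVERSIONS)}"
        )
    return _NPP_CONVERSIONS[key]


def read_forcing(path: str | Path) -> Forcing:
    """Read a forcing file (netCDF grid or per-site CSV).

    netCDF: variables ``npp`` (with a units attribute) and ``temperature``
    over dims (lat, lon[, month]); cells with missing values are dropped and
    spherical cell areas are computed from latitude.  CSV: columns time,
    npp, temperature; 12 rows are interpreted as a cyclic monthly
    climatology for a single site.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        return _read_forcing_netcdf(path)
    return _read_forcing_csv(path)


def _read_forcing_csv(path: Path) -> Forcing:
    df = pd.read_csv(path)
    missing = {"npp", "temperature"} - set(df.columns)
    if missing:
        raise ValueError(f"forcing CSV missing columns: {sorted(missing)}")
    npp = df["npp"].to_numpy(float)
    temp = df["temperature"].to_numpy(float)
    if len(df) == 12:  # monthly climatology, single site
        return Forcing(npp=npp[None, :], temperature=temp[None, :], area=np.array([1.0]))
    if len(df) == 1:
        return Forcing(npp=npp, temperature=temp, area=np.array([1.0]))
    # annual-average multi-site table
    return Forcing(npp=npp, temperature=temp, area=np.ones(len(df)))


EARTH_RADIUS_M = 6.371e6


def cell_areas_from_lat(lat: np.ndarray, dlat: float, dlon: float) -> np.ndarray:
    """Spherical cell areas (m^2) for a regular lat-lon grid."""
    lat_r = np.deg2rad(lat)
    return (
        EARTH_RADIUS_M**2
        * np.deg2rad(dlon)
        * (np.sin(lat_r + np.deg2rad(dlat) / 2) - np.sin(lat_r - np.deg2rad(dlat) / 2))
    )


def _read_forcing_netcdf(path: Path) -> Forcing:
    with xr.open_dataset(path, engine="scipy") as ds:
        for var in ("npp", "temperature"):
            if var not in ds:
                raise ValueError(f"forcing file missing variable {var!r}")
        factor = _npp_factor(ds["npp"].attrs.get("units"))
        npp = ds["npp"].values * factor
        temp = ds["temperature"].values
        lat = ds["lat"].values
        lon = ds["lon"].values
    dlat = float(np.abs(np.diff(lat)).mean()) if lat.size > 1 else 1.0
    dlon = float(np.abs(np.diff(lon)).mean()) if lon.size > 1 else 1.0
    area_row = cell_areas_from_lat(lat, dlat, dlon)  # (lat,)
    if npp.ndim == 3:  # (month, lat, lon) or (lat, lon, month)
        if npp.shape[0] == 12:
            npp = np.moveaxis(npp, 0, -1)
            temp = np.moveaxis(temp, 0, -1)
        flat_npp = npp.reshape(-1, 12)
        flat_temp = temp.reshape(-1, 12)
    else:
        flat_npp = npp.reshape(-1)
        flat_temp = temp.reshape(-1)
    area = np.repeat(area_row[:, None], lon.size, axis=1).reshape(-1)
    valid = np.all(np.isfinite(np.atleast_2d(flat_npp.T)), axis=0) & np.all(
        np.isfinite(np.atleast_2d(flat_temp.T)), axis=0
    )
    return Forcing(
        npp=flat_npp[valid], temperature=flat_temp[valid], area=area[valid]
    )


def write_forcing_netcdf(forcing: Forcing, path: str | Path, lat=None, lon=None) -> None:
    """Write a cell-list forcing back to netCDF (round-trips with
    :func:`read_forcing` for 1D lat/lon layouts)."""
    n = forcing.n_cells
    lat = np.asarray(lat) if lat is not None else np.arange(n, dtype=float)
    lon = np.asarray(lon) if lon is not None else np.array([0.0])
    shape = (lat.size, lon.size)
    if forcing.n_phases > 1:
        dims = ("lat", "lon", "month")
        npp = forcing.npp.reshape(shape + (12,))
        temp = forcing.temperature.reshape(shape + (12,))
        coords = {"lat": lat, "lon": lon, "month": np.arange(1, 13)}
    else:
        dims = ("lat", "lon")
        npp = forcing.npp.reshape(shape)
        temp = forcing.temperature.reshape(shape)
        coords = {"lat": lat, "lon": lon}
    ds = xr.Dataset(
        {
            "npp": (dims, npp, {"units": "mg C m-2 d-1"}),
            "temperature": (dims, temp, {"units": "degC"}),
        },
        coords=coords,
    )
    ds.to_netcdf(path, engine="scipy")


def write_annual_csv(result: RunResult, path: str | Path) -> None:
    """Annual aggregate series (biomass, per-group harvest, effort) as CSV."""
    labels = [g.label for g in result.community]
    df = pd.DataFrame({"year": result.years, "q": result.q, "biomass_gwB_m2": result.biomass})
    for i, lab in enumerate(labels):
        df[f"harvest_{lab}_gwB_m2_yr"] = result.harvest[i]
        df[f"effort_{lab}_W_m2"] = result.effort[i]
    df.to_csv(path, index=False)


def write_provenance(path: str | Path, *, config_hash: str, seed: int, **extra) -> None:
    """JSON sidecar binding outputs to the config hash and seed."""
    doc = {"config_hash": config_hash, "seed": seed, **extra}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
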