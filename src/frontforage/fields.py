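"""Synthetic frontal-intensity (FSLE-like) raster fields.

The backward-in-time finite-size Lyapunov exponent maps convergent transport
fronts in altimetry-derived surface currents: the diagnostic is non-positive,
and filaments ("ridges") of strongly negative values trace the fronts that
aggregate prey.  Downstream analyses only need the statistical shape of such
a field — smooth, ridge-dominated, temporally autocorrelated — so the
generator builds it as a band-pass-filtered (difference-of-Gaussians) random
surface whose high-|value| ridges are elongated filaments, not by Lagrangian
particle advection.

Fields are carried as an :class:`xarray.DataArray` with ``(time, lat, lon)``
dimensions (CF-style), values in d^-1 and, like the real product, <= 0;
consumers take absolute values ("transformed to a positive scale").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .projection import LocalProjection


@dataclass(frozen=True)
class FieldParams:
    """Geometry and texture of the synthetic frontal field.

    extent_km        half-width of the square domain around the colony
    res_km           nominal grid spacing (the Aviso product is ~4 km)
    ridge_density    relative amplitude of the filament texture; 0 gives a
                     field that is identically zero (no-front limit)
    ridge_scale_km   width of the filaments (band-pass centre scale)
    temporal_rho     day-to-day AR(1) correlation of the underlying surface
    n_days           number of daily snapshots
    start            first day (ISO date)
    max_intensity    |FSLE| scale of the strongest ridges, d^-1
    """

    extent_km: float = 150.0
    res_km: float = 5.0
    ridge_density: float = 1.0
    ridge_scale_km: float = 15.0
    temporal_rho: float = 0.8
    n_days: int = 40
    start: str = "2015-06-01"
    max_intensity: float = 1.0


def simulate_fsle_field(
    params: FieldParams,
    colony: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> xr.DataArray:
    """Simulate a daily frontal-intensity raster centred on the colony.

    Returns a DataArray ``(time, lat, lon)`` of non-positive values (d^-1).
    Ridges are the loci of large ``|value|``.  Deterministic for a fixed
    seed.  Raises ``ValueError`` on a degenerate (zero-cell) extent.
    """
    rng = np.random.default_rng(seed)
    proj = LocalProjection(*colony)

    half_m = params.extent_km * 1000.0
    n_cells = int(round(2 * params.extent_km / params.res_km)) + 1
    if n_cells < 2 or params.extent_km <= 0:
        raise ValueError("degenerate field extent: no grid cells")

    # Regular lon/lat lattice spanning the projected square.
    xs = np.linspace(-half_m, half_m, n_cells)
    lon_w, _ = proj.inverse(-half_m, 0.0)
    lon_e, _ = proj.inverse(half_m, 0.0)
    _, lat_s = proj.inverse(0.0, -half_m)
    _, lat_n = proj.inverse(0.0, half_m)
    lons = np.linspace(lon_w, lon_e, n_cells)
    lats = np.linspace(lat_s, lat_n, n_cells)

    sigma_hi = max(params.ridge_scale_km / params.res_km, 0.6)
    sigma_lo = 2.5 * sigma_hi

    # AR(1) white-noise stack -> band-pass -> |.| gives filamentary ridges.
    rho = params.temporal_rho
    noise = rng.standard_normal((params.n_days, n_cells, n_cells))
    for t in range(1, params.n_days):
        noise[t] = rho * noise[t - 1] + np.sqrt(1.0 - rho**2) * noise[t]

    vals = np.empty_like(noise)
    for t in range(params.n_days):
        hi = ndimage.gaussian_filter(noise[t], sigma_hi, mode="wrap")
        lo = ndimage.gaussian_filter(noise[t], sigma_lo, mode="wrap")
        vals[t] = np.abs(hi - lo)

    scale = vals.max()
    if scale > 0 and params.ridge_density > 0:
        vals *= params.ridge_density * params.max_intensity / scale
    else:
        vals[:] = 0.0

    times = pd.date_range(params.start, periods=params.n_days, freq="D")
    da = xr.DataArray(
        -vals,  # backward FSLE is non-positive
        coords={"time": times, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name="fsle",
        attrs={
            "units": "1/day",
            "long_name": "backward finite-size Lyapunov exponent (synthetic)",
            "colony_lon": colony[0],
            "colony_lat": colony[1],
        },
    )
    da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    if not np.isfinite(da.values).all():
        raise AssertionError("non-finite values in simulated field")
    return da


def save_field(da: xr.DataArray, path) -> None:
    """Write the field as classic NetCDF (CF conventions, scipy backend)."""
    da.to_dataset(name="fsle").to_netcdf(path, engine="scipy")


def load_field(path) -> xr.DataArray:
    """Read a field written by :func:`save_field`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds["fsle"].load()


def sample_field(da: xr.DataArray, lon, lat, time) -> np.ndarray:
    """Nearest-cell, nearest-day sample of the field at query points.

    ``time`` may be a scalar or array of datetimes.  Queries outside the
    spatial grid use the nearest edge cell; queries outside the temporal
    coverage raise ``ValueError`` naming the offending date.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(time, dtype="datetime64[ns]")))

    times = pd.DatetimeIndex(da["time"].values)
    lo, hi = times.min(), times.max()
    bad = (t < lo - pd.Timedelta(days=1)) | (t > hi + pd.Timedelta(days=1))
    if bad.any():
        raise ValueError(
            f"fix at {t[bad][0]} is outside field temporal coverage "
            f"[{lo.date()} .. {hi.date()}]"
        )
    ti = times.get_indexer(t, method="nearest")
    lati = _nearest_index(da["lat"].values, lat)
    loni = _nearest_index(da["lon"].values, lon)
    return da.values[ti, lati, loni]


def _nearest_index(coord: np.ndarray, q: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(coord, q)
    idx = np.clip(idx, 1, len(coord) - 1)
    left = coord[idx - 1]
    right = coord[idx]
    idx -= q - left < right - q
    return np.clip(idx, 0, len(coord) - 1)
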