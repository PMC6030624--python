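"""Trip segmentation, regularization, trip metrics and covariate attachment.

Raw GPS fixes become foraging trips by the central-place rule: maximal runs
of fixes more than ``radius_km`` from the colony that last longer than
``min_duration_min`` (everything else is colony attendance or rafting and is
excluded).  Trips are regularized by linear interpolation of the projected
coordinates onto an exact fix-interval lattice, turned into step-length /
turning-angle series, and annotated with the frontal-intensity covariate
sampled at each step's origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.stats import circmean

from .fields import sample_field
from .projection import LocalProjection, bearing, wrap_angle

AGE_CODE = {"adult": 0, "immature": 1}


@dataclass
class Trip:
    """A contiguous at-sea segment of one bird's fixes.

    ``fixes`` columns: ``time`` (UTC), ``lon, lat`` (degrees), ``x, y``
    (projected metres), plus provenance flags after regularization
    (``interpolated``, ``in_long_gap``).
    """

    trip_id: str
    bird_id: str
    age_class: str
    fixes: pd.DataFrame
    regular: bool = False
    interval_s: float | None = None

    @property
    def age(self) -> int:
        return AGE_CODE[self.age_class]

    def __len__(self):
        return len(self.fixes)


@dataclass
class TripMetrics:
    """The seven per-trip characteristics used for group comparisons."""

    trip_id: str
    bird_id: str
    age_class: str
    duration_h: float
    length_km: float
    departure_angle: float
    range_km: float
    terminal_x: float
    terminal_y: float
    area_km2: float
    n_departure_bearings: int = 5

    def as_row(self) -> dict:
        return {
            "trip_id": self.trip_id,
            "bird_id": self.bird_id,
            "age_class": self.age_class,
            "duration_h": self.duration_h,
            "length_km": self.length_km,
            "departure_angle": self.departure_angle,
            "range_km": self.range_km,
            "terminal_x": self.terminal_x,
            "terminal_y": self.terminal_y,
            "area_km2": self.area_km2,
            "n_departure_bearings": self.n_departure_bearings,
        }


@dataclass
class StepSeries:
    """Per-trip HMM observation sequence.

    ``steps`` are km per fix interval; ``turns`` are signed heading changes
    in (-pi, pi] with NaN where undefined (sequence start and either side of
    a zero-length step); ``covariate`` holds |FSLE| at each step's origin.
    """

    trip_id: str
    bird_id: str
    age: int
    steps: np.ndarray
    turns: np.ndarray
    covariate: np.ndarray
    times: np.ndarray = None
    x: np.ndarray = None
    y: np.ndarray = None
    covariate_flag: np.ndarray = dc_field(default=None)

    def __len__(self):
        return len(self.steps)


def read_tracks(path) -> pd.DataFrame:
    """Read a track CSV (bird_id, age_class, timestamp, lon, lat)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    return df


def segment_trips(
    fixes: pd.DataFrame,
    colony: tuple[float, float],
    radius_km: float = 10.0,
    min_duration_min: float = 40.0,
) -> list[Trip]:
    """Extract foraging trips from raw fixes of one or many birds.

    A trip is a maximal run of consecutive fixes more than ``radius_km``
    (projected distance) from the colony whose first-to-last time span
    exceeds ``min_duration_min``.  Shorter excursions are discarded; birds
    with no qualifying run yield no trips.
    """
    proj = LocalProjection(*colony)
    trips: list[Trip] = []
    for bird_id, g in fixes.groupby("bird_id", sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        x, y = proj.forward(g["lon"].values, g["lat"].values)
        away = np.hypot(x, y) > radius_km * 1000.0
        age_class = str(g["age_class"].iloc[0])
        k = 0
        for lo, hi in _runs(away):
            dur_min = (
                g["timestamp"].iloc[hi - 1] - g["timestamp"].iloc[lo]
            ).total_seconds() / 60.0
            if dur_min <= min_duration_min:
                continue
            sub = pd.DataFrame(
                {
                    "time": g["timestamp"].iloc[lo:hi].values,
                    "lon": g["lon"].iloc[lo:hi].values,
                    "lat": g["lat"].iloc[lo:hi].values,
                    "x": x[lo:hi],
                    "y": y[lo:hi],
                }
            )
            trips.append(
                Trip(
                    trip_id=f"{bird_id}_t{k:02d}",
                    bird_id=str(bird_id),
                    age_class=age_class,
                    fixes=sub,
                )
            )
            k += 1
    return trips


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs."""
    if mask.size == 0:
        return
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    yield from zip(starts, stops)


def regularize(
    trip: Trip,
    interval_s: float = 120.0,
    gap_flag_s: float = 1800.0,
    colony: tuple[float, float] | None = None,
) -> Trip:
    """Linear interpolation of projected positions onto an exact lattice.

    The lattice starts at the trip's first fix.  Fixes created inside raw
    gaps longer than ``gap_flag_s`` are flagged ``in_long_gap``; every
    non-coincident fix is flagged ``interpolated``.  Idempotent on trips
    already on the lattice.  A single-fix trip is an error.
    """
    f = trip.fixes
    if len(f) < 2:
        raise ValueError(f"trip {trip.trip_id}: cannot regularize <2 fixes")
    t = (f["time"] - f["time"].iloc[0]).dt.total_seconds().values.astype(float)
    n_out = int(np.floor(t[-1] / interval_s)) + 1
    tq = np.arange(n_out) * interval_s
    xq = np.interp(tq, t, f["x"].values)
    yq = np.interp(tq, t, f["y"].values)
    # provenance: which raw inter-fix gap each lattice point falls into
    idx = np.searchsorted(t, tq, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 2)
    gap_len = t[idx + 1] - t[idx]
    coincident = np.isin(tq, t)
    proj = LocalProjection(*(colony if colony is not None else (0.0, 0.0)))
    if colony is not None:
        lon, lat = proj.inverse(xq, yq)
    else:
        lon = np.interp(tq, t, f["lon"].values)
        lat = np.interp(tq, t, f["lat"].values)
    out = pd.DataFrame(
        {
            "time": f["time"].iloc[0] + pd.to_timedelta(tq, unit="s"),
            "lon": lon,
            "lat": lat,
            "x": xq,
            "y": yq,
            "interpolated": ~coincident,
            "in_long_gap": (~coincident) & (gap_len > gap_flag_s),
        }
    )
    return replace(trip, fixes=out, regular=True, interval_s=interval_s)


def steps_and_turns(trip: Trip) -> StepSeries:
    """Step lengths (km) and signed turning angles (rad) of a regular trip.

    ``turns[i]`` is the heading change entering step ``i``; the first turn
    and any turn adjacent to a zero-length step are NaN (undefined).
    """
    if not trip.regular:
        raise ValueError("steps_and_turns expects a regularized trip")
    x = trip.fixes["x"].values
    y = trip.fixes["y"].values
    dx = np.diff(x)
    dy = np.diff(y)
    steps = np.hypot(dx, dy) / 1000.0
    heading = np.arctan2(dx, dy)
    turns = np.full(len(steps), np.nan)
    if len(steps) > 1:
        turns[1:] = wrap_angle(heading[1:] - heading[:-1])
        zero = steps == 0.0
        turns[np.flatnonzero(zero)] = np.nan
        after = np.flatnonzero(zero[:-1]) + 1
        turns[after] = np.nan
    turns[0] = np.nan
    return StepSeries(
        trip_id=trip.trip_id,
        bird_id=trip.bird_id,
        age=trip.age,
        steps=steps,
        turns=turns,
        covariate=np.zeros(len(steps)),
        times=trip.fixes["time"].values[:-1],
        x=x[:-1],
        y=y[:-1],
    )


def trip_metrics(
    trip: Trip,
    colony: tuple[float, float],
    departure_radius_km: float = 10.0,
    n_bearings: int = 5,
) -> TripMetrics:
    """The seven trip characteristics of a regularized trip.

    Departure angle is the circular mean of the first ``n_bearings``
    colony-to-bird bearings at fixes beyond ``departure_radius_km``; if fewer
    qualify, all available are used and ``n_departure_bearings`` records how
    many.  Area is the convex hull (minimum convex polygon) of the fixes.
    """
    proj = LocalProjection(*colony)
    f = trip.fixes
    x, y = proj.forward(f["lon"].values, f["lat"].values)
    dist = np.hypot(x, y)
    duration_h = (
        f["time"].iloc[-1] - f["time"].iloc[0]
    ).total_seconds() / 3600.0
    length_km = float(np.hypot(np.diff(x), np.diff(y)).sum() / 1000.0)
    far = np.flatnonzero(dist > departure_radius_km * 1000.0)
    use = far[:n_bearings]
    if len(use) == 0:
        dep = np.nan
    else:
        brngs = bearing(0.0, 0.0, x[use], y[use])
        dep = float(circmean(brngs, high=np.pi, low=-np.pi))
        dep = wrap_angle(dep)
    imax = int(np.argmax(dist))
    pts = np.column_stack([x, y]) / 1000.0
    if len(np.unique(pts, axis=0)) >= 3:
        try:
            area = float(ConvexHull(pts).volume)  # 2-D: volume is the area
        except Exception:
            area = 0.0
    else:
        area = 0.0
    return TripMetrics(
        trip_id=trip.trip_id,
        bird_id=trip.bird_id,
        age_class=trip.age_class,
        duration_h=float(duration_h),
        length_km=length_km,
        departure_angle=dep,
        range_km=float(dist[imax] / 1000.0),
        terminal_x=float(x[imax]),
        terminal_y=float(y[imax]),
        area_km2=area,
        n_departure_bearings=int(len(use)),
    )


def metrics_table(trips, colony) -> pd.DataFrame:
    """Trip-metrics rows for a list of regularized trips."""
    return pd.DataFrame([trip_metrics(t, colony).as_row() for t in trips])


def mcp_geojson(trips, colony, path) -> None:
    """Write each trip's minimum convex polygon as GeoJSON (lon/lat)."""
    import json

    from shapely.geometry import MultiPoint, mapping

    proj = LocalProjection(*colony)
    features = []
    for tr in trips:
        hull = MultiPoint(
            list(zip(tr.fixes["x"].values, tr.fixes["y"].values))
        ).convex_hull
        if hull.geom_type != "Polygon":
            continue
        xs, ys = hull.exterior.coords.xy
        lon, lat = proj.inverse(np.asarray(xs), np.asarray(ys))
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[round(a, 6), round(b, 6)] for a, b in zip(lon, lat)]
                    ],
                },
                "properties": {"trip_id": tr.trip_id, "bird_id": tr.bird_id},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def attach_covariate(series: StepSeries, fsle, colony) -> StepSeries:
    """Sample |FSLE| at each step's origin fix, nearest field day.

    The frontal covariate is the absolute value of the (non-positive)
    backward FSLE ("transformed to a positive scale").  Cells missing in the
    raster propagate as NaN and are flagged.
    """
    proj = LocalProjection(*colony)
    lon, lat = proj.inverse(series.x, series.y)
    vals = np.abs(sample_field(fsle, lon, lat, series.times))
    flag = ~np.isfinite(vals)
    if flag.any():
        vals = _fill_nearest(vals, series.x, series.y)
        flag = ~np.isfinite(vals)
    return replace(series, covariate=vals, covariate_flag=flag)


def _fill_nearest(vals, x, y, radius_m=50_000.0):
    """Fill NaN covariates from the nearest finite-valued step within radius."""
    out = vals.copy()
    ok = np.isfinite(vals)
    if not ok.any():
        return out
    for i in np.flatnonzero(~ok):
        d2 = (x[ok] - x[i]) ** 2 + (y[ok] - y[i]) ** 2
        j = np.argmin(d2)
        if d2[j] <= radius_m**2:
            out[i] = vals[ok][j]
    return out


def prepare_series(
    trips,
    fsle,
    colony,
    interval_s: float = 120.0,
) -> list[StepSeries]:
    """Regularize, derive steps/turns and attach covariates for many trips."""
    out = []
    for tr in trips:
        reg = tr if tr.regular else regularize(tr, interval_s, colony=colony)
        if len(reg) < 3:
            continue
        s = steps_and_turns(reg)
        out.append(attach_covariate(s, fsle, colony))
    return out
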