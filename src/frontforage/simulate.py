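"""Generative model for GPS-tracked central-place foraging trips.

The simulator runs the movement HMM forwards: a latent 3-state chain (rest,
forage, transit) whose transition probabilities follow the multinomial-logit
regression on local frontal intensity, age class and their interaction, with
state-dependent gamma step lengths and von Mises turning angles at a fixed
fix interval.  Birds are central-place foragers: every trip leaves the colony,
ranges over a synthetic frontal field, and is steered home once a drawn trip
duration is exceeded.  The hidden state sequence is recorded per fix as ground
truth, so every downstream stage (trip segmentation, HMM fitting, space-use
overlap, repeatability) can be validated against known parameters.

Trip geometry guarantees: the outbound leg is forced to transit until the
track passes the trip-definition radius, and the return leg steers the
transit-state heading toward the colony, so the segmentation rule ("more than
10 km from the colony for more than 40 min") recovers exactly one trip per
simulated trip when dropout is zero.  Only the state-transition process is
perturbed by this steering; emissions are always drawn from the
state-dependent distributions, keeping emission-parameter recovery clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .fields import FieldParams, simulate_fsle_field
from .hmm import N_STATES, EmissionParams, TransitionModel, transition_matrix
from .projection import LocalProjection, wrap_angle

#: Bass Rock, Firth of Forth, Scotland (lon, lat).
BASS_ROCK = (-2.64, 56.08)

#: Reported state-dependent distributions: rest, forage, transit.
DEFAULT_EMISSIONS = EmissionParams(
    step_mean=np.array([0.03, 0.41, 1.66]),
    step_sd=np.array([0.02, 0.54, 0.43]),
    turn_mu=np.zeros(3),
    turn_kappa=np.array([22.3, 1.0, 27.1]),
)

#: Transition coefficients on the natural |FSLE| scale, design "fsle*age",
#: rows in TRANSITION_ROWS order (rest->forage, rest->transit, forage->rest,
#: forage->transit, transit->rest, transit->forage); columns
#: (1, fsle, age, fsle:age).  Adults (age 0) switch from transit to foraging
#: increasingly with frontal intensity and hold foraging on fronts; immatures
#: (age 1) respond far more weakly and rest more.
DEFAULT_BETA = np.array(
    [
        [-1.9, 0.0, 0.0, 0.0],  # rest -> forage
        [-1.7, 0.0, -0.8, 0.0],  # rest -> transit
        [-2.8, 0.0, 1.0, 0.0],  # forage -> rest
        [-1.8, -2.0, 0.0, 1.5],  # forage -> transit
        [-3.0, 0.0, 1.0, 0.0],  # transit -> rest
        [-2.2, 2.5, 0.0, -2.0],  # transit -> forage
    ]
)


@dataclass(frozen=True)
class AgeProfile:
    """Per-age-class cohort structure and departure-heading behaviour.

    ``trips_range``            inclusive (lo, hi) trips per bird
    ``pop_heading_kappa``      concentration of bird-level preferred headings
                               around ``pop_heading_mu`` (0 = uniform)
    ``trip_heading_kappa``     concentration of per-trip departure headings
                               around the bird's preferred heading; large
                               values give strong foraging-site fidelity
    """

    trips_range: tuple[int, int]
    pop_heading_mu: float = 0.0
    pop_heading_kappa: float = 0.0
    trip_heading_kappa: float = 1.0


#: Default cohort: the study's 31 adults / 15 immatures with unbalanced trip
#: counts (~4 vs ~8 per bird, ~247 trips).  Adults repeat bird-specific
#: departure headings drawn from a concentrated population distribution
#: (narrow group range, high site fidelity); immatures disperse widely with
#: low fidelity.
DEFAULT_AGE_PROFILES = {
    "adult": AgeProfile((3, 5), pop_heading_mu=0.9, pop_heading_kappa=3.0,
                        trip_heading_kappa=8.0),
    "immature": AgeProfile((7, 9), pop_heading_mu=0.0, pop_heading_kappa=0.0,
                           trip_heading_kappa=0.6),
}


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic tracking cohort."""

    n_adults: int = 31
    n_immatures: int = 15
    colony: tuple[float, float] = BASS_ROCK
    fix_interval_s: float = 120.0
    state_params: EmissionParams = dc_field(
        default_factory=lambda: DEFAULT_EMISSIONS
    )
    beta: np.ndarray = dc_field(default_factory=lambda: DEFAULT_BETA.copy())
    field_params: FieldParams = dc_field(default_factory=FieldParams)
    age_profiles: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_AGE_PROFILES)
    )
    trip_duration_h: tuple[float, float] = (1.0, 2.4)
    trip_radius_km: float = 10.0
    exit_radius_km: float = 12.0
    colony_dwell_fixes: tuple[int, int] = (5, 20)
    dropout_rate: float = 0.0
    dropout_mean_len: float = 3.0
    seed: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.n_adults < 0 or self.n_immatures < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.n_adults + self.n_immatures == 0:
            raise ValueError("cohort must contain at least one bird")
        if self.fix_interval_s <= 0:
            raise ValueError("fix interval must be positive")
        for age, prof in self.age_profiles.items():
            lo, hi = prof.trips_range
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid trips_range for {age!r}")
        if self.beta.shape != (6, 4):
            raise ValueError("beta must be 6x4 (design 'fsle*age')")
        em = self.state_params
        if not (np.all(em.step_mean > 0) and np.all(em.turn_kappa > 0)):
            raise ValueError("state parameters must be positive")


@dataclass
class CohortData:
    """A simulated cohort: the track table, per-fix truth, and the field."""

    tracks: pd.DataFrame
    truth: pd.DataFrame
    fsle: xr.DataArray
    config: SimConfig

    def write(self, tracks_csv, truth_csv=None, fsle_nc=None):
        from .fields import save_field

        self.tracks.to_csv(tracks_csv, index=False)
        if truth_csv is not None:
            self.truth.to_csv(truth_csv, index=False)
        if fsle_nc is not None:
            save_field(self.fsle, fsle_nc)


class _FieldSampler:
    """Fast nearest-cell, nearest-day lookup in projected coordinates."""

    def __init__(self, da: xr.DataArray, proj: LocalProjection):
        self.vals = np.abs(da.values)  # transition covariate is |FSLE|
        lats = da["lat"].values
        lons = da["lon"].values
        self.lat0, self.dlat, self.nlat = lats[0], lats[1] - lats[0], len(lats)
        self.lon0, self.dlon, self.nlon = lons[0], lons[1] - lons[0], len(lons)
        self.t0 = pd.Timestamp(da["time"].values[0])
        self.n_days = self.vals.shape[0]
        self.proj = proj

    def at(self, x: float, y: float, seconds: float) -> float:
        lon, lat = self.proj.inverse(x, y)
        i = min(max(int(round((float(lat) - self.lat0) / self.dlat)), 0),
                self.nlat - 1)
        j = min(max(int(round((float(lon) - self.lon0) / self.dlon)), 0),
                self.nlon - 1)
        d = min(max(int(seconds // 86400.0), 0), self.n_days - 1)
        return float(self.vals[d, i, j])


def _gamma_draw(rng, mean, sd):
    shape = mean * mean / (sd * sd)
    scale = sd * sd / mean
    return rng.gamma(shape, scale)


def _simulate_trip(cfg, rng, sampler, tm, age_num, heading0, t_start_s):
    """One trip in the colony plane; returns (x, y, state, seconds) arrays."""
    em = cfg.state_params
    dt = cfg.fix_interval_s
    radius_m = cfg.trip_radius_km * 1000.0
    exit_m = cfg.exit_radius_km * 1000.0
    extent_m = cfg.field_params.extent_km * 1000.0 * 0.92
    dur_s = rng.uniform(*cfg.trip_duration_h) * 3600.0
    max_steps = int(dur_s / dt)
    cap = 4 * max_steps + 200

    x, y = 0.0, 0.0
    h = heading0
    state = 2  # transit out
    xs, ys, states, tts = [x], [y], [state], [t_start_s]
    t_s = t_start_s
    forced_home = False
    left_colony = False
    for n in range(cap):
        t_s += dt
        dist = math.hypot(x, y)
        if dist >= exit_m:
            left_colony = True
        returning = n > max_steps or forced_home
        outbound = not left_colony and not returning

        if outbound or (returning and dist < radius_m * 1.1):
            state = 2  # forced transit: leaving, or on final approach home
        else:
            z = sampler.at(x, y, t_s)
            gam = transition_matrix(tm, {"fsle": z, "age": age_num})
            state = int(rng.choice(N_STATES, p=gam[state]))

        step_m = _gamma_draw(rng, em.step_mean[state], em.step_sd[state]) * 1000.0
        if returning and state == 2:
            # steer the transit heading home; the von Mises noise keeps the
            # turning-angle distribution of the state
            mu_eff = wrap_angle(math.atan2(-x, -y) - h)
        elif outbound:
            mu_eff = 0.0
        else:
            mu_eff = em.turn_mu[state]
        turn = rng.vonmises(mu_eff, em.turn_kappa[state])
        h = wrap_angle(h + turn)

        # reflective barriers: stay at sea until returning, stay on the field
        if not returning and not outbound:
            if dist > extent_m:
                h = wrap_angle(math.atan2(-x, -y) + rng.vonmises(0.0, 8.0))
            elif dist < radius_m * 1.2:
                away = math.atan2(x, y)
                if math.cos(h - away) < 0.3:  # require an outward component
                    h = wrap_angle(away + rng.vonmises(0.0, 8.0))

        nx = x + step_m * math.sin(h)
        ny = y + step_m * math.cos(h)
        if not returning and not outbound:
            # hard barrier: the free phase never re-enters the trip radius
            tries = 0
            while math.hypot(nx, ny) < radius_m * 1.02 and tries < 8:
                h = wrap_angle(
                    math.atan2(x, y)
                    + (rng.vonmises(0.0, 8.0) if tries < 7 else 0.0)
                )
                nx = x + step_m * math.sin(h)
                ny = y + step_m * math.cos(h)
                tries += 1
        x, y = nx, ny
        xs.append(x)
        ys.append(y)
        states.append(state)
        tts.append(t_s)

        if returning and math.hypot(x, y) < 700.0:
            break
        if n == cap - 50:
            forced_home = True  # tail guard: finish the trip in transit
    # close the trip at the colony
    xs.append(0.0)
    ys.append(0.0)
    states.append(2)
    tts.append(t_s + dt)
    return (
        np.array(xs),
        np.array(ys),
        np.array(states, dtype=int),
        np.array(tts),
    )


def simulate_track(
    cfg: SimConfig,
    bird_id: str,
    age_class: str,
    fsle: xr.DataArray,
    seed,
    start_s: float | None = None,
) -> pd.DataFrame:
    """Simulate one bird's full track (trips separated by colony dwell).

    Returns a per-fix frame with ``bird_id, age_class, timestamp, lon, lat``
    plus truth columns ``x, y, state, trip_index`` (state 0 = at colony,
    otherwise 1 rest / 2 forage / 3 transit).
    """
    rng = np.random.default_rng(seed)
    proj = LocalProjection(*cfg.colony)
    sampler = _FieldSampler(fsle, proj)
    tm = TransitionModel("fsle*age", cfg.beta)
    prof: AgeProfile = cfg.age_profiles[age_class]
    age_num = 0.0 if age_class == "adult" else 1.0
    dt = cfg.fix_interval_s

    span_s = (sampler.n_days - 1) * 86400.0
    if start_s is None:
        start_s = rng.uniform(0.0, max(span_s - 2 * 86400.0, 0.0))

    if prof.pop_heading_kappa > 0:
        bird_mu = rng.vonmises(prof.pop_heading_mu, prof.pop_heading_kappa)
    else:
        bird_mu = rng.uniform(-math.pi, math.pi)

    n_trips = int(rng.integers(prof.trips_range[0], prof.trips_range[1] + 1))
    xs, ys, states, tts, trip_idx = [], [], [], [], []
    t_s = float(start_s)
    for k in range(n_trips):
        dwell = int(rng.integers(*cfg.colony_dwell_fixes))
        for _ in range(dwell):
            xs.append(0.0)
            ys.append(0.0)
            states.append(0)
            tts.append(t_s)
            trip_idx.append(-1)
            t_s += dt
        if prof.trip_heading_kappa > 0:
            h0 = rng.vonmises(bird_mu, prof.trip_heading_kappa)
        else:
            h0 = rng.uniform(-math.pi, math.pi)
        tx, ty, tst, ttt = _simulate_trip(
            cfg, rng, sampler, tm, age_num, h0, t_s
        )
        xs.extend(tx)
        ys.extend(ty)
        states.extend(tst + 1)  # truth codes: 0 colony, 1 rest, 2 forage, 3 transit
        tts.extend(ttt)
        trip_idx.extend([k] * len(tx))
        t_s = ttt[-1] + dt
    # trailing colony fixes so the last trip is bounded on both sides
    for _ in range(3):
        xs.append(0.0)
        ys.append(0.0)
        states.append(0)
        tts.append(t_s)
        trip_idx.append(-1)
        t_s += dt

    x = np.asarray(xs)
    y = np.asarray(ys)
    lon, lat = proj.inverse(x, y)
    times = sampler.t0 + pd.to_timedelta(np.asarray(tts), unit="s")
    df = pd.DataFrame(
        {
            "bird_id": bird_id,
            "age_class": age_class,
            "timestamp": times,
            "lon": np.round(lon, 6),
            "lat": np.round(lat, 6),
            "x": x,
            "y": y,
            "state": np.asarray(states, dtype=int),
            "trip_index": np.asarray(trip_idx, dtype=int),
        }
    )
    if cfg.dropout_rate > 0:
        keep = np.ones(len(df), dtype=bool)
        i = 1
        while i < len(df) - 1:
            if rng.random() < cfg.dropout_rate:
                gap = 1 + rng.geometric(1.0 / cfg.dropout_mean_len)
                keep[i : min(i + gap, len(df) - 1)] = False
                i += gap
            i += 1
        df = df[keep].reset_index(drop=True)
    return df


def simulate_cohort(cfg: SimConfig) -> CohortData:
    """Simulate the frontal field and every bird in the cohort.

    Deterministic for a fixed ``cfg.seed``: per-bird generators are spawned
    from one seed sequence, so outputs are byte-identical across runs.
    """
    root = np.random.SeedSequence(cfg.seed)
    field_seed, *bird_seeds = root.spawn(
        1 + cfg.n_adults + cfg.n_immatures
    )
    fsle = simulate_fsle_field(
        cfg.field_params, cfg.colony, np.random.default_rng(field_seed)
    )
    frames = []
    birds = [("A", i, "adult") for i in range(cfg.n_adults)] + [
        ("I", i, "immature") for i in range(cfg.n_immatures)
    ]
    for (tag, i, age), bs in zip(birds, bird_seeds):
        bird_id = f"{tag}{i + 1:03d}"
        frames.append(
            simulate_track(cfg, bird_id, age, fsle, np.random.default_rng(bs))
        )
    full = pd.concat(frames, ignore_index=True)
    tracks = full[["bird_id", "age_class", "timestamp", "lon", "lat"]].copy()
    tracks["timestamp"] = tracks["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    truth = full[
        ["bird_id", "age_class", "timestamp", "x", "y", "state", "trip_index"]
    ].copy()
    truth["timestamp"] = truth["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    return CohortData(tracks=tracks, truth=truth, fsle=fsle, config=cfg)
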