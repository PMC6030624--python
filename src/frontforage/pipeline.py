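"""End-to-end pipeline: simulate -> preprocess -> HMM -> space use ->
repeatability -> budgets, with a reproducibility manifest.

One global seed deterministically spawns per-stage seeds, so each stage is
individually reproducible and the whole run is byte-stable: rerunning with
the same configuration and seed yields identical artifact checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import budgets as bud
from . import hmm as hmm_mod
from . import preprocessing as prep
from . import repeatability as rpt
from . import spaceuse as su
from .fields import load_field
from .projection import LocalProjection
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger("frontforage")


@dataclass
class PipelineConfig:
    """All stage parameters, at the analysis' standard defaults."""

    outdir: str = "frontforage_out"
    tracks_csv: str | None = None  # None -> simulate a cohort
    fsle_nc: str | None = None
    colony_lon: float = -2.64
    colony_lat: float = 56.08
    trip_radius_km: float = 10.0
    trip_min_duration_min: float = 40.0
    fix_interval_s: float = 120.0
    hmm_designs: tuple = ("fsle*age", "fsle+age", "~1")
    hmm_restarts: int = 25
    ud_bandwidth_km: float = 10.0
    ud_cell_km: float = 1.0
    contour_levels: tuple = (0.5, 0.95)
    n_perm: int = 1000
    n_boot: int = 1000
    solar_split: bool = True
    seed: int = 0
    sim: dict = dc_field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self):
        for name in ("trip_radius_km", "trip_min_duration_min", "fix_interval_s",
                     "ud_bandwidth_km", "ud_cell_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_perm < 1 or self.n_boot < 1 or self.hmm_restarts < 1:
            raise ValueError("n_perm, n_boot and hmm_restarts must be >= 1")
        if self.sim:
            SimConfig(**{**self.sim, "seed": 0})  # validate overrides early

    @property
    def colony(self) -> tuple[float, float]:
        return (self.colony_lon, self.colony_lat)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hmm_designs"] = list(self.hmm_designs)
        d["contour_levels"] = list(self.contour_levels)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the outdir).

    Any stage failure raises with the stage name; artifacts written before
    the failure are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("simulate", "hmm", "spaceuse", "repeatability", "budgets"),
            root.spawn(5),
        )
    }
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": stage_seed,
        "config": config.to_dict(),
        "artifacts": {},
    }
    cfg_blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    manifest["config_hash"] = hashlib.sha256(cfg_blob).hexdigest()

    def record(name, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    def stage(name):
        log.info("stage %s ...", name)
        return _StageTimer(name, manifest)

    # -- simulate / load ----------------------------------------------------
    with stage("inputs"):
        if config.tracks_csv is None:
            sim_cfg = SimConfig(**{**config.sim, "seed": stage_seed["simulate"]})
            cohort = simulate_cohort(sim_cfg)
            tracks_path = out / "tracks.csv"
            truth_path = out / "truth.csv"
            fsle_path = out / "fsle.nc"
            cohort.write(tracks_path, truth_path, fsle_path)
            record("tracks", tracks_path)
            record("truth", truth_path)
            record("fsle", fsle_path)
            fixes = prep.read_tracks(tracks_path)
            fsle = cohort.fsle
            colony = sim_cfg.colony
        else:
            fixes = prep.read_tracks(config.tracks_csv)
            if config.fsle_nc is None:
                raise RuntimeError("stage inputs: fsle_nc required with tracks_csv")
            fsle = load_field(config.fsle_nc)
            colony = config.colony

    # -- preprocessing ------------------------------------------------------
    with stage("preprocess"):
        trips = prep.segment_trips(
            fixes, colony, config.trip_radius_km, config.trip_min_duration_min
        )
        if not trips:
            raise RuntimeError("stage preprocess: no trips found")
        trips = [
            prep.regularize(t, config.fix_interval_s, colony=colony)
            for t in trips
        ]
        series = prep.prepare_series(trips, fsle, colony, config.fix_interval_s)
        metrics = prep.metrics_table(trips, colony)
        metrics_path = out / "trip_metrics.csv"
        metrics.to_csv(metrics_path, index=False, float_format="%.6f")
        record("trip_metrics", metrics_path)
        mcp_path = out / "trip_mcp.geojson"
        prep.mcp_geojson(trips, colony, mcp_path)
        record("trip_mcp", mcp_path)

    # -- HMM ----------------------------------------------------------------
    with stage("hmm"):
        table = hmm_mod.rank_models(
            series,
            designs=config.hmm_designs,
            n_restarts=config.hmm_restarts,
            seed=stage_seed["hmm"],
        )
        best = table.attrs["fits"][table["design"].iloc[0]]
        aic_path = out / "hmm_aic.csv"
        table.to_csv(aic_path, index=False, float_format="%.4f")
        record("hmm_aic", aic_path)
        fit_path = out / "hmm_fit.json"
        best.to_json(fit_path)
        record("hmm_fit", fit_path)
        decoded = best.decode(series)
        dec = pd.concat(
            [
                pd.DataFrame(
                    {
                        "trip_id": s.trip_id,
                        "time": s.times,
                        "x": s.x,
                        "y": s.y,
                        "step_km": s.steps,
                        "turn_rad": s.turns,
                        "fsle": s.covariate,
                        "state": st,
                    }
                )
                for s, st in zip(series, decoded)
            ],
            ignore_index=True,
        )
        dec_path = out / "decoded_states.csv"
        dec.to_csv(dec_path, index=False, float_format="%.6f")
        record("decoded_states", dec_path)

    # -- space use ----------------------------------------------------------
    with stage("spaceuse"):
        proj = LocalProjection(*colony)
        by_bird: dict[str, list] = {}
        ages: dict[str, int] = {}
        for t in trips:
            by_bird.setdefault(t.bird_id, []).append(
                np.column_stack([t.fixes["x"].values, t.fixes["y"].values])
            )
            ages[t.bird_id] = t.age
        birds = sorted(by_bird)
        xy_by_bird = [np.concatenate(by_bird[b], axis=0) for b in birds]
        labels = [ages[b] for b in birds]
        overlap = {}
        for level in config.contour_levels:
            res = su.overlap_permutation_test(
                xy_by_bird,
                labels,
                contour_level=level,
                n_perm=config.n_perm,
                bandwidth_km=config.ud_bandwidth_km,
                cell_km=config.ud_cell_km,
                seed=stage_seed["spaceuse"],
            )
            overlap[f"{int(level * 100)}"] = {
                "ba": res.ba_observed,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
            }
        ov_path = out / "overlap.json"
        _write_json(overlap, ov_path)
        record("overlap", ov_path)
        # per-class UD rasters and volume contours
        allxy = np.concatenate(xy_by_bird, axis=0)
        grid = su.make_grid(
            allxy[:, 0], allxy[:, 1], config.ud_cell_km,
            pad_km=4.0 * config.ud_bandwidth_km,
        )
        for cls, name in ((0, "adult"), (1, "immature")):
            pts = np.concatenate(
                [xy for xy, lab in zip(xy_by_bird, labels) if lab == cls]
            )
            ud = su.kde_ud(
                pts[:, 0], pts[:, 1], config.ud_bandwidth_km, grid=grid
            )
            asc = out / f"ud_{name}.asc"
            su.write_esri_ascii(ud, asc)
            record(f"ud_{name}", asc)
            for level in config.contour_levels:
                gj = out / f"ud_{name}_{int(level * 100)}.geojson"
                su.contour_geojson(ud, level, gj, {"age_class": name})
                record(f"ud_{name}_{int(level * 100)}", gj)

    # -- repeatability ------------------------------------------------------
    with stage("repeatability"):
        rtab = rpt.repeatability_table(
            metrics, n_boot=config.n_boot, seed=stage_seed["repeatability"]
        )
        r_path = out / "repeatability.csv"
        rtab.to_csv(r_path, index=False, float_format="%.6f")
        record("repeatability", r_path)
        ztab = rpt.zr_difference_table(rtab)
        z_path = out / "zr_differences.csv"
        ztab.to_csv(z_path, index=False, float_format="%.6f")
        record("zr_differences", z_path)

    # -- budgets ------------------------------------------------------------
    with stage("budgets"):
        btab = bud.budget_table(
            series, decoded, colony=colony, solar_split=config.solar_split
        )
        b_path = out / "time_budgets.csv"
        btab.to_csv(b_path, index=False, float_format="%.6f")
        record("time_budgets", b_path)
        ctab = bud.compare_budgets(
            btab, n_perm=config.n_perm, seed=stage_seed["budgets"]
        )
        c_path = out / "budget_comparison.csv"
        ctab.to_csv(c_path, index=False, float_format="%.6f")
        record("budget_comparison", c_path)

    _write_json(manifest, out / "manifest.json")
    return manifest


class _StageTimer:
    def __init__(self, name, manifest):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s failed after %.1fs: %s", self.name, dt, exc)
            if exc_type is not RuntimeError:
                raise RuntimeError(f"stage {self.name}: {exc}") from exc
        else:
            log.info("stage %s done in %.1fs", self.name, dt)
        return False
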