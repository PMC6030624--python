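"""Behavioural time budgets from decoded state sequences.

Each trip's Viterbi-decoded states (1 rest, 2 forage, 3 transit) become
proportions of fixes spent in each mode, overall and split into day/night by
solar elevation.  Age classes are compared per state with a bird-level
permutation test on bird-mean proportions: birds — not trips or fixes — are
the exchangeable unit, which respects the repeated-measures structure that
the original mixed-model analysis accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import LocalProjection
from .solar import is_day

STATE_NAMES = {1: "rest", 2: "forage", 3: "transit"}


@dataclass
class TimeBudget:
    """Per-trip proportions of time in each behavioural mode."""

    trip_id: str
    bird_id: str
    age_class: str
    n_fixes: int
    prop_rest: float
    prop_forage: float
    prop_transit: float
    day: dict | None = None
    night: dict | None = None

    def as_row(self) -> dict:
        row = {
            "trip_id": self.trip_id,
            "bird_id": self.bird_id,
            "age_class": self.age_class,
            "n_fixes": self.n_fixes,
            "prop_rest": self.prop_rest,
            "prop_forage": self.prop_forage,
            "prop_transit": self.prop_transit,
        }
        for part, d in (("day", self.day), ("night", self.night)):
            if d is not None:
                for k, v in d.items():
                    row[f"{part}_{k}"] = v
        return row


def _props(states: np.ndarray) -> dict:
    n = len(states)
    if n == 0:
        return {"n": 0, "prop_rest": np.nan, "prop_forage": np.nan,
                "prop_transit": np.nan}
    return {
        "n": int(n),
        "prop_rest": float((states == 1).sum() / n),
        "prop_forage": float((states == 2).sum() / n),
        "prop_transit": float((states == 3).sum() / n),
    }


def time_budget(
    series,
    states: np.ndarray,
    colony=None,
    solar_split: bool = True,
    exclude: np.ndarray | None = None,
) -> TimeBudget:
    """Time budget of one decoded trip.

    ``series`` is the trip's step series (times and projected positions of
    step origins); ``states`` the matching decoded sequence.  ``exclude``
    marks fixes to drop from all denominators (e.g. interpolated in long
    gaps).  Day/night is classified by solar elevation at each fix.
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("no decoded states supplied")
    keep = np.ones(len(states), dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    st = states[keep]
    overall = _props(st)
    day_d = night_d = None
    if solar_split:
        if colony is None:
            raise ValueError("solar_split requires colony coordinates")
        proj = LocalProjection(*colony)
        lon, lat = proj.inverse(series.x[keep], series.y[keep])
        daymask = is_day(series.times[keep], lat, lon)
        day_d = _props(st[daymask])
        night_d = _props(st[~daymask])
    return TimeBudget(
        trip_id=series.trip_id,
        bird_id=series.bird_id,
        age_class="adult" if series.age == 0 else "immature",
        n_fixes=overall["n"],
        prop_rest=overall["prop_rest"],
        prop_forage=overall["prop_forage"],
        prop_transit=overall["prop_transit"],
        day=day_d,
        night=night_d,
    )


def budget_table(series_list, decoded, colony=None, solar_split=True) -> pd.DataFrame:
    """Per-trip budget rows for matching series and decoded sequences."""
    rows = [
        time_budget(s, st, colony=colony, solar_split=solar_split).as_row()
        for s, st in zip(series_list, decoded)
    ]
    return pd.DataFrame(rows)


def compare_budgets(
    budgets: pd.DataFrame,
    n_perm: int = 1000,
    seed=None,
    columns=("prop_forage", "prop_rest", "prop_transit"),
) -> pd.DataFrame:
    """Age-class comparison of time budgets, per behavioural state.

    Reports median and range of the per-trip proportions by class, and a
    two-sided bird-level permutation p-value on the difference of class
    means of bird-mean proportions.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    bird = budgets.groupby(["bird_id", "age_class"], as_index=False)[
        list(columns)
    ].mean()
    labels = (bird["age_class"] == "immature").values
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least two birds per age class")
    rows = []
    for col in columns:
        vals = bird[col].values
        obs = np.nanmean(vals[~labels]) - np.nanmean(vals[labels])
        perms = np.empty(n_perm)
        for b in range(n_perm):
            pl = rng.permutation(labels)
            perms[b] = np.nanmean(vals[~pl]) - np.nanmean(vals[pl])
        p = float((np.abs(perms) >= abs(obs) - 1e-15).mean())
        sub_a = budgets.loc[budgets["age_class"] == "adult", col]
        sub_i = budgets.loc[budgets["age_class"] == "immature", col]
        rows.append(
            {
                "state": col.replace("prop_", ""),
                "adult_median": float(sub_a.median()),
                "adult_min": float(sub_a.min()),
                "adult_max": float(sub_a.max()),
                "immature_median": float(sub_i.median()),
                "immature_min": float(sub_i.min()),
                "immature_max": float(sub_i.max()),
                "mean_diff_bird_level": float(obs),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
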