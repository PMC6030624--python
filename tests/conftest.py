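import numpy as np
import pandas as pd
import pytest

import frontforage as ff


def cohort_to_fixes(cohort):
    """Track CSV frame as the preprocessing stage reads it."""
    fixes = cohort.tracks.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"]).dt.tz_localize(None)
    return fixes


def simulate_and_prepare(cfg):
    """Cohort -> (trips, step series with covariates, cohort)."""
    cohort = ff.simulate_cohort(cfg)
    fixes = cohort_to_fixes(cohort)
    trips = ff.segment_trips(fixes, cfg.colony)
    trips = [ff.regularize(t, cfg.fix_interval_s, colony=cfg.colony) for t in trips]
    series = ff.prepare_series(trips, cohort.fsle, cfg.colony, cfg.fix_interval_s)
    return trips, series, cohort


def small_sim_config(seed, n_adults=6, n_immatures=3, **kw):
    return ff.SimConfig(n_adults=n_adults, n_immatures=n_immatures, seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across tests (6 adults, 3 immatures)."""
    cfg = small_sim_config(42)
    trips, series, cohort = simulate_and_prepare(cfg)
    return {"cfg": cfg, "trips": trips, "series": series, "cohort": cohort}


def make_series(steps, turns=None, covariate=None, age=0, trip_id="t0", bird="b0"):
    steps = np.asarray(steps, dtype=float)
    if turns is None:
        turns = np.full(len(steps), np.nan)
        turns[1:] = 0.0
    if covariate is None:
        covariate = np.zeros(len(steps))
    return ff.StepSeries(
        trip_id=trip_id,
        bird_id=bird,
        age=age,
        steps=steps,
        turns=np.asarray(turns, dtype=float),
        covariate=np.asarray(covariate, dtype=float),
    )


def brute_force_loglik(series, em, tm, stationary=False):
    """Path-enumeration oracle for the forward likelihood (numpy gather)."""
    import itertools

    from frontforage.hmm import (
        _design_matrix,
        step_density,
        stationary_distribution,
        transition_matrix,
        turn_density,
    )

    T = len(series.steps)
    Z = _design_matrix([series], tm.design)
    tpms = np.array([transition_matrix(tm, Z[t]) for t in range(T)])
    d0 = (
        stationary_distribution(tpms[0])
        if stationary
        else np.full(3, 1.0 / 3.0)
    )
    logb = np.empty((T, 3))
    for t in range(T):
        for k in range(3):
            d = step_density(
                series.steps[t], em.step_mean[k], em.step_sd[k], em.zero_mass[k]
            )
            if np.isfinite(series.turns[t]):
                d *= turn_density(series.turns[t], em.turn_mu[k], em.turn_kappa[k])
            logb[t, k] = np.log(d)
    paths = np.array(list(itertools.product(range(3), repeat=T)))
    logp = np.log(d0[paths[:, 0]]) + logb[0, paths[:, 0]]
    for t in range(1, T):
        logp += np.log(tpms[t - 1][paths[:, t - 1], paths[:, t]])
        logp += logb[t, paths[:, t]]
    m = logp.max()
    best = paths[int(np.argmax(logp))]
    return m + np.log(np.exp(logp - m).sum()), best


def random_hmm(rng):
    em = ff.EmissionParams(
        np.sort(rng.uniform(0.05, 2.0, 3)),
        rng.uniform(0.05, 1.0, 3),
        rng.uniform(-np.pi, np.pi, 3),
        rng.uniform(0.5, 15.0, 3),
    )
    tm = ff.TransitionModel("fsle*age", rng.normal(0.0, 1.0, (6, 4)))
    return em, tm


def random_series(rng, T):
    steps = rng.gamma(1.0, 0.5, T) + 1e-3
    turns = rng.uniform(-np.pi, np.pi, T)
    turns[0] = np.nan
    cov = rng.uniform(0.0, 1.0, T)
    return make_series(steps, turns, cov, age=int(rng.integers(2)))
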