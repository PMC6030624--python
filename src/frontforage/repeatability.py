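"""Repeatability (intra-class correlation) of trip characteristics.

Individual foraging-site fidelity is quantified as repeatability: the share
of between-individual variance in the total variance of a trip metric,

    R = sigma2_id / (sigma2_id + sigma2_res),

estimated from a Gaussian one-random-intercept model (bird ID as the
grouping factor) fitted by REML.  Confidence intervals come from a
parametric bootstrap (simulate from the fitted model, refit, percentile
interval).  Group contrasts use Fisher's z transform, Zr = atanh(R), with
the CI of the difference built from independent bootstrap draws.  Departure
angles get a circular analogue built on mean resultant lengths.

The random-intercept REML/ML fit is written directly as a profile
likelihood over the variance ratio — with a single grouping factor the
per-group matrix algebra collapses to scalars, which makes the thousands of
bootstrap refits cheap and reproduces balanced-ANOVA method-of-moments
components exactly on balanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

LOG10_METRICS = ("duration_h", "length_km", "area_km2")
LINEAR_METRICS = (
    "duration_h",
    "length_km",
    "range_km",
    "terminal_x",
    "terminal_y",
    "area_km2",
)


@dataclass
class LMMFit:
    """One-random-intercept Gaussian mixed model fit."""

    fe_params: dict
    sigma2_id: float
    sigma2_res: float
    loglik: float
    method: str  # "reml" or "ml"
    n_obs: int
    n_groups: int

    @property
    def icc(self) -> float:
        tot = self.sigma2_id + self.sigma2_res
        return float(self.sigma2_id / tot) if tot > 0 else 0.0


@dataclass
class RepeatabilityResult:
    """Point estimate, bootstrap CI and Fisher-z of a repeatability."""

    R: float
    ci_low: float
    ci_high: float
    zr: float
    metric: str = ""
    group: str = ""
    boot_draws: np.ndarray | None = None

    def as_row(self) -> dict:
        return {
            "metric": self.metric,
            "group": self.group,
            "R": self.R,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "zr": self.zr,
        }


def fisher_z(r: float) -> float:
    """Fisher's z transform of a repeatability, clipped away from 1."""
    return float(np.arctanh(np.clip(r, 0.0, 1.0 - 1e-9)))


# ---------------------------------------------------------------------------
# profile REML / ML for the one-way random-intercept model


def _group_index(bird_ids):
    codes, _ = pd.factorize(np.asarray(bird_ids))
    return codes


def _profile_neg2ll(lam, y, codes, xmat, reml):
    """-2 log (restricted) likelihood profiled over sigma2 and fixed effects.

    lam is the variance ratio sigma2_id / sigma2_res.  Per group,
    (I + lam J)^-1 = I - lam/(1 + n_i lam) J and
    log|I + lam J| = log(1 + n_i lam).
    """
    n = len(y)
    p = xmat.shape[1]
    ng = codes.max() + 1
    n_i = np.bincount(codes, minlength=ng).astype(float)
    w = lam / (1.0 + n_i * lam)  # per-group correction weight

    sy = np.bincount(codes, weights=y, minlength=ng)
    xtx = xmat.T @ xmat
    xty = xmat.T @ y
    sx = np.vstack(
        [np.bincount(codes, weights=xmat[:, j], minlength=ng) for j in range(p)]
    )  # (p, ng)
    xtvx = xtx - (sx * w) @ sx.T
    xtvy = xty - (sx * w) @ sy
    beta = np.linalg.solve(xtvx, xtvy)
    r = y - xmat @ beta
    sr = sy - sx.T @ beta
    rss = float(r @ r - (w * sr) @ sr)
    logdet = float(np.log1p(n_i * lam).sum())
    if reml:
        dof = n - p
        sig2 = rss / dof
        _, ld2 = np.linalg.slogdet(xtvx)
        val = dof * np.log(2 * np.pi * sig2) + logdet + dof + ld2
    else:
        sig2 = rss / n
        val = n * np.log(2 * np.pi * sig2) + logdet + n
    return val, beta, sig2


def _profile_score(lam, y, codes, xmat, reml):
    """d(-2 profile log-lik)/d lambda, analytic (envelope theorem)."""
    n = len(y)
    p = xmat.shape[1]
    ng = codes.max() + 1
    n_i = np.bincount(codes, minlength=ng).astype(float)
    w = lam / (1.0 + n_i * lam)
    dw = 1.0 / (1.0 + n_i * lam) ** 2
    sy = np.bincount(codes, weights=y, minlength=ng)
    sx = np.vstack(
        [np.bincount(codes, weights=xmat[:, j], minlength=ng) for j in range(p)]
    )
    xtvx = xmat.T @ xmat - (sx * w) @ sx.T
    beta = np.linalg.solve(xtvx, xmat.T @ y - (sx * w) @ sy)
    r = y - xmat @ beta
    sr = sy - sx.T @ beta
    rss = float(r @ r - (w * sr) @ sr)
    drss = -float((dw * sr) @ sr)
    dlogdet = float((n_i / (1.0 + n_i * lam)).sum())
    if reml:
        da = -(sx * dw) @ sx.T
        tr = float(np.trace(np.linalg.solve(xtvx, da)))
        return (n - p) * drss / rss + dlogdet + tr
    return n * drss / rss + dlogdet


def fit_lmm(values, bird_ids, age=None, reml: bool = True) -> LMMFit:
    """Fit the one-random-intercept model, optionally with an age effect.

    ``age`` (0/1 per observation) enters as a fixed effect.  Requires at
    least two birds and at least one bird with two or more observations
    (otherwise the between-bird variance is unidentifiable).
    """
    y = np.asarray(values, dtype=float)
    codes = _group_index(bird_ids)
    ng = codes.max() + 1
    if ng < 2:
        raise ValueError("need at least two birds")
    if np.bincount(codes).max() < 2:
        raise ValueError(
            "every bird has a single observation: between-bird variance "
            "is unidentifiable"
        )
    cols = [np.ones(len(y))]
    names = ["intercept"]
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
        names.append("age")
    xmat = np.column_stack(cols)

    def score(u):
        return _profile_score(np.exp(u), y, codes, xmat, reml)

    # the -2 log-lik is decreasing where the score is negative; locate the
    # interior stationary point exactly, else take the lambda = 0 boundary
    lo, hi = -30.0, 16.0
    if score(lo) >= 0.0:
        lam = 0.0  # no between-bird variance
    elif score(hi) <= 0.0:
        lam = float(np.exp(hi))
    else:
        lam = float(np.exp(brentq(score, lo, hi, xtol=1e-13, rtol=1e-15)))
    val, beta, sig2 = _profile_neg2ll(max(lam, 1e-300), y, codes, xmat, reml)
    if lam == 0.0:
        val, beta, sig2 = _profile_neg2ll(1e-14, y, codes, xmat, reml)
        lam = 0.0
    return LMMFit(
        fe_params=dict(zip(names, beta.tolist())),
        sigma2_id=lam * sig2,
        sigma2_res=sig2,
        loglik=-0.5 * val,
        method="reml" if reml else "ml",
        n_obs=len(y),
        n_groups=int(ng),
    )


def lrt_age(values, bird_ids, age) -> tuple[float, float]:
    """Likelihood-ratio test of the age fixed effect (ML fits, chi2_1)."""
    full = fit_lmm(values, bird_ids, age=age, reml=False)
    null = fit_lmm(values, bird_ids, age=None, reml=False)
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    return float(stat), float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# repeatability with parametric bootstrap


def repeatability(
    values,
    bird_ids,
    n_boot: int = 1000,
    seed=None,
    metric: str = "",
    group: str = "",
) -> RepeatabilityResult:
    """ICC-based repeatability with a parametric-bootstrap CI.

    Bootstrap replicates simulate responses from the fitted model on the
    observed grouping structure, refit by REML and take percentile bounds.
    """
    y = np.asarray(values, dtype=float)
    codes = _group_index(bird_ids)
    fitted = fit_lmm(y, codes)
    rng = np.random.default_rng(seed)
    ng = codes.max() + 1
    mu = fitted.fe_params["intercept"]
    sd_id = np.sqrt(fitted.sigma2_id)
    sd_res = np.sqrt(fitted.sigma2_res)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        u = rng.normal(0.0, sd_id, ng)
        ysim = mu + u[codes] + rng.normal(0.0, sd_res, len(y))
        try:
            draws[b] = fit_lmm(ysim, codes).icc
        except ValueError:
            draws[b] = np.nan
    good = draws[np.isfinite(draws)]
    lo, hi = np.percentile(good, [2.5, 97.5]) if len(good) else (np.nan, np.nan)
    return RepeatabilityResult(
        R=fitted.icc,
        ci_low=float(lo),
        ci_high=float(hi),
        zr=fisher_z(fitted.icc),
        metric=metric,
        group=group,
        boot_draws=draws,
    )


def zr_difference(
    res_a: RepeatabilityResult, res_b: RepeatabilityResult
) -> tuple[float, tuple[float, float]]:
    """Difference in Fisher-z repeatabilities with a bootstrap CI.

    The CI comes from percentiles of differences of the two (independent)
    bootstrap draw vectors.  Raises if either result lacks stored draws.
    """
    if res_a.boot_draws is None or res_b.boot_draws is None:
        raise ValueError("both results need stored bootstrap draws")
    da = np.asarray(res_a.boot_draws, dtype=float)
    db = np.asarray(res_b.boot_draws, dtype=float)
    n = min(len(da), len(db))
    za = np.arctanh(np.clip(da[:n], 0.0, 1.0 - 1e-9))
    zb = np.arctanh(np.clip(db[:n], 0.0, 1.0 - 1e-9))
    diff = za - zb
    diff = diff[np.isfinite(diff)]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return res_a.zr - res_b.zr, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# circular repeatability


def _resultant_length(angles):
    return float(np.hypot(np.sum(np.cos(angles)), np.sum(np.sin(angles))))


def circular_repeatability(
    angles,
    bird_ids,
    n_boot: int = 1000,
    seed=None,
    metric: str = "departure_angle",
    group: str = "",
) -> RepeatabilityResult:
    """Circular-ANOVA repeatability of angles grouped by bird.

    An among/within decomposition on mean resultant lengths:

        R = (sum_i R_i - R_tot) / (N - R_tot)

    with R_i the resultant length of bird i's angles and R_tot of all N
    angles pooled.  If every bird repeats its own fixed angle (within-bird
    dispersion zero) the estimator is 1; for i.i.d. angles it tends to 0 at
    large N.  It is invariant under a common rotation of all angles and is
    clipped to [0, 1].  The CI is a bird-level (cluster) bootstrap.
    """
    a = np.asarray(angles, dtype=float)
    codes = _group_index(bird_ids)
    ng = codes.max() + 1
    if ng < 2 or np.bincount(codes).max() < 2:
        raise ValueError("need >= 2 birds and >= 1 bird with >= 2 angles")
    r_point = _circ_r(a, codes, ng)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, ng, ng)
        parts_a = []
        parts_c = []
        for newg, g in enumerate(pick):
            sel = codes == g
            parts_a.append(a[sel])
            parts_c.append(np.full(sel.sum(), newg))
        draws[b] = _circ_r(
            np.concatenate(parts_a), np.concatenate(parts_c), ng
        )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return RepeatabilityResult(
        R=r_point,
        ci_low=float(lo),
        ci_high=float(hi),
        zr=fisher_z(r_point),
        metric=metric,
        group=group,
        boot_draws=draws,
    )


def _circ_r(a, codes, ng):
    n = len(a)
    r_within = sum(
        _resultant_length(a[codes == g]) for g in range(ng) if (codes == g).any()
    )
    r_tot = _resultant_length(a)
    denom = n - r_tot
    if denom < 1e-12:
        return 0.0  # no angular variance anywhere: R undefined, report 0
    return float(np.clip((r_within - r_tot) / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# tables over the seven trip metrics


def repeatability_table(
    metrics: pd.DataFrame, n_boot: int = 1000, seed=None
) -> pd.DataFrame:
    """Per-metric, per-age-class repeatability of the trip characteristics.

    Duration, length and area are log10-transformed first; the departure
    angle uses the circular estimator.  Repeatability is computed within
    each age class separately (no age fixed effect).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    results = {}
    for grp, sub in metrics.groupby("age_class", sort=True):
        for name in LINEAR_METRICS + ("departure_angle",):
            child = np.random.default_rng(ss.spawn(1)[0])
            vals = sub[name].values
            ok = np.isfinite(vals)
            try:
                if name == "departure_angle":
                    res = circular_repeatability(
                        vals[ok], sub["bird_id"].values[ok],
                        n_boot=n_boot, seed=child, metric=name, group=grp,
                    )
                else:
                    v = np.log10(vals[ok]) if name in LOG10_METRICS else vals[ok]
                    res = repeatability(
                        v, sub["bird_id"].values[ok],
                        n_boot=n_boot, seed=child, metric=name, group=grp,
                    )
            except ValueError:
                continue
            results[(name, grp)] = res
            rows.append(res.as_row())
    table = pd.DataFrame(rows)
    table.attrs["results"] = results
    return table


def zr_difference_table(table: pd.DataFrame) -> pd.DataFrame:
    """Adult-minus-immature Zr differences for every metric in a table."""
    results = table.attrs.get("results", {})
    rows = []
    for name in sorted({m for (m, _) in results}):
        ra = results.get((name, "adult"))
        ri = results.get((name, "immature"))
        if ra is None or ri is None:
            continue
        dz, (lo, hi) = zr_difference(ra, ri)
        rows.append(
            {
                "metric": name,
                "zr_adult": ra.zr,
                "zr_immature": ri.zr,
                "zr_diff": dz,
                "ci_low": lo,
                "ci_high": hi,
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)
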