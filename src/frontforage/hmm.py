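"""Three-state movement HMM with covariate-dependent transition probabilities.

The model decomposes a central-place forager's trajectory, sampled at a fixed
interval, into three latent behavioural states — rest (short steps, straight),
forage (short steps, tortuous) and transit (long steps, straight).  Each state
emits a step length from a gamma distribution (mean/sd parameterisation) and a
turning angle from a von Mises distribution.  The state process is a Markov
chain whose transition probabilities follow a multinomial-logit regression on
per-step covariates (frontal intensity, age class and their interaction), with
"stay in the current state" as the reference category:

    eta_ij(t)   = beta_ij . z(t)            (i != j, 6 off-diagonal rows)
    gamma_ij(t) = exp(eta_ij) / sum_j' exp(eta_ij'),   eta_ii = 0

Fitting maximises the forward-algorithm likelihood over all trips jointly
(each trip an independent sequence) by quasi-Newton on unconstrained working
parameters, with random restarts to guard against local optima.  States are
relabelled by ascending step mean so that state 1 = rest, 2 = forage,
3 = transit regardless of the optimiser's labelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln, i0e

N_STATES = 3
#: Off-diagonal transition rows, in fixed order.
TRANSITION_ROWS = [(i, j) for i in range(N_STATES) for j in range(N_STATES) if i != j]

_DESIGNS = {
    "~1": ("1",),
    "1": ("1",),
    "fsle": ("1", "fsle"),
    "age": ("1", "age"),
    "fsle+age": ("1", "fsle", "age"),
    "fsle*age": ("1", "fsle", "age", "fsle:age"),
}

#: The candidate design set ranked in the analysis.
DEFAULT_DESIGNS = ("fsle*age", "fsle+age", "age", "fsle", "~1")


def design_columns(design: str) -> tuple[str, ...]:
    """Resolve a formula-style design name to its column labels."""
    key = design.replace(" ", "").lower()
    try:
        return _DESIGNS[key]
    except KeyError:
        raise ValueError(
            f"unknown design {design!r}; expected one of {sorted(_DESIGNS)}"
        ) from None


@dataclass
class EmissionParams:
    """State-dependent distribution parameters, state-indexed arrays of 3.

    Step lengths: gamma with given mean and sd (km); ``zero_mass`` is an
    optional point mass at exactly zero (used only when the data contain
    exact zeros — a gamma density has no mass there).  Turning angles:
    von Mises with mean ``turn_mu`` (radians) and concentration
    ``turn_kappa``.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mu: np.ndarray
    turn_kappa: np.ndarray
    zero_mass: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES))

    def __post_init__(self):
        for name in ("step_mean", "step_sd", "turn_mu", "turn_kappa", "zero_mass"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            np.all(self.step_mean > 0)
            and np.all(self.step_sd > 0)
            and np.all(self.turn_kappa > 0)
        ):
            raise ValueError("step_mean, step_sd and turn_kappa must be positive")
        if np.any(self.zero_mass < 0) or np.any(self.zero_mass >= 1):
            raise ValueError("zero_mass must lie in [0, 1)")


@dataclass
class TransitionModel:
    """Multinomial-logit transition structure.

    ``beta`` has one row per off-diagonal transition (order
    :data:`TRANSITION_ROWS`) and one column per design column.
    """

    design: str
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        ncol = len(design_columns(self.design))
        if self.beta.shape != (len(TRANSITION_ROWS), ncol):
            raise ValueError(
                f"beta must be {len(TRANSITION_ROWS)}x{ncol} for design "
                f"{self.design!r}, got {self.beta.shape}"
            )
        if not np.isfinite(self.beta).all():
            raise ValueError("beta must be finite")


# ---------------------------------------------------------------------------
# densities


def step_density(x, mean, sd, zero_mass=0.0):
    """Gamma step-length density with optional zero inflation.

    Gamma parameterised by mean and sd: shape = mean^2/sd^2,
    rate = mean/sd^2.  At exactly x = 0 returns the point mass.
    """
    if not (np.isfinite(mean) and np.isfinite(sd) and mean > 0 and sd > 0):
        raise ValueError("mean and sd must be finite and positive")
    x = np.asarray(x, dtype=float)
    shape = mean**2 / sd**2
    rate = mean / sd**2
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = (
            shape * np.log(rate)
            - gammaln(shape)
            + (shape - 1.0) * np.log(x)
            - rate * x
        )
    dens = np.where(x > 0, (1.0 - zero_mass) * np.exp(logpdf), zero_mass)
    return dens if dens.ndim else float(dens)


def turn_density(phi, mu, kappa):
    """Von Mises turning-angle density on (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    # log I0(kappa) = log(i0e(kappa)) + kappa, stable for large kappa
    logc = np.log(2.0 * np.pi) + np.log(i0e(kappa)) + kappa
    dens = np.exp(kappa * np.cos(phi - mu) - logc)
    return dens if dens.ndim else float(dens)


def transition_matrix(tm: TransitionModel, covariate_row) -> np.ndarray:
    """3x3 transition-probability matrix at one covariate row.

    ``covariate_row`` is a mapping or sequence matching the design columns
    (the intercept column may be supplied or implied).
    """
    cols = design_columns(tm.design)
    if isinstance(covariate_row, dict):
        z = np.array(
            [
                1.0
                if c == "1"
                else (
                    covariate_row["fsle"] * covariate_row["age"]
                    if c == "fsle:age"
                    else covariate_row[c]
                )
                for c in cols
            ]
        )
    else:
        z = np.asarray(covariate_row, dtype=float)
        if z.shape != (len(cols),):
            raise ValueError(f"covariate row must have {len(cols)} entries")
    return _tpm_from_eta(tm.beta @ z)


def _tpm_from_eta(eta6: np.ndarray) -> np.ndarray:
    """Row-softmax with zero diagonal; overflow guarded by max-subtraction."""
    eta = np.zeros((N_STATES, N_STATES))
    for r, (i, j) in enumerate(TRANSITION_ROWS):
        eta[i, j] = eta6[r]
    eta -= eta.max(axis=1, keepdims=True)
    g = np.exp(eta)
    return g / g.sum(axis=1, keepdims=True)


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 3x3 stochastic matrix."""
    a = np.vstack([(gamma.T - np.eye(N_STATES))[:-1], np.ones(N_STATES)])
    b = np.array([0.0, 0.0, 1.0])
    delta = np.linalg.solve(a, b)
    return np.clip(delta, 1e-300, None) / np.clip(delta, 1e-300, None).sum()


# ---------------------------------------------------------------------------
# compiled recursions


@njit(cache=True)
def _forward_core(logb, tpm, starts, ends, delta0):  # pragma: no cover - jit
    ll = 0.0
    k = logb.shape[1]
    alpha = np.empty(k)
    new = np.empty(k)
    for s in range(starts.shape[0]):
        t0 = starts[s]
        m = logb[t0, 0]
        for j in range(1, k):
            if logb[t0, j] > m:
                m = logb[t0, j]
        c = 0.0
        for j in range(k):
            alpha[j] = delta0[s, j] * np.exp(logb[t0, j] - m)
            c += alpha[j]
        if not c > 0:
            return -np.inf
        ll += m + np.log(c)
        for j in range(k):
            alpha[j] /= c
        for t in range(t0 + 1, ends[s]):
            m = logb[t, 0]
            for j in range(1, k):
                if logb[t, j] > m:
                    m = logb[t, j]
            c = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += alpha[i] * tpm[t - 1, i, j]
                new[j] = acc * np.exp(logb[t, j] - m)
                c += new[j]
            if not c > 0:
                return -np.inf
            ll += m + np.log(c)
            for j in range(k):
                alpha[j] = new[j] / c
    return ll


@njit(cache=True)
def _fb_grad_core(logb, dlogb, tpm, zmat, rowmap, starts, ends, delta0):
    """Log-likelihood and its gradient by scaled forward-backward.

    ``dlogb`` holds, per step and state, the derivatives of the log emission
    density with respect to that state's own working parameters (columns:
    log step mean, log step sd, kappa*cos/sin pair, logit zero mass).  The
    transition gradient uses the multinomial-logit identity
    d log G(i,j) / d eta(i,j') = 1[j=j'] - G(i,j').
    """  # pragma: no cover - jit
    t_tot, k = logb.shape
    pe = dlogb.shape[2]
    pz = zmat.shape[1]
    ll = 0.0
    grad_em = np.zeros((k, pe))
    grad_beta = np.zeros((k * (k - 1), pz))
    alpha = np.empty((t_tot, k))
    cs = np.empty(t_tot)
    ms = np.empty(t_tot)
    bshift = np.empty((t_tot, k))
    beta_v = np.empty(k)
    beta_new = np.empty(k)
    gamma_t = np.empty(k)
    for s in range(starts.shape[0]):
        t0 = starts[s]
        t1 = ends[s]
        # forward, scaled
        for t in range(t0, t1):
            m = logb[t, 0]
            for j in range(1, k):
                if logb[t, j] > m:
                    m = logb[t, j]
            ms[t] = m
            for j in range(k):
                bshift[t, j] = np.exp(logb[t, j] - m)
        c = 0.0
        for j in range(k):
            alpha[t0, j] = delta0[s, j] * bshift[t0, j]
            c += alpha[t0, j]
        if not c > 0:
            return -np.inf, grad_em, grad_beta
        cs[t0] = c
        ll += ms[t0] + np.log(c)
        for j in range(k):
            alpha[t0, j] /= c
        for t in range(t0 + 1, t1):
            c = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += alpha[t - 1, i] * tpm[t - 1, i, j]
                alpha[t, j] = acc * bshift[t, j]
                c += alpha[t, j]
            if not c > 0:
                return -np.inf, grad_em, grad_beta
            cs[t] = c
            ll += ms[t] + np.log(c)
            for j in range(k):
                alpha[t, j] /= c
        # backward, accumulating gradient terms
        for j in range(k):
            beta_v[j] = 1.0
        # t = t1-1 smoothing term
        for j in range(k):
            gamma_t[j] = alpha[t1 - 1, j]
        for p in range(pe):
            for j in range(k):
                grad_em[j, p] += gamma_t[j] * dlogb[t1 - 1, j, p]
        for t in range(t1 - 2, t0 - 1, -1):
            # xi(i,j) for transition t -> t+1
            for i in range(k):
                rs = 0.0
                for j in range(k):
                    rs += (
                        alpha[t, i]
                        * tpm[t, i, j]
                        * bshift[t + 1, j]
                        * beta_v[j]
                        / cs[t + 1]
                    )
                # row-wise logit gradient: xi_ij - rowsum * G_ij
                for j in range(k):
                    xij = (
                        alpha[t, i]
                        * tpm[t, i, j]
                        * bshift[t + 1, j]
                        * beta_v[j]
                        / cs[t + 1]
                    )
                    if i != j:
                        r = rowmap[i, j]
                        coef = xij - rs * tpm[t, i, j]
                        for q in range(pz):
                            grad_beta[r, q] += coef * zmat[t, q]
                    else:
                        pass
            # diagonal entries have no free coefficient, but the -rs*G term
            # for j == i is absorbed because eta_ii is fixed at zero
            for j in range(k):
                acc = 0.0
                for jj in range(k):
                    acc += tpm[t, j, jj] * bshift[t + 1, jj] * beta_v[jj]
                beta_new[j] = acc / cs[t + 1]
            for j in range(k):
                beta_v[j] = beta_new[j]
            for j in range(k):
                gamma_t[j] = alpha[t, j] * beta_v[j]
            for p in range(pe):
                for j in range(k):
                    grad_em[j, p] += gamma_t[j] * dlogb[t, j, p]
    return ll, grad_em, grad_beta


@njit(cache=True)
def _viterbi_core(logb, logtpm, log_delta0):  # pragma: no cover - jit
    t_len, k = logb.shape
    delta = np.empty((t_len, k))
    psi = np.zeros((t_len, k), dtype=np.int64)
    for j in range(k):
        delta[0, j] = log_delta0[j] + logb[0, j]
    for t in range(1, t_len):
        for j in range(k):
            best = delta[t - 1, 0] + logtpm[t - 1, 0, j]
            arg = 0
            for i in range(1, k):
                v = delta[t - 1, i] + logtpm[t - 1, i, j]
                if v > best:  # strict: ties resolve to the lower state
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    states = np.empty(t_len, dtype=np.int64)
    best = delta[t_len - 1, 0]
    arg = 0
    for j in range(1, k):
        if delta[t_len - 1, j] > best:
            best = delta[t_len - 1, j]
            arg = j
    states[t_len - 1] = arg
    for t in range(t_len - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states


# ---------------------------------------------------------------------------
# observation preparation


def _design_matrix(series_list, design, fsle_loc=0.0, fsle_scale=1.0):
    cols = design_columns(design)
    zs = []
    for s in series_list:
        t = len(s.steps)
        f = (np.abs(np.asarray(s.covariate, dtype=float)) - fsle_loc) / fsle_scale
        a = np.full(t, float(s.age))
        parts = {
            "1": np.ones(t),
            "fsle": f,
            "age": a,
            "fsle:age": f * a,
        }
        zs.append(np.column_stack([parts[c] for c in cols]))
    return np.concatenate(zs, axis=0)


def _log_obs_densities(series_list, em: EmissionParams):
    """(T_total, 3) log emission densities; NaN turns contribute step only."""
    steps = np.concatenate([np.asarray(s.steps, dtype=float) for s in series_list])
    turns = np.concatenate([np.asarray(s.turns, dtype=float) for s in series_list])
    t_tot = len(steps)
    logb = np.empty((t_tot, N_STATES))
    shape = em.step_mean**2 / em.step_sd**2
    rate = em.step_mean / em.step_sd**2
    pos = steps > 0
    logk = np.log(2.0 * np.pi) + np.log(i0e(em.turn_kappa)) + em.turn_kappa
    xk = em.turn_kappa * np.cos(em.turn_mu)
    yk = em.turn_kappa * np.sin(em.turn_mu)
    ok_turn = np.isfinite(turns)
    cos_t = np.where(ok_turn, np.cos(turns), 0.0)
    sin_t = np.where(ok_turn, np.sin(turns), 0.0)
    with np.errstate(divide="ignore"):
        log_steps = np.where(pos, np.log(np.where(pos, steps, 1.0)), 0.0)
    for k in range(N_STATES):
        ls = (
            shape[k] * np.log(rate[k])
            - gammaln(shape[k])
            + (shape[k] - 1.0) * log_steps
            - rate[k] * steps
        )
        if em.zero_mass[k] > 0:
            ls = ls + np.log1p(-em.zero_mass[k])
            ls = np.where(pos, ls, np.log(em.zero_mass[k]))
        elif not pos.all():
            ls = np.where(pos, ls, -np.inf)
        lt = np.where(ok_turn, xk[k] * cos_t + yk[k] * sin_t - logk[k], 0.0)
        logb[:, k] = ls + lt
    return logb


def _dlog_obs_densities(series_list, em: EmissionParams, zero_inflated):
    """(T, 3, pe) derivatives of log emission densities w.r.t. each state's
    working parameters: columns (log mean, log sd, kappa*cos mu, kappa*sin mu
    [, logit zero mass])."""
    from scipy.special import digamma, i1e

    steps = np.concatenate([np.asarray(s.steps, dtype=float) for s in series_list])
    turns = np.concatenate([np.asarray(s.turns, dtype=float) for s in series_list])
    t_tot = len(steps)
    pe = 5 if zero_inflated else 4
    d = np.zeros((t_tot, N_STATES, pe))
    pos = steps > 0
    with np.errstate(divide="ignore"):
        logx = np.where(pos, np.log(np.where(pos, steps, 1.0)), 0.0)
    ok = np.isfinite(turns)
    cos_t = np.where(ok, np.cos(turns), 0.0)
    sin_t = np.where(ok, np.sin(turns), 0.0)
    for k in range(N_STATES):
        a = em.step_mean[k] ** 2 / em.step_sd[k] ** 2
        r = em.step_mean[k] / em.step_sd[k] ** 2
        core = np.log(r) - digamma(a) + logx
        d[:, k, 0] = np.where(pos, 2.0 * a * core + a - steps * r, 0.0)
        d[:, k, 1] = np.where(pos, -2.0 * a * core - 2.0 * a + 2.0 * steps * r, 0.0)
        kap = max(em.turn_kappa[k], 1e-8)
        ratio = i1e(kap) / i0e(kap) / kap  # A(kappa)/kappa, -> 1/2 at 0
        xk = kap * np.cos(em.turn_mu[k])
        yk = kap * np.sin(em.turn_mu[k])
        d[:, k, 2] = np.where(ok, cos_t - ratio * xk, 0.0)
        d[:, k, 3] = np.where(ok, sin_t - ratio * yk, 0.0)
        if zero_inflated:
            zm = em.zero_mass[k]
            d[:, k, 4] = np.where(pos, -zm, 1.0 - zm)
            if zm == 0.0:
                d[~pos, k, 4] = 0.0
    return d


@njit(cache=True)
def _emission_core(steps, logx, pos, ok, cos_t, sin_t, consts, zinf):
    """Per-step log emission densities and their working-parameter
    derivatives; ``consts`` rows are per-state (shape, rate, lognorm,
    digamma(shape), log 2 pi I0(kappa), A(kappa)/kappa, kappa cos mu,
    kappa sin mu, zero mass)."""  # pragma: no cover - jit
    t_tot = steps.shape[0]
    k_st = consts.shape[0]
    pe = 5 if zinf else 4
    logb = np.empty((t_tot, k_st))
    dlogb = np.zeros((t_tot, k_st, pe))
    for k in range(k_st):
        a = consts[k, 0]
        r = consts[k, 1]
        lnorm = consts[k, 2]
        dga = consts[k, 3]
        logk = consts[k, 4]
        ratio = consts[k, 5]
        xk = consts[k, 6]
        yk = consts[k, 7]
        zm = consts[k, 8]
        logr = np.log(r)
        l1mz = np.log1p(-zm) if zm > 0 else 0.0
        lz = np.log(zm) if zm > 0 else -np.inf
        for t in range(t_tot):
            if pos[t]:
                ls = lnorm + (a - 1.0) * logx[t] - r * steps[t]
                gm = 2.0 * a * (logr - dga + logx[t]) + a - steps[t] * r
                dlogb[t, k, 0] = gm
                dlogb[t, k, 1] = -gm - a + steps[t] * r
                if zm > 0:
                    ls += l1mz
                    dlogb[t, k, 4] = -zm
            else:
                ls = lz
                if zinf:
                    dlogb[t, k, 4] = 1.0 - zm
            if ok[t]:
                logb[t, k] = ls + xk * cos_t[t] + yk * sin_t[t] - logk
                dlogb[t, k, 2] = cos_t[t] - ratio * xk
                dlogb[t, k, 3] = sin_t[t] - ratio * yk
            else:
                logb[t, k] = ls
    return logb, dlogb


_ROWMAP = np.full((N_STATES, N_STATES), -1, dtype=np.int64)
for _r, (_i, _j) in enumerate(TRANSITION_ROWS):
    _ROWMAP[_i, _j] = _r


def _series_bounds(series_list):
    lens = np.array([len(s.steps) for s in series_list], dtype=np.int64)
    ends = np.cumsum(lens)
    starts = ends - lens
    return starts, ends


@njit(cache=True)
def _tpm_core(eta6, rowmap):  # pragma: no cover - jit
    t_tot = eta6.shape[0]
    k = rowmap.shape[0]
    out = np.empty((t_tot, k, k))
    for t in range(t_tot):
        for i in range(k):
            m = 0.0  # diagonal eta is 0
            for j in range(k):
                if i != j and eta6[t, rowmap[i, j]] > m:
                    m = eta6[t, rowmap[i, j]]
            ssum = 0.0
            for j in range(k):
                e = 0.0 if i == j else eta6[t, rowmap[i, j]]
                out[t, i, j] = np.exp(e - m)
                ssum += out[t, i, j]
            for j in range(k):
                out[t, i, j] /= ssum
    return out


def _tpms(beta, zmat):
    """(T, 3, 3) per-step transition matrices from the design matrix."""
    return _tpm_core(np.ascontiguousarray(zmat @ beta.T), _ROWMAP)


def _initial_distributions(series_list, tpm, starts, stationary=True):
    n = len(series_list)
    delta0 = np.full((n, N_STATES), 1.0 / N_STATES)
    if stationary:
        for s in range(n):
            try:
                delta0[s] = stationary_distribution(tpm[starts[s]])
            except np.linalg.LinAlgError:
                pass
    return delta0


def forward_loglik(
    series_list, emissions: EmissionParams, transitions: TransitionModel,
    stationary_start: bool = False,
) -> float:
    """Forward-algorithm log-likelihood summed over independent trips.

    Covariates enter on their natural (absolute-FSLE) scale.  Raises if any
    observation has zero density under every state.
    """
    if not series_list:
        raise ValueError("empty series list")
    logb = _log_obs_densities(series_list, emissions)
    zmat = _design_matrix(series_list, transitions.design)
    tpm = _tpms(transitions.beta, zmat)
    starts, ends = _series_bounds(series_list)
    bad = ~np.isfinite(logb.max(axis=1))
    if bad.any():
        t = int(np.flatnonzero(bad)[0])
        s = int(np.searchsorted(ends, t, side="right"))
        raise ValueError(
            f"zero observation density at step {t - starts[s]} of trip "
            f"{series_list[s].trip_id}"
        )
    delta0 = _initial_distributions(series_list, tpm, starts, stationary_start)
    return float(_forward_core(logb, tpm, starts, ends, delta0))


def viterbi(series, fit: "MovementHMMResults") -> np.ndarray:
    """Most-likely state sequence (1-based: 1 rest, 2 forage, 3 transit)."""
    return fit.decode([series])[0]


# ---------------------------------------------------------------------------
# working-parameter packing


def _n_beta(design):
    return len(TRANSITION_ROWS) * len(design_columns(design))


def _pack(em: EmissionParams, beta, zero_inflated):
    parts = [
        np.log(em.step_mean),
        np.log(em.step_sd),
        em.turn_kappa * np.cos(em.turn_mu),
        em.turn_kappa * np.sin(em.turn_mu),
    ]
    if zero_inflated:
        zm = np.clip(em.zero_mass, 1e-8, 1 - 1e-8)
        parts.append(np.log(zm / (1 - zm)))
    parts.append(np.asarray(beta, dtype=float).ravel())
    return np.concatenate(parts)


def _unpack(theta, design, zero_inflated):
    mean = np.exp(theta[0:3])
    sd = np.exp(theta[3:6])
    xk = theta[6:9]
    yk = theta[9:12]
    kappa = np.hypot(xk, yk)
    mu = np.arctan2(yk, xk)
    off = 12
    if zero_inflated:
        zm = 1.0 / (1.0 + np.exp(-theta[off : off + 3]))
        off += 3
    else:
        zm = np.zeros(3)
    ncol = len(design_columns(design))
    beta = theta[off:].reshape(len(TRANSITION_ROWS), ncol)
    em = EmissionParams(mean, sd, mu, np.clip(kappa, 1e-8, None), zm)
    return em, beta


# ---------------------------------------------------------------------------
# model / results


class MovementHMM:
    """Three-state movement HMM built from a list of step series.

    Parameters
    ----------
    series_list
        Sequence of step-series objects (``steps`` km, ``turns`` rad with NaN
        for undefined angles, per-step ``covariate``, binary ``age``).
    design
        Transition covariate structure: ``"~1"``, ``"fsle"``, ``"age"``,
        ``"fsle+age"`` or ``"fsle*age"``.
    standardize
        Z-score the absolute frontal-intensity covariate across all steps
        before optimisation (improves conditioning); fitted coefficients are
        reported on both scales.
    stationary_start
        Start each trip from the stationary distribution of its first
        transition matrix (otherwise uniform).
    zero_inflation
        ``"auto"`` enables a point mass at zero step length only when the
        data contain exact zeros.
    """

    def __init__(
        self,
        series_list,
        design: str = "fsle*age",
        standardize: bool = True,
        stationary_start: bool = False,
        zero_inflation: str | bool = "auto",
    ):
        if not series_list:
            raise ValueError("need at least one series")
        self.series_list = list(series_list)
        self.design = design
        self.design_cols = design_columns(design)
        self.stationary_start = stationary_start
        self._steps = np.concatenate(
            [np.asarray(s.steps, dtype=float) for s in self.series_list]
        )
        has_zeros = bool((self._steps == 0).any())
        if zero_inflation == "auto":
            self.zero_inflated = has_zeros
        else:
            self.zero_inflated = bool(zero_inflation)
        if has_zeros and not self.zero_inflated:
            raise ValueError(
                "data contain zero step lengths; enable zero_inflation"
            )
        fsle_abs = np.abs(
            np.concatenate(
                [np.asarray(s.covariate, dtype=float) for s in self.series_list]
            )
        )
        if standardize and "fsle" in {c.split(":")[0] for c in self.design_cols}:
            self.fsle_loc = float(fsle_abs.mean())
            self.fsle_scale = float(fsle_abs.std()) or 1.0
        else:
            self.fsle_loc, self.fsle_scale = 0.0, 1.0
        self._zmat = _design_matrix(
            self.series_list, design, self.fsle_loc, self.fsle_scale
        )
        self._starts, self._ends = _series_bounds(self.series_list)
        self.n_obs = int(self._ends[-1])
        # theta-independent observation terms, cached for the optimizer
        turns = np.concatenate(
            [np.asarray(s.turns, dtype=float) for s in self.series_list]
        )
        self._pos = self._steps > 0
        with np.errstate(divide="ignore"):
            self._logx = np.where(
                self._pos, np.log(np.where(self._pos, self._steps, 1.0)), 0.0
            )
        ok = np.isfinite(turns)
        self._ok_turn = ok
        self._cos_t = np.where(ok, np.cos(turns), 0.0)
        self._sin_t = np.where(ok, np.sin(turns), 0.0)

    # -- likelihood ---------------------------------------------------------

    def _emission_terms(self, em):
        """logb (T,3) and dlogb (T,3,pe) from the cached observation arrays."""
        from scipy.special import digamma, i1e

        shape = em.step_mean**2 / em.step_sd**2
        rate = em.step_mean / em.step_sd**2
        kap = np.clip(em.turn_kappa, 1e-8, None)
        consts = np.column_stack(
            [
                shape,
                rate,
                shape * np.log(rate) - gammaln(shape),
                digamma(shape),
                np.log(2.0 * np.pi) + np.log(i0e(kap)) + kap,
                i1e(kap) / i0e(kap) / kap,
                kap * np.cos(em.turn_mu),
                kap * np.sin(em.turn_mu),
                em.zero_mass,
            ]
        )
        return _emission_core(
            self._steps, self._logx, self._pos, self._ok_turn,
            self._cos_t, self._sin_t, consts, self.zero_inflated,
        )

    def _nll_grad(self, theta):
        """Negative log-likelihood and its exact gradient (uniform trip
        starts), via scaled forward-backward and Fisher's identity."""
        em, beta = _unpack(theta, self.design, self.zero_inflated)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                logb, dlogb = self._emission_terms(em)
        except (ValueError, FloatingPointError):
            return np.inf, np.zeros_like(theta)
        if not (np.isfinite(logb.max(axis=1)).all() and np.isfinite(dlogb).all()):
            return np.inf, np.zeros_like(theta)
        tpm = _tpms(beta, self._zmat)
        delta0 = np.full((len(self.series_list), N_STATES), 1.0 / N_STATES)
        ll, gem, gbeta = _fb_grad_core(
            logb, dlogb, tpm, self._zmat, _ROWMAP,
            self._starts, self._ends, delta0,
        )
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(theta)
        parts = [gem[:, 0], gem[:, 1], gem[:, 2], gem[:, 3]]
        if self.zero_inflated:
            parts.append(gem[:, 4])
        parts.append(gbeta.ravel())
        return -ll, -np.concatenate(parts)

    def _nll(self, theta):
        em, beta = _unpack(theta, self.design, self.zero_inflated)
        try:
            logb = _log_obs_densities(self.series_list, em)
        except (ValueError, FloatingPointError):
            return np.inf
        if not np.isfinite(logb.max(axis=1)).all():
            return np.inf
        tpm = _tpms(beta, self._zmat)
        delta0 = _initial_distributions(
            self.series_list, tpm, self._starts, self.stationary_start
        )
        ll = _forward_core(logb, tpm, self._starts, self._ends, delta0)
        return -ll if np.isfinite(ll) else np.inf

    @property
    def n_params(self):
        return 12 + (3 if self.zero_inflated else 0) + _n_beta(self.design)

    # -- initial values -----------------------------------------------------

    def _random_start(self, rng):
        pos = self._steps[self._steps > 0]
        lo, hi = np.quantile(pos, [0.1, 0.9])
        means = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), N_STATES)))
        sds = means * np.exp(rng.uniform(-0.5, 0.5, N_STATES))
        kappas = np.exp(rng.uniform(np.log(0.5), np.log(30.0), N_STATES))
        em = EmissionParams(means, sds, np.zeros(N_STATES), kappas)
        if self.zero_inflated:
            frac = max((self._steps == 0).mean(), 1e-4)
            em = replace(em, zero_mass=np.full(N_STATES, frac))
        beta = rng.normal(0.0, 0.5, (len(TRANSITION_ROWS), len(self.design_cols)))
        beta[:, 0] -= 2.0  # favour state persistence at start
        return _pack(em, beta, self.zero_inflated)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_restarts: int = 25,
        seed: int | np.random.Generator | None = None,
        maxiter: int = 1500,
        start: np.ndarray | None = None,
    ) -> "MovementHMMResults":
        """Maximise the likelihood over ``n_restarts`` random starts.

        Returns the best converged restart.  A restart that exhausts its
        iteration budget but ends near-stationary (tiny projected gradient
        relative to the objective) is accepted; line-search failures are
        excluded.  Raises ``RuntimeError`` with per-restart diagnostics if
        no restart converges.
        """
        rng = np.random.default_rng(seed)
        rows = []
        best = None
        for r in range(n_restarts):
            theta0 = start if (start is not None and r == 0) else self._random_start(rng)
            res = minimize(
                self._nll_grad,
                theta0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-6},
            )
            near_stationary = np.isfinite(res.fun) and np.max(
                np.abs(np.asarray(res.jac))
            ) < 1e-4 * max(1.0, abs(res.fun))
            ok = np.isfinite(res.fun) and (bool(res.success) or near_stationary)
            rows.append(
                {
                    "restart": r,
                    "loglik": -float(res.fun) if np.isfinite(res.fun) else np.nan,
                    "converged": ok,
                    "n_iter": int(res.nit),
                    "message": str(res.message),
                }
            )
            if ok and (best is None or res.fun < best.fun):
                best = res
        table = pd.DataFrame(rows)
        if best is None:
            raise RuntimeError(
                "no HMM restart converged; diagnostics:\n" + table.to_string()
            )
        return self._results_from_theta(best.x, table)

    def _results_from_theta(self, theta, restarts_table):
        em, beta = _unpack(theta, self.design, self.zero_inflated)
        em, beta = _relabel(em, beta)
        ll = -self._nll(_pack(em, beta, self.zero_inflated))
        return MovementHMMResults(
            model=self,
            emissions=em,
            beta=beta,
            loglik=float(ll),
            restarts_table=restarts_table,
        )


def _relabel(em: EmissionParams, beta):
    """Relabel states by ascending step mean (rest < forage < transit)."""
    order = np.argsort(em.step_mean)
    em2 = EmissionParams(
        em.step_mean[order],
        em.step_sd[order],
        em.turn_mu[order],
        em.turn_kappa[order],
        em.zero_mass[order],
    )
    row_of = {rc: r for r, rc in enumerate(TRANSITION_ROWS)}
    beta2 = np.empty_like(beta)
    for r, (i, j) in enumerate(TRANSITION_ROWS):
        beta2[r] = beta[row_of[(order[i], order[j])]]
    return em2, beta2


class MovementHMMResults:
    """Fitted movement HMM: estimates, fit statistics and decoding."""

    STATE_NAMES = ("rest", "forage", "transit")

    def __init__(self, model, emissions, beta, loglik, restarts_table):
        self.model = model
        self.emissions = emissions
        self.beta = beta  # on the standardized covariate scale
        self.loglik = loglik
        self.restarts_table = restarts_table
        self.n_params = model.n_params
        self.aic = -2.0 * loglik + 2.0 * self.n_params
        self.transitions = TransitionModel(model.design, self.beta_natural)

    # -- coefficient scales -------------------------------------------------

    @property
    def beta_natural(self) -> np.ndarray:
        """Coefficients on the natural (absolute FSLE, unscaled) scale."""
        cols = self.model.design_cols
        b = self.beta.copy()
        m, s = self.model.fsle_loc, self.model.fsle_scale
        if "fsle" in cols:
            jf = cols.index("fsle")
            b[:, cols.index("1")] -= self.beta[:, jf] * m / s
            b[:, jf] = self.beta[:, jf] / s
        if "fsle:age" in cols:
            jfa = cols.index("fsle:age")
            b[:, cols.index("age")] -= self.beta[:, jfa] * m / s
            b[:, jfa] = self.beta[:, jfa] / s
        return b

    def transition_matrix(self, fsle: float, age: int) -> np.ndarray:
        """Predicted 3x3 transition matrix at a covariate value."""
        return transition_matrix(
            self.transitions, {"fsle": abs(fsle), "age": float(age)}
        )

    # -- decoding -----------------------------------------------------------

    def decode(self, series_list=None) -> list[np.ndarray]:
        """Viterbi state sequences (1-based) for each series."""
        series_list = self.model.series_list if series_list is None else series_list
        out = []
        for s in series_list:
            logb = _log_obs_densities([s], self.emissions)
            zmat = _design_matrix(
                [s], self.model.design, self.model.fsle_loc, self.model.fsle_scale
            )
            tpm = _tpms(self.beta, zmat)
            delta0 = _initial_distributions(
                [s], tpm, np.array([0]), self.model.stationary_start
            )
            with np.errstate(divide="ignore"):
                states = _viterbi_core(logb, np.log(tpm), np.log(delta0[0]))
            out.append(states + 1)
        return out

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Three-state movement HMM",
            f"  design: {self.model.design}   trips: {len(self.model.series_list)}"
            f"   steps: {self.model.n_obs}",
            f"  loglik: {self.loglik:.2f}   params: {self.n_params}"
            f"   AIC: {self.aic:.2f}",
            "",
            "State-dependent distributions",
            "  state    step mean  step sd   turn mu  turn kappa",
        ]
        for k, name in enumerate(self.STATE_NAMES):
            lines.append(
                f"  {name:<8} {self.emissions.step_mean[k]:>8.3f}"
                f" {self.emissions.step_sd[k]:>8.3f}"
                f" {self.emissions.turn_mu[k]:>9.3f}"
                f" {self.emissions.turn_kappa[k]:>10.2f}"
            )
        lines += ["", "Transition coefficients (natural covariate scale)"]
        cols = self.model.design_cols
        lines.append("  transition        " + "".join(f"{c:>12}" for c in cols))
        bn = self.beta_natural
        for r, (i, j) in enumerate(TRANSITION_ROWS):
            nm = f"{self.STATE_NAMES[i]}->{self.STATE_NAMES[j]}"
            lines.append(
                f"  {nm:<16}" + "".join(f"{bn[r, c]:>12.3f}" for c in range(len(cols)))
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "design": self.model.design,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "step_mean": self.emissions.step_mean.tolist(),
            "step_sd": self.emissions.step_sd.tolist(),
            "turn_mu": self.emissions.turn_mu.tolist(),
            "turn_kappa": self.emissions.turn_kappa.tolist(),
            "zero_mass": self.emissions.zero_mass.tolist(),
            "beta_standardized": self.beta.tolist(),
            "beta_natural": self.beta_natural.tolist(),
            "fsle_loc": self.model.fsle_loc,
            "fsle_scale": self.model.fsle_scale,
            "restarts": self.restarts_table.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def fit(series_list, design="fsle*age", n_restarts=25, seed=None, **kwargs):
    """Convenience wrapper: build a :class:`MovementHMM` and fit it."""
    return MovementHMM(series_list, design=design, **kwargs).fit(
        n_restarts=n_restarts, seed=seed
    )


def _embed_start(prev: "MovementHMMResults", model: "MovementHMM"):
    """Warm-start vector for ``model`` from a fit of a (sub)design on the
    same data: shared coefficient columns carry over, new columns start at
    zero."""
    prev_cols = prev.model.design_cols
    beta = np.zeros((len(TRANSITION_ROWS), len(model.design_cols)))
    for j, c in enumerate(model.design_cols):
        if c in prev_cols:
            beta[:, j] = prev.beta[:, prev_cols.index(c)]
    return _pack(prev.emissions, beta, model.zero_inflated)


def rank_models(
    series_list,
    designs=DEFAULT_DESIGNS,
    n_restarts: int = 25,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit each candidate design and rank by AIC (ascending).

    Returns a DataFrame with ``design, loglik, n_params, aic, delta_aic``
    and attaches the fitted results in ``.attrs["fits"]``.
    """
    ss = np.random.SeedSequence(seed)
    fits = {}
    rows = []
    # fit nested designs first and warm-start each larger design from the
    # previous fit, so the log-likelihood respects nesting by construction
    order = sorted(designs, key=lambda d: len(design_columns(d)))
    children = dict(zip(order, ss.spawn(len(order))))
    prev = None
    for design in order:
        model = MovementHMM(series_list, design=design, **kwargs)
        start = _embed_start(prev, model) if prev is not None else None
        res = model.fit(
            n_restarts=n_restarts,
            seed=np.random.default_rng(children[design]),
            start=start,
        )
        prev = res
        fits[design] = res
        rows.append(
            {
                "design": design,
                "loglik": res.loglik,
                "n_params": res.n_params,
                "aic": res.aic,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table.attrs["fits"] = fits
    return table
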