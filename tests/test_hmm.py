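import numpy as np
import pytest
from scipy import integrate, stats

import frontforage as ff
from frontforage.hmm import (
    MovementHMM,
    design_columns,
    forward_loglik,
    stationary_distribution,
    transition_matrix,
)
from conftest import brute_force_loglik, make_series, random_hmm, random_series


class TestStepDensity:
    def test_exponential_limit_at_mean_equals_sd(self):
        # shape 1 -> exponential; density at 0+ equals the rate
        mean = sd = 0.5
        rate = mean / sd**2
        assert ff.step_density(1e-12, mean, sd) == pytest.approx(rate, rel=1e-6)

    def test_normalization_with_zero_mass(self):
        val, _ = integrate.quad(lambda x: ff.step_density(x, 0.4, 0.3, 0.2), 0, 20)
        assert val == pytest.approx(0.8, abs=1e-6)

    def test_matches_scipy_gamma_for_reported_forage_state(self):
        # forage state: mean 0.41, sd 0.54 -> shape ~0.576, rate ~1.406
        mean, sd = 0.41, 0.54
        shape = mean**2 / sd**2
        scale = sd**2 / mean
        assert shape == pytest.approx(0.5764, abs=1e-4)
        assert 1 / scale == pytest.approx(1.4060, abs=1e-3)
        x = np.array([0.05, 0.41, 1.3])
        np.testing.assert_allclose(
            ff.step_density(x, mean, sd),
            stats.gamma.pdf(x, a=shape, scale=scale),
            rtol=1e-10,
        )

    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            ff.step_density(0.1, -1.0, 0.5)
        with pytest.raises(ValueError):
            ff.step_density(0.1, np.nan, 0.5)


class TestTurnDensity:
    def test_uniform_limit_small_kappa(self):
        phi = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(
            ff.turn_density(phi, 0.0, 1e-10), 1 / (2 * np.pi), rtol=1e-6
        )

    def test_normalization(self):
        val, _ = integrate.quad(
            lambda p: ff.turn_density(p, 0.4, 22.3), -np.pi, np.pi
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_bessel_series_at_high_concentration(self):
        # I0 via its power series, independent of scipy
        kappa = 22.3
        term, i0 = 1.0, 1.0
        for m in range(1, 200):
            term *= (kappa / 2.0) ** 2 / m**2
            i0 += term
            if term < 1e-18 * i0:
                break
        expect = np.exp(kappa) / (2 * np.pi * i0)
        assert ff.turn_density(0.0, 0.0, kappa) == pytest.approx(expect, rel=1e-10)


class TestTransitionMatrix:
    def test_zero_beta_gives_uniform_rows(self):
        tm = ff.TransitionModel("fsle*age", np.zeros((6, 4)))
        g = transition_matrix(tm, {"fsle": 0.3, "age": 1})
        np.testing.assert_allclose(g, 1 / 3)

    def test_rows_sum_to_one_for_extreme_covariates(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tm = ff.TransitionModel("fsle*age", rng.normal(0, 5, (6, 4)))
            g = transition_matrix(tm, {"fsle": rng.uniform(0, 100), "age": 1})
            np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)
            assert (g >= 0).all()

    def test_monotone_in_fsle_with_positive_coefficient(self):
        beta = np.zeros((6, 4))
        beta[5, 1] = 2.0  # transit->forage rises with frontal intensity
        tm = ff.TransitionModel("fsle*age", beta)
        vals = [
            transition_matrix(tm, {"fsle": f, "age": 0})[2, 1]
            for f in np.linspace(0, 2, 9)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_saturation_limit(self):
        beta = np.zeros((6, 4))
        beta[0, 0] = 200.0  # rest->forage intercept -> +inf
        tm = ff.TransitionModel("fsle*age", beta)
        g = transition_matrix(tm, {"fsle": 0.0, "age": 0})
        assert g[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert g[0, 0] == pytest.approx(0.0, abs=1e-12)


class TestForwardLoglik:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            em, tm = random_hmm(rng)
            s = random_series(rng, int(rng.integers(2, 7)))
            ll = forward_loglik([s], em, tm)
            bf, _ = brute_force_loglik(s, em, tm)
            assert ll == pytest.approx(bf, abs=1e-10)

    def test_single_state_degenerate_is_sum_of_emissions(self):
        em = ff.EmissionParams([0.1, 0.5, 1.5], [0.1, 0.3, 0.4], [0, 0, 0], [5, 1, 9])
        beta = np.zeros((6, 1))
        beta[:, 0] = -500.0
        # all mass stays in the start state; with uniform start over k states
        # the likelihood is a mixture of pure-state paths
        tm = ff.TransitionModel("~1", beta)
        s = make_series([0.5, 0.6, 0.55], [np.nan, 0.1, -0.2])
        ll = forward_loglik([s], em, tm)
        per_state = []
        for k in range(3):
            lp = np.log(ff.step_density(s.steps, em.step_mean[k], em.step_sd[k])).sum()
            lp += np.log(
                ff.turn_density(s.turns[1:], em.turn_mu[k], em.turn_kappa[k])
            ).sum()
            per_state.append(lp)
        expect = np.log(np.mean(np.exp(per_state)))
        assert ll == pytest.approx(expect, abs=1e-8)

    def test_duplicating_a_trip_doubles_its_contribution(self):
        rng = np.random.default_rng(3)
        em, tm = random_hmm(rng)
        s = random_series(rng, 12)
        assert forward_loglik([s, s], em, tm) == pytest.approx(
            2 * forward_loglik([s], em, tm), abs=1e-9
        )

    def test_zero_density_observation_names_trip(self):
        em = ff.EmissionParams([0.1, 0.5, 1.5], [0.1, 0.3, 0.4], [0, 0, 0], [5, 1, 9])
        tm = ff.TransitionModel("~1", np.zeros((6, 1)))
        s = make_series([0.5, 0.0, 0.5], trip_id="badtrip")  # zero step, no zero mass
        with pytest.raises(ValueError, match="badtrip"):
            forward_loglik([s], em, tm)


class TestViterbi:
    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            em, tm = random_hmm(rng)
            s = random_series(rng, 6)
            model = MovementHMM([s], design="fsle*age", standardize=False)
            res = ff.MovementHMMResults(
                model, em, tm.beta, 0.0, None
            )
            vit = ff.viterbi(s, res) - 1
            _, best = brute_force_loglik(s, em, tm)
            np.testing.assert_array_equal(vit, best)

    def test_perfectly_separated_emissions_recover_truth(self):
        em = ff.EmissionParams([0.01, 1.0, 100.0], [0.005, 0.05, 5.0],
                               [0, 0, 0], [1, 1, 1])
        tm = ff.TransitionModel("~1", np.zeros((6, 1)))
        truth = np.array([0, 0, 1, 1, 2, 2, 1, 0])
        steps = np.array([0.01, 0.012, 1.0, 1.1, 100.0, 95.0, 0.9, 0.011])
        s = make_series(steps)
        model = MovementHMM([s], design="~1", standardize=False)
        res = ff.MovementHMMResults(model, em, tm.beta, 0.0, None)
        np.testing.assert_array_equal(res.decode([s])[0] - 1, truth)


@pytest.fixture(scope="module")
def tiny_fit():
    rng = np.random.default_rng(0)
    em = ff.EmissionParams([0.05, 0.5, 1.8], [0.03, 0.4, 0.5], [0, 0, 0],
                           [15, 1, 15])
    # persistent 3-state chain, no covariate effects
    beta = np.full((6, 1), -2.0)
    tm = ff.TransitionModel("~1", beta)
    series = []
    for _ in range(6):
        T = 120
        states = np.zeros(T, dtype=int)
        g = transition_matrix(tm, [1.0])
        for t in range(1, T):
            states[t] = rng.choice(3, p=g[states[t - 1]])
        steps = rng.gamma(
            em.step_mean[states] ** 2 / em.step_sd[states] ** 2,
            em.step_sd[states] ** 2 / em.step_mean[states],
        )
        turns = rng.vonmises(0.0, em.turn_kappa[states])
        turns[0] = np.nan
        series.append(make_series(steps, turns))
    model = MovementHMM(series, design="~1")
    return model, model.fit(n_restarts=4, seed=1)


class TestFit:
    def test_refit_from_optimum_is_fixed_point(self, tiny_fit):
        from frontforage.hmm import _pack

        model, res = tiny_fit
        theta = _pack(res.emissions, res.beta, model.zero_inflated)
        res2 = model.fit(n_restarts=1, seed=0, start=theta)
        assert abs(res2.loglik - res.loglik) < 1e-6

    def test_states_relabelled_by_step_mean(self, tiny_fit):
        _, res = tiny_fit
        assert np.all(np.diff(res.emissions.step_mean) > 0)

    def test_aic_identity_and_summary(self, tiny_fit):
        _, res = tiny_fit
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.n_params)
        out = res.summary()
        assert "rest" in out and "transit" in out and "AIC" in out

    def test_standardization_leaves_loglik_invariant(self, small_cohort):
        series = small_cohort["series"][:40]
        m_std = MovementHMM(series, design="fsle*age", standardize=True)
        res = m_std.fit(n_restarts=2, seed=3)
        # evaluate the back-transformed coefficients on the natural scale
        ll_nat = forward_loglik(
            series, res.emissions, ff.TransitionModel("fsle*age", res.beta_natural)
        )
        assert ll_nat == pytest.approx(res.loglik, abs=1e-5)


class TestRankModels:
    def test_single_design_delta_zero(self, small_cohort):
        series = small_cohort["series"][:25]
        table = ff.rank_models(series, designs=("~1",), n_restarts=2, seed=0)
        assert table["delta_aic"].iloc[0] == 0.0

    def test_nested_designs_loglik_ordering(self, small_cohort):
        series = small_cohort["series"][:25]
        table = ff.rank_models(
            series, designs=("fsle*age", "fsle", "~1"), n_restarts=2, seed=0
        )
        ll = table.set_index("design")["loglik"]
        assert ll["fsle*age"] >= ll["fsle"] - 1e-4
        assert ll["fsle"] >= ll["~1"] - 1e-4


def test_design_column_resolution():
    assert design_columns("~1") == ("1",)
    assert design_columns("FSLE * age") == ("1", "fsle", "age", "fsle:age")
    with pytest.raises(ValueError):
        design_columns("fsle^2")


def test_stationary_distribution_is_left_eigenvector():
    rng = np.random.default_rng(5)
    g = rng.dirichlet(np.ones(3), size=3)
    pi = stationary_distribution(g)
    np.testing.assert_allclose(pi @ g, pi, atol=1e-12)
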