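import numpy as np
import pandas as pd
import pytest

from frontforage.projection import wrap_angle
from frontforage.repeatability import (
    circular_repeatability,
    fisher_z,
    fit_lmm,
    lrt_age,
    repeatability,
    repeatability_table,
    zr_difference,
    zr_difference_table,
)


def balanced(nb, nt, sd_id, sd_res, rng, mu=0.0):
    y = (mu + rng.normal(0, sd_id, nb)[:, None] + rng.normal(0, sd_res, (nb, nt))).ravel()
    return y, np.repeat(np.arange(nb), nt)


class TestLMM:
    def test_pure_between_bird_variance_gives_r_one(self):
        y = np.repeat([1.0, 5.0, -2.0, 9.0], 4)  # identical within birds
        ids = np.repeat(np.arange(4), 4)
        f = fit_lmm(y, ids)
        assert f.sigma2_res < 1e-6 * f.sigma2_id
        assert f.icc > 1.0 - 1e-6

    def test_matches_balanced_anova_closed_form(self):
        rng = np.random.default_rng(4)
        y, ids = balanced(6, 5, 2.0, 1.0, rng)
        f = fit_lmm(y, ids)
        Y = y.reshape(6, 5)
        msb = 5 * ((Y.mean(1) - y.mean()) ** 2).sum() / 5
        msw = ((Y - Y.mean(1, keepdims=True)) ** 2).sum() / (6 * 4)
        assert f.sigma2_res == pytest.approx(msw, abs=1e-10)
        assert f.sigma2_id == pytest.approx((msb - msw) / 5, abs=1e-10)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        nb, nt = 10, 4
        age = np.repeat(rng.integers(0, 2, nb), nt)
        y, ids = balanced(nb, nt, 1.2, 0.9, rng)
        y = y + 0.7 * age
        f = fit_lmm(y, ids, age=age)
        mm = sm.MixedLM(y, np.column_stack([np.ones(len(y)), age]), groups=ids).fit(
            reml=True
        )
        assert f.sigma2_id == pytest.approx(float(np.asarray(mm.cov_re)[0, 0]), abs=1e-4)
        assert f.sigma2_res == pytest.approx(float(mm.scale), abs=1e-4)
        assert f.fe_params["age"] == pytest.approx(float(np.asarray(mm.params)[1]), abs=1e-6)

    def test_single_trip_birds_unidentifiable(self):
        with pytest.raises(ValueError):
            fit_lmm([1.0, 2.0, 3.0], ["a", "b", "c"])

    def test_lrt_null_calibration(self):
        """With no true age effect, the LRT p-value is roughly uniform
        (chi-square asymptotics need a reasonable number of birds)."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            nb, nt = 24, 4
            y, ids = balanced(nb, nt, 1.0, 1.0, rng)
            age = np.repeat(np.arange(nb) % 2, nt)
            ps.append(lrt_age(y, ids, age)[1])
        assert np.mean(np.array(ps) < 0.05) <= 0.10

    def test_lrt_detects_strong_effect(self):
        rng = np.random.default_rng(1)
        nb, nt = 12, 5
        age = np.repeat(np.array([0] * 6 + [1] * 6), nt)
        y, ids = balanced(nb, nt, 0.5, 0.5, rng)
        y = y + 3.0 * age
        stat, p = lrt_age(y, ids, age)
        assert p < 1e-3


class TestRepeatability:
    def test_equal_variances_give_half(self):
        rng = np.random.default_rng(3)
        y, ids = balanced(60, 20, 1.0, 1.0, rng)
        res = repeatability(y, ids, n_boot=50, seed=1)
        assert res.R == pytest.approx(0.5, abs=0.08)

    def test_no_individual_effect_gives_near_zero_with_zero_lower_bound(self):
        rng = np.random.default_rng(5)
        y, ids = balanced(15, 6, 0.0, 1.0, rng)
        res = repeatability(y, ids, n_boot=200, seed=2)
        assert res.R < 0.15
        assert res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        y, ids = balanced(10, 5, 1.5, 0.8, rng)
        r1 = repeatability(y, ids, n_boot=10, seed=0).R
        r2 = repeatability(3.7 * y - 11.0, ids, n_boot=10, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_monotone_in_between_bird_spread(self):
        rng = np.random.default_rng(7)
        rs = []
        base = rng.normal(0, 1, (12, 6))
        u = rng.normal(0, 1, 12)
        ids = np.repeat(np.arange(12), 6)
        for scale in (0.2, 0.8, 1.6, 3.2):
            y = (scale * u[:, None] + base).ravel()
            rs.append(fit_lmm(y, ids).icc)
        assert all(b >= a for a, b in zip(rs, rs[1:]))


class TestZr:
    def test_fisher_z_fixed_points(self):
        assert fisher_z(0.0) == 0.0
        r = 0.87
        assert fisher_z(r) == pytest.approx(0.5 * np.log((1 + r) / (1 - r)))

    def test_identical_groups_difference_straddles_zero(self):
        rng = np.random.default_rng(9)
        y1, ids = balanced(12, 6, 1.0, 1.0, rng)
        y2, _ = balanced(12, 6, 1.0, 1.0, rng)
        r1 = repeatability(y1, ids, n_boot=300, seed=1)
        r2 = repeatability(y2, ids, n_boot=300, seed=2)
        dz, (lo, hi) = zr_difference(r1, r2)
        assert lo < 0 < hi

    def test_missing_draws_error(self):
        from frontforage.repeatability import RepeatabilityResult

        a = RepeatabilityResult(0.5, 0.3, 0.7, fisher_z(0.5))
        with pytest.raises(ValueError):
            zr_difference(a, a)


class TestCircular:
    def test_fixed_angle_per_bird_gives_one(self):
        ang = np.repeat([0.2, 1.7, -2.4, 3.0], 5)
        ids = np.repeat(np.arange(4), 5)
        res = circular_repeatability(ang, ids, n_boot=20, seed=0)
        assert res.R == pytest.approx(1.0, abs=1e-9)

    def test_uniform_angles_tend_to_zero(self):
        rng = np.random.default_rng(10)
        ang = rng.uniform(-np.pi, np.pi, 10 * 400)
        ids = np.repeat(np.arange(10), 400)
        res = circular_repeatability(ang, ids, n_boot=20, seed=0)
        assert res.R < 0.05

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        ang = rng.vonmises(rng.uniform(-np.pi, np.pi, 8)[np.repeat(np.arange(8), 6)], 4.0)
        ids = np.repeat(np.arange(8), 6)
        r1 = circular_repeatability(ang, ids, n_boot=5, seed=0).R
        r2 = circular_repeatability(wrap_angle(ang + 2.1), ids, n_boot=5, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_needs_repeated_measures(self):
        with pytest.raises(ValueError):
            circular_repeatability([0.1, 0.2], [0, 1], n_boot=5, seed=0)


class TestTables:
    def test_repeatability_and_zr_tables(self):
        rng = np.random.default_rng(13)
        rows = []
        for grp, nbird, sd_id in (("adult", 8, 1.5), ("immature", 6, 0.2)):
            for b in range(nbird):
                mu_b = rng.normal(0, sd_id)
                angle_b = rng.uniform(-np.pi, np.pi)
                for t in range(5):
                    rows.append(
                        {
                            "bird_id": f"{grp[0]}{b}",
                            "age_class": grp,
                            "duration_h": float(np.exp(2 + mu_b + rng.normal(0, 0.5))),
                            "length_km": float(np.exp(5 + mu_b + rng.normal(0, 0.5))),
                            "range_km": float(50 + 10 * mu_b + rng.normal(0, 5)),
                            "terminal_x": float(1e4 * mu_b + rng.normal(0, 1e4)),
                            "terminal_y": float(1e4 * mu_b + rng.normal(0, 1e4)),
                            "area_km2": float(np.exp(7 + mu_b + rng.normal(0, 0.6))),
                            "departure_angle": float(
                                wrap_angle(angle_b + rng.vonmises(0, 8.0))
                            ),
                        }
                    )
        metrics = pd.DataFrame(rows)
        table = repeatability_table(metrics, n_boot=60, seed=3)
        assert set(table["group"]) == {"adult", "immature"}
        assert ((table["R"] >= 0) & (table["R"] <= 1)).all()
        assert ((table["ci_low"] <= table["R"] + 1e-9)).all()
        ztab = zr_difference_table(table)
        assert len(ztab) == 7
        assert {"zr_diff", "ci_low", "ci_high"} <= set(ztab.columns)
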