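"""Statistical battery vs independent oracles (enumeration, brute force,
hand formulas, leave-one-out refits, pingouin cross-checks)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from emovoc import stats as st


def exact_rank_sum_p(x, y):
    """Full-enumeration two-sided p for the rank-sum statistic (no ties)."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:nx].sum() - nx * (nx + 1) / 2  # Mann-Whitney U of x
    us = []
    for idx in itertools.combinations(range(n), nx):
        r = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        us.append(r)
    us = np.asarray(us)
    mu = nx * (n - nx) / 2
    return np.mean(np.abs(us - mu) >= abs(w_obs - mu) - 1e-9)


class TestWilcoxon:
    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 5.5, 9.0]
        w, p = st.wilcoxon_rank_sum(x, list(x))
        assert p > 0.9

    def test_all_constant_convention(self):
        w, p = st.wilcoxon_rank_sum([3, 3, 3], [3, 3])
        assert p == 1.0

    def test_tiny_exact_enumeration_value(self):
        # x={1,2}, y={3,4}: the 6 assignments give two-sided p = 2/6
        _, p = st.wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_dominant_shift_gives_extreme_w(self):
        x = [101, 102, 103, 104, 105]
        y = [1, 2, 3, 4, 5]
        w, p = st.wilcoxon_rank_sum(x, y)
        assert w == 25  # every pair won by x
        assert p == pytest.approx(2 / math.comb(10, 5))  # the two extreme assignments

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(4, 9))
        y = rng.normal(0.8, size=rng.integers(4, 9))
        _, p = st.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)

    @pytest.mark.parametrize("n", [8, 9, 10])
    def test_exact_vs_normal_approximation_close(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        y = rng.normal(0.5, size=n)
        _, p_exact = st.wilcoxon_rank_sum(x, y, exact=True)
        _, p_approx = st.wilcoxon_rank_sum(x, y, exact=False)
        assert abs(p_exact - p_approx) < 0.02


class TestVarghaDelaney:
    def test_identical_samples_half(self):
        a, interp = st.vda_effect_size([1, 2, 3], [1, 2, 3])
        assert a == pytest.approx(0.5)
        assert interp == "negligible"

    def test_complete_dominance(self):
        a, interp = st.vda_effect_size([10, 11], [1, 2])
        assert a == 1.0 and interp == "large"

    def test_hand_counted_quartet(self):
        a, interp = st.vda_effect_size([1, 3], [2, 4])
        assert a == pytest.approx(0.25)
        assert interp == "large"

    @pytest.mark.parametrize(
        "a,band",
        [
            (0.50, "negligible"), (0.45, "negligible"), (0.55, "negligible"),
            (0.56, "small"), (0.63, "small"), (0.44, "small"), (0.35, "small"),
            (0.64, "medium"), (0.70, "medium"), (0.34, "medium"), (0.30, "medium"),
            (0.71, "large"), (0.29, "large"), (0.0, "large"), (1.0, "large"),
        ],
    )
    def test_interpretation_band_boundaries(self, a, band):
        assert st.interpret_vda(a) == band

    def test_bands_partition_unit_interval(self):
        for a in np.linspace(0, 1, 2001):
            assert st.interpret_vda(float(a)) in {
                "negligible", "small", "medium", "large"
            }

    @settings(max_examples=60, deadline=None)
    @given(
        x=hs.lists(hs.integers(0, 30), min_size=1, max_size=50),
        y=hs.lists(hs.integers(0, 30), min_size=1, max_size=50),
    )
    def test_matches_brute_force_pair_counting(self, x, y):
        a, _ = st.vda_effect_size(x, y)
        wins = sum(1 for xi in x for yi in y if xi > yi)
        ties = sum(1 for xi in x for yi in y if xi == yi)
        assert a == pytest.approx((wins + 0.5 * ties) / (len(x) * len(y)))

    @settings(max_examples=40, deadline=None)
    @given(
        x=hs.lists(hs.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        y=hs.lists(hs.floats(2, 3, allow_nan=False), min_size=1, max_size=30),
    )
    def test_complementarity(self, x, y):
        a_xy, _ = st.vda_effect_size(x, y)
        a_yx, _ = st.vda_effect_size(y, x)
        assert a_xy + a_yx == pytest.approx(1.0)


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert st.spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert st.spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_rank_formula_with_tie(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 4, 6, 5]
        rho, _ = st.spearman(x, y)
        rx = pd.Series(x).rank()
        ry = pd.Series(y).rank()
        byhand = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(byhand)

    def test_zero_variance_undefined(self):
        rho, p = st.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho)

    def test_partial_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        z = rng.normal(size=40)
        x = z + rng.normal(size=40)
        y = -z + rng.normal(size=40)
        rho, p = st.partial_spearman(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_partial_removes_common_driver(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=300)
        x = 2 * z + rng.normal(size=300)
        y = 3 * z + rng.normal(size=300)
        rho_raw, _ = st.spearman(x, y)
        rho_part, _ = st.partial_spearman(x, y, z)
        assert rho_raw > 0.5
        assert abs(rho_part) < 0.2


class TestWelchChi2:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p = st.welch_t(x, x)
        assert t == 0 and p == pytest.approx(1.0)
        assert st.cohen_d(x, x) == 0

    def test_closed_form_two_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        t, df, p = st.welch_t(x, y)
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 4
        t_hand = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 3)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        sp = math.sqrt(((2) * x.var(ddof=1) + 3 * y.var(ddof=1)) / 5)
        assert st.cohen_d(x, y) == pytest.approx((x.mean() - y.mean()) / sp)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(1, size=12)
        t1, _, _ = st.welch_t(x, y)
        t2, _, _ = st.welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert st.cohen_d(x, y) == pytest.approx(-st.cohen_d(y, x))

    def test_chi2_proportional_table_zero(self):
        chi2, df, p = st.chi_square_independence([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_hand_formula_2x2(self):
        chi2, df, _ = st.chi_square_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3)
        assert df == 1

    def test_chi2_df_for_2x5(self):
        table = [[5, 6, 7, 8, 6], [6, 5, 9, 7, 5]]
        _, df, _ = st.chi_square_independence(table)
        assert df == 4

    def test_chi2_zero_marginal_undefined(self):
        with pytest.raises(ValueError, match="marginal"):
            st.chi_square_independence([[0, 0], [5, 5]])


def _sim_logistic(n, beta, rng):
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
    })
    eta = beta[0] + beta[1] * X["x1"] + beta[2] * X["x2"]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return X, y


class TestLogistic:
    def test_null_model_baseline_classification(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(30), np.zeros(30)]
        X = pd.DataFrame({"x": rng.normal(size=60)})
        fit = st.logistic_fit(X, y)
        assert fit.params["const"] == pytest.approx(0.0, abs=0.7)
        assert fit.classification_rate >= fit.baseline_rate - 0.25

    def test_single_binary_predictor_or_equals_cross_product_ratio(self):
        # 2x2 table: exposed 30/10, unexposed 15/45
        y = np.r_[np.ones(30), np.zeros(10), np.ones(15), np.zeros(45)]
        x = np.r_[np.ones(40), np.zeros(60)]
        fit = st.logistic_fit(pd.DataFrame({"x": x}), y)
        cross = (30 * 45) / (10 * 15)
        assert fit.odds_ratios.loc["x", "or"] == pytest.approx(cross, rel=1e-4)

    def test_parameter_recovery_within_2se(self):
        rng = np.random.default_rng(12)
        beta = (-0.4, 0.8, -0.6)
        X, y = _sim_logistic(2000, beta, rng)
        fit = st.logistic_fit(X, y)
        for name, true in zip(("const", "x1", "x2"), beta):
            assert abs(fit.params[name] - true) < 2 * fit.bse[name]

    def test_nagelkerke_bounds_cox_snell(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X, y = _sim_logistic(150, (0.2, 0.5, -0.3), rng)
            if len(set(y)) < 2:
                continue
            fit = st.logistic_fit(X, y)
            assert 0 <= fit.r2_cox_snell <= fit.r2_nagelkerke <= 1

    def test_aic_and_model_chi2_consistency(self):
        rng = np.random.default_rng(2)
        X, y = _sim_logistic(200, (0.0, 1.0, 0.0), rng)
        fit = st.logistic_fit(X, y)
        assert fit.aic == pytest.approx(fit.deviance + 2 * 3)
        assert fit.model_chi2 == pytest.approx(fit.null_deviance - fit.deviance)
        assert fit.model_df == 2

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        with pytest.raises(st.SeparationError):
            st.logistic_fit(pd.DataFrame({"x": x}), y)

    def test_wald_z_is_param_over_se(self):
        rng = np.random.default_rng(3)
        X, y = _sim_logistic(300, (0.1, 0.7, -0.2), rng)
        fit = st.logistic_fit(X, y)
        for name in fit.params.index:
            assert fit.wald_z[name] == pytest.approx(fit.params[name] / fit.bse[name])


class TestHosmerLemeshow:
    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(0)
        X, y = _sim_logistic(200, (0.0, 0.8, 0.5), rng)
        fit = st.logistic_fit(X, y)
        _, df, _ = st.hosmer_lemeshow(fit, n_groups=10)
        assert df == 8

    def test_hand_computed_four_group_fixture(self):
        probs = np.repeat([0.1, 0.3, 0.6, 0.9], 10)
        rng = np.random.default_rng(9)
        y = rng.binomial(1, probs)
        chi2, df, p = st.hosmer_lemeshow(probs, y, n_groups=4)
        hand = 0.0
        for lo in (0.1, 0.3, 0.6, 0.9):
            mask = probs == lo
            o1, e1 = y[mask].sum(), probs[mask].sum()
            o0, e0 = (1 - y[mask]).sum(), (1 - probs[mask]).sum()
            hand += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        assert chi2 == pytest.approx(hand)
        assert df == 2

    def test_calibrated_model_p_not_extreme(self):
        # well-specified model: HL p should rarely be tiny
        rng = np.random.default_rng(11)
        small = 0
        for _ in range(20):
            X, y = _sim_logistic(300, (0.0, 1.0, -0.5), rng)
            fit = st.logistic_fit(X, y)
            _, _, p = st.hosmer_lemeshow(fit)
            small += p < 0.05
        assert small <= 4


class TestBoxTidwellVifCooks:
    def test_linear_logit_rarely_flagged(self):
        rng = np.random.default_rng(21)
        flagged = 0
        for _ in range(20):
            n = 300
            x = rng.uniform(0.5, 3.0, size=n)
            y = rng.binomial(1, 1 / (1 + np.exp(-(x - 1.5))))
            if len(set(y)) < 2:
                continue
            ps = st.box_tidwell(pd.DataFrame({"x": x}), y, ["x"])
            flagged += ps["x"] < 0.05
        assert flagged <= 4

    def test_strong_quadratic_logit_flagged(self):
        rng = np.random.default_rng(22)
        n = 800
        x = rng.uniform(0.5, 4.0, size=n)
        eta = -4 + 2.5 * (x - 2.0) ** 2
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        ps = st.box_tidwell(pd.DataFrame({"x": x}), y, ["x"])
        assert ps["x"] < 0.05

    def test_zero_containing_predictor_requires_shift(self):
        rng = np.random.default_rng(23)
        x = np.r_[np.zeros(4), rng.uniform(0.5, 3.0, size=196)]
        y = rng.binomial(1, 1 / (1 + np.exp(-(x - 1.2))))
        with pytest.raises(ValueError, match="strictly positive"):
            st.box_tidwell(pd.DataFrame({"x": x}), y, ["x"])
        ps = st.box_tidwell(pd.DataFrame({"x": x}), y, ["x"], shift=True)
        assert 0 <= ps["x"] <= 1

    def test_vif_orthogonal_predictors_near_one(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        assert (st.vif(X) < 1.1).all()

    def test_vif_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": a})
        v = st.vif(X)
        assert np.isinf(v).all() or (v > 1e10).all()

    def test_cooks_distance_matches_leave_one_out_refit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        X, y = _sim_logistic(60, (0.2, 1.0, -0.8), rng)
        fit = st.logistic_fit(X, y)
        cd = st.cooks_distance(fit)
        Xc = fit.exog.to_numpy()
        probs = fit.fitted_probs
        W = probs * (1 - probs)
        XtWX = Xc.T @ (Xc * W[:, None])
        k = Xc.shape[1]
        beta = fit.params.to_numpy()
        refit_cd = np.empty(len(y))
        for i in range(len(y)):
            mask = np.ones(len(y), bool)
            mask[i] = False
            res_i = sm.Logit(fit.outcome[mask], Xc[mask]).fit(disp=0)
            diff = beta - res_i.params
            refit_cd[i] = diff @ XtWX @ diff / k
        # one-step approximation: near-exact for ordinary points, within
        # ~40% relative on the most influential ones
        assert np.corrcoef(cd, refit_cd)[0, 1] > 0.95
        assert np.allclose(cd, refit_cd, rtol=0.4, atol=0.01)


class TestCompareGroups:
    def test_wilcoxon_bundle(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(2, size=20)
        comp = st.compare_groups(x, y)
        assert comp.statistic_name == "W" and comp.effect_size_name == "A"
        assert comp.effect_size < 0.3 and comp.interpretation == "large"

    def test_welch_bundle(self):
        comp = st.compare_groups([1, 2, 3, 4], [1, 2, 3, 4], method="welch")
        assert comp.statistic == 0 and comp.interpretation == "negligible"
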