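"""Statistical machinery: independent oracles, subgroup selection, and
parameter recovery on the generative model."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from firesmoke.analysis import (
    SUBGROUP_RULES,
    SubgroupRule,
    fit_semi_model,
    linearity_test,
    oneway_anova,
    ols_fit,
    pearson_r,
    run_analysis,
    select_subgroup,
)
from firesmoke.simulate import (
    SimConfig,
    compute_exposure_summary,
    generate_cohort,
    generate_grid,
)
from firesmoke.types import SmokingStatus, UrineSample, ValidationError

from conftest import constant_grid, day, make_deployment, make_record


# ---------------------------------------------------------------------------
# independent oracles


def normal_equations(y, X):
    """Brute-force OLS: beta = (X'X)^-1 X'y, classical SEs, t p-values."""
    Xm = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
    resid = y - Xm @ beta
    df = len(y) - Xm.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * st.t.sf(np.abs(t), df)
    return beta, se, p


def anova_by_sums_of_squares(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = all_vals.size
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = st.f.sf(f, k - 1, n - k)
    return f, p


def contrast_t(groups):
    """Brute-force linear-trend contrast across ordered levels."""
    levels = sorted(groups)
    scores = np.array(levels, float)
    c = scores - scores.mean()
    means = np.array([np.mean(groups[l]) for l in levels])
    ns = np.array([len(groups[l]) for l in levels])
    df = int(ns.sum()) - len(levels)
    msw = sum(((np.asarray(groups[l]) - np.mean(groups[l])) ** 2).sum()
              for l in levels) / df
    t = (c @ means) / np.sqrt(msw * (c**2 / ns).sum())
    return t, 2 * st.t.sf(abs(t), df)


# ---------------------------------------------------------------------------


class TestOlsFit:
    def test_exact_linear_relation_recovered(self):
        x = np.arange(10.0)
        y = 3.0 + 2.0 * x
        table = ols_fit(y, pd.DataFrame({"x": x}))
        assert table["x"]["beta"] == pytest.approx(2.0, abs=1e-10)
        assert table["const"]["beta"] == pytest.approx(3.0, abs=1e-10)

    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(5.0, 1.0, size=30)
        table = ols_fit(y, pd.DataFrame(index=range(30)))
        assert table["const"]["beta"] == pytest.approx(y.mean())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        table = ols_fit(y, pd.DataFrame(X, columns=["a", "b", "c"]))
        beta, se, p = normal_equations(y, X)
        got = table.table.loc[["const", "a", "b", "c"]]
        np.testing.assert_allclose(got["beta"], beta, atol=1e-8)
        np.testing.assert_allclose(got["se"], se, atol=1e-8)
        np.testing.assert_allclose(got["p"], p, atol=1e-8)

    def test_ci_uses_t_quantile(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        table = ols_fit(y, pd.DataFrame(X, columns=["a", "b"]))
        tq = st.t.ppf(0.975, table.df_resid)
        row = table["a"]
        assert row["ci_high"] - row["beta"] == pytest.approx(tq * row["se"])

    def test_singular_design_names_collinear_term(self, rng):
        x = rng.normal(size=25)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValidationError) as err:
            ols_fit(rng.normal(size=25), X)
        assert "collinear" in str(err.value)

    def test_underdetermined_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 3)), columns=list("abc"))
        with pytest.raises(ValidationError):
            ols_fit(rng.normal(size=3), X)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_covariance_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 40))
        r, _ = pearson_r(x, y)
        expect = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_identical_values_give_zero_f(self):
        f, p = oneway_anova([[5.0, 5.0, 5.0], [5.0, 5.0], [5.0, 5.0, 5.0]])
        assert f == 0.0 and p == 1.0

    def test_two_groups_equal_t_squared(self, rng):
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0.5, 1, size=15)
        f, p_f = oneway_anova([a, b])
        t, p_t = st.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(m, 1, size=rng.integers(5, 15)) for m in (0, 0.3, 1.0)]
        f, p = oneway_anova(groups)
        f2, p2 = anova_by_sums_of_squares(groups)
        assert f == pytest.approx(f2, rel=1e-10)
        assert p == pytest.approx(p2, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            oneway_anova([[1.0, 2.0]])


class TestLinearityTest:
    def test_perfect_trend_small_p(self, rng):
        groups = {k: 10.0 * k + rng.normal(0, 0.01, size=6) for k in range(4)}
        t, p = linearity_test(groups)
        assert p < 1e-10 and t > 0

    def test_equal_means_null(self, rng):
        base = rng.normal(0, 1, size=8)
        groups = {k: base.copy() for k in range(4)}
        t, p = linearity_test(groups)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_contrast_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            k: rng.normal(-5.0 * k, 2.0, size=int(rng.integers(3, 9)))
            for k in range(4)
        }
        t, p = linearity_test(groups)
        t2, p2 = contrast_t(groups)
        assert t == pytest.approx(t2, rel=1e-10)
        assert p == pytest.approx(p2, rel=1e-10)

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            linearity_test({1: [1.0, 2.0]})


# ---------------------------------------------------------------------------
# subgroup selection


def _with_sample(rec, delay=1):
    rec.sample = UrineSample(
        hp_ug_per_L=0.2,
        below_lod=False,
        below_loq=False,
        creatinine_mg_per_dL=120.0,
        collection_date=rec.last_deployment_end + dt.timedelta(days=delay),
    )
    return rec


class TestSelectSubgroup:
    def test_empty_cohort(self):
        subset, att = select_subgroup([], SUBGROUP_RULES["WX"])
        assert subset == []
        assert (att["n_excluded"] == 0).all()

    def test_first_week_window_accepts_early_start(self):
        # deployed May 3 with the first-week window May 2-7: passes
        rec = _with_sample(
            make_record(deployments=[make_deployment(start=day(2), n_days=3)])
        )
        subset, _ = select_subgroup([rec], SUBGROUP_RULES["WX"])
        assert subset == [rec]
        late = _with_sample(
            make_record(deployments=[make_deployment(start=day(20), n_days=3)])
        )
        subset, _ = select_subgroup([late], SUBGROUP_RULES["WX"])
        assert subset == []

    def test_planted_attrition_counts(self):
        # one record failing exactly one criterion each, one passing all
        passing = _with_sample(
            make_record("ok", deployments=[make_deployment(start=day(2), n_days=3)])
        )
        multi = _with_sample(
            make_record(
                "multi",
                deployments=[
                    make_deployment(start=day(2), n_days=2),
                    make_deployment(start=day(10), n_days=2),
                ],
            )
        )
        short = _with_sample(
            make_record(
                "short",
                deployments=[make_deployment(start=day(2), n_days=1, hours=10.0)],
            )
        )
        logistic = _with_sample(
            make_record(
                "logistic",
                deployments=[make_deployment(start=day(2), n_days=3)],
                role_firefighter=False,
            )
        )
        smoker = _with_sample(
            make_record(
                "smoker",
                deployments=[make_deployment(start=day(2), n_days=3)],
                smoking=SmokingStatus.CURRENT,
            )
        )
        late_sample = _with_sample(
            make_record("late", deployments=[make_deployment(start=day(2), n_days=3)]),
            delay=20,
        )
        late_start = _with_sample(
            make_record(
                "late_start", deployments=[make_deployment(start=day(15), n_days=3)]
            )
        )
        cohort = [passing, multi, short, logistic, smoker, late_sample, late_start]
        subset, att = select_subgroup(cohort, SUBGROUP_RULES["WX"])
        assert [r.subject_id for r in subset] == ["ok"]
        att = att.set_index("criterion")
        assert att.loc["single_deployment", "n_excluded"] == 1
        assert att.loc["min_deployment_hours", "n_excluded"] == 1
        assert att.loc["firefighter_role", "n_excluded"] == 1
        assert att.loc["nonsmoker", "n_excluded"] == 1
        assert att.loc["max_delay", "n_excluded"] == 1
        assert att.loc["first_week_start", "n_excluded"] == 1
        # sequential bookkeeping: in = out + excluded at every step
        assert (att["n_in"] == att["n_out"] + att["n_excluded"]).all()
        assert att["n_out"].iloc[-1] == 1

    def test_contradictory_rule_rejected(self):
        with pytest.raises(ValidationError):
            SubgroupRule(name="bad", max_delay_days=-1)


# ---------------------------------------------------------------------------
# orchestration and parameter recovery


class TestRunAnalysis:
    def test_semi_effect_sign_recovered(self):
        """With dermal mitigation active in the generator, the fitted SEMI
        coefficient is negative (better hygiene, lower 1-HP)."""
        cfg = SimConfig(n_subjects=600, m_skin=0.8, seed=21)
        grid = generate_grid(cfg)
        cohort = generate_cohort(cfg, grid)
        report = run_analysis(cohort, grid, cfg)
        model = report.subgroup_models["single_deployment"]
        assert model is not None
        assert model["semi"]["beta"] < 0
        focused = fit_semi_model(cohort, grid, cfg)
        assert focused["semi"]["beta"] < 0
        assert focused["semi"]["p"] < 0.05

    def test_report_deterministic(self):
        cfg = SimConfig(n_subjects=80, seed=13)
        grid = generate_grid(cfg)
        cohort = generate_cohort(cfg, grid)
        r1 = run_analysis(cohort, grid, cfg).render()
        r2 = run_analysis(cohort, grid, cfg).render()
        assert r1 == r2

    def test_empty_subgroup_reported_not_crashed(self):
        deps = [
            [
                make_deployment(start=day(2), n_days=2),
                make_deployment(start=day(8), n_days=2),
            ]
            for _ in range(8)
        ]
        cohort = [
            _with_sample(make_record(f"m{i}", deployments=d))
            for i, d in enumerate(deps)
        ]
        report = run_analysis(cohort, constant_grid(), SimConfig())
        assert report.subgroup_models["WX"] is None
        assert any("WX" in m for m in report.messages)

    def test_coverage_of_semi_ci(self):
        """Parameter recovery: the 95% CI of the fitted SEMI term covers the
        generative target (the cohort-mean marginal SEMI effect on the
        creatinine-corrected scale) in at least 93% of replicates."""
        m = 0.8
        hits = 0
        reps = 200
        for rep in range(reps):
            cfg = SimConfig(n_subjects=1000, m_skin=m, seed=50_000 + rep)
            grid = generate_grid(cfg)
            cohort = generate_cohort(cfg, grid)
            model = fit_semi_model(cohort, grid, cfg)
            # generative target: mean over analyzed subjects of the exact
            # derivative dE[y]/dSEMI = -(m/3) w_skin E_i k_skin(t_i) * 1e5/creat_i
            targets = []
            for rec in cohort:
                s = rec.sample
                if not (30.0 <= s.creatinine_mg_per_dL <= 300.0):
                    continue
                ex = compute_exposure_summary(rec, grid, cfg)
                t = rec.collection_delay_days()
                k_skin = cfg.a_skin * 2 ** (-t / cfg.T_fast) + (
                    1 - cfg.a_skin
                ) * 2 ** (-t / cfg.T_slow)
                targets.append(
                    -(m / 3.0)
                    * cfg.w_skin
                    * ex.exposure_index
                    * k_skin
                    * 1e5
                    / s.creatinine_mg_per_dL
                )
            target = float(np.mean(targets))
            row = model["semi"]
            if row["ci_low"] <= target <= row["ci_high"]:
                hits += 1
        assert hits / reps >= 0.93
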