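"""Design construction, likelihood evaluation and mixed-model fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growthtraj import (
    ModelSpec,
    build_design,
    default_config,
    fit_lmm,
    fixed_effect_table,
    formula_string,
    load_model,
    loglikelihood,
    parse_formula,
    random_effect_table,
    reshape_wide_to_long,
    save_model,
    simulate_cohort,
)
from growthtraj.model_core import DesignError, Z975

from conftest import make_long, random_long, synthetic_model


# ---------------------------------------------------------------------------
# build_design


def test_design_polynomial_columns():
    rng = np.random.default_rng(0)
    ds = random_long(rng, n_subjects=6, max_obs=5)
    spec = ModelSpec(fixed_degree=3, random_degree=2, time_center=0.0)
    dm = build_design(ds, spec)
    assert dm.X.shape[1] == 4
    assert dm.term_names == ["(Intercept)", "t", "I(t^2)", "I(t^3)"]
    np.testing.assert_allclose(dm.X[:, 2], dm.X[:, 1] ** 2)
    np.testing.assert_allclose(dm.X[:, 3], dm.X[:, 1] ** 3)
    assert dm.Z.shape[1] == 3


def test_design_binary_interaction_degree4_has_10_columns():
    rng = np.random.default_rng(1)
    ds = random_long(rng, n_subjects=8, max_obs=6)
    ds.data["female"] = (ds.data["id"].to_numpy() % 2).astype(int)
    spec = ModelSpec(
        fixed_degree=4, random_degree=1,
        interaction=("female", "categorical"), time_center=0.0,
    )
    dm = build_design(ds, spec)
    # 5 intercept/polynomial + 1 main effect + 4 interaction terms
    assert dm.X.shape[1] == 10


def test_design_continuous_interaction_standardized():
    ds = make_long(
        [1, 1, 2, 2, 3, 3],
        [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        [1.0, 2.0, 2.0, 3.0, 3.0, 4.0],
        covariates={"x": [8.0, 8.0, 10.0, 10.0, 12.0, 12.0]},
    )
    spec = ModelSpec(fixed_degree=1, random_degree=0,
                     interaction=("x", "continuous"), time_center=0.0)
    dm = build_design(ds, spec)
    enc = dm.encoding_info["interaction"]
    assert enc["mean"] == 10.0
    # sample sd with n-1 over the modelled rows
    assert math.isclose(enc["sd"], np.std([8, 8, 10, 10, 12, 12], ddof=1))
    col = dm.X[:, dm.term_names.index("x")]
    assert math.isclose(col[-1], (12.0 - 10.0) / enc["sd"])


def test_design_drops_incomplete_rows_and_counts():
    ds = make_long(
        [1, 1, 2, 2, 3, 3],
        [0.0, 1.0, np.nan, 1.0, 0.0, 1.0],
        [1.0, np.nan, 2.0, 3.0, 3.0, 4.0],
    )
    dm = build_design(ds, ModelSpec(fixed_degree=1, random_degree=0))
    assert dm.n_obs == 4
    assert dm.n_dropped == 2


def test_design_single_level_categorical_errors():
    ds = make_long([1, 1, 2, 2], [0.0, 1.0, 0.0, 1.0], [1.0, 2.0, 2.0, 3.0],
                   covariates={"g": ["a", "a", "a", "a"]})
    spec = ModelSpec(fixed_degree=1, random_degree=0,
                     covariates=(("g", "categorical"),))
    with pytest.raises(DesignError, match="g"):
        build_design(ds, spec)


def test_design_collinear_columns_error():
    ds = make_long([1, 1, 2, 2, 3, 3], [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
                   [1.0, 2.0, 2.0, 3.0, 3.0, 4.0],
                   covariates={"dup": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]})
    spec = ModelSpec(fixed_degree=1, random_degree=0,
                     covariates=(("dup", "continuous"),), time_center=0.0)
    with pytest.raises(DesignError, match="collinear"):
        build_design(ds, spec)


def test_design_categorical_reference_is_lowest_numeric():
    ds = make_long([1, 1, 2, 2, 3, 3], [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
                   [1.0, 2.0, 2.0, 3.0, 3.0, 4.0],
                   covariates={"g": [10, 10, 2, 2, 5, 5]})
    spec = ModelSpec(fixed_degree=1, random_degree=0,
                     covariates=(("g", "categorical"),))
    dm = build_design(ds, spec)
    assert dm.encoding_info["covariates"]["g"]["reference"] == 2
    assert dm.encoding_info["covariates"]["g"]["levels"] == [2, 5, 10]


# ---------------------------------------------------------------------------
# loglikelihood


def _dense_loglik(dm, beta, G, sigma2):
    """Independent oracle: one stacked multivariate normal over all rows."""
    n = dm.n_obs
    Sigma = np.zeros((n, n))
    order = np.arange(n)
    for code in range(dm.n_subjects):
        pos = order[dm.subject_index == code]
        Zi = dm.Z[pos]
        Sigma[np.ix_(pos, pos)] = Zi @ G @ Zi.T
    Sigma[np.diag_indices(n)] += sigma2 / dm.w
    return stats.multivariate_normal.logpdf(dm.y, mean=dm.X @ beta, cov=Sigma)


def test_loglik_single_obs_standard_normal():
    # two subjects, one observation each, zero residuals, G = 0, sigma2 = 1:
    # each row contributes the standard-normal log-density at 0
    ds = make_long([1, 2], [0.0, 1.0], [0.0, 0.0])
    dm = build_design(ds, ModelSpec(fixed_degree=1, random_degree=0, time_center=0.0))
    ll = loglikelihood(dm, beta=np.zeros(2), G=np.zeros((1, 1)), sigma2=1.0)
    assert math.isclose(ll, 2 * (-0.5 * math.log(2 * math.pi)), rel_tol=1e-12)


def test_loglik_matches_dense_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        ds = random_long(rng, n_subjects=4, max_obs=4)
        spec = ModelSpec(fixed_degree=2, random_degree=1, time_center=0.0)
        dm = build_design(ds, spec)
        beta = rng.normal(size=3)
        A = rng.normal(size=(2, 2))
        G = A @ A.T + 0.1 * np.eye(2)
        sigma2 = float(rng.uniform(0.5, 2.0))
        ll = loglikelihood(dm, beta, G, sigma2)
        assert abs(ll - _dense_loglik(dm, beta, G, sigma2)) < 1e-10


def test_loglik_weight_scaling_identity():
    """Scaling all precision weights and sigma2 by the same factor leaves the
    residual covariance sigma2/w, and hence the likelihood, unchanged."""
    rng = np.random.default_rng(5)
    ds = random_long(rng, n_subjects=4, max_obs=4)
    ds.data["w"] = rng.uniform(0.5, 2.0, size=len(ds.data))
    spec = ModelSpec(fixed_degree=1, random_degree=1, weights_col="w",
                     time_center=0.0)
    dm = build_design(ds, spec)
    beta = np.array([0.5, 0.2])
    G = np.array([[0.3, 0.05], [0.05, 0.1]])
    ll1 = loglikelihood(dm, beta, G, 1.0)
    dm2 = build_design(ds, spec)
    dm2.w = 2 * dm.w
    ll2 = loglikelihood(dm2, beta, G, 2.0)
    assert math.isclose(ll1, ll2, rel_tol=1e-12)


def test_loglik_rejects_non_psd_G():
    rng = np.random.default_rng(6)
    ds = random_long(rng)
    dm = build_design(ds, ModelSpec(fixed_degree=1, random_degree=1, time_center=0.0))
    with pytest.raises(ValueError, match="semidefinite"):
        loglikelihood(dm, np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)


# ---------------------------------------------------------------------------
# fit_lmm


def test_fit_noise_free_linear_recovers_exactly():
    t = np.tile([0.0, 1.0, 2.0, 3.0], 5)
    s = np.repeat(np.arange(5), 4)
    y = 1.5 + 0.75 * t
    ds = make_long(s, t, y)
    spec = ModelSpec(fixed_degree=1, random_degree=0, time_center=0.0)
    with pytest.warns(RuntimeWarning, match="singular"):
        fm = fit_lmm(build_design(ds, spec), spec)
    np.testing.assert_allclose(fm.beta, [1.5, 0.75], atol=1e-6)
    assert fm.sigma2 < 1e-10
    assert fm.singular


def _balanced_anova_ml(y):
    """Closed-form ML for the balanced one-way random-intercept model,
    y: (m subjects, k obs)."""
    m, k = y.shape
    mu = y.mean()
    ybar = y.mean(axis=1)
    ssw = ((y - ybar[:, None]) ** 2).sum()
    ssb = k * ((ybar - mu) ** 2).sum()
    sigma2 = ssw / (m * (k - 1))
    tau = ssb / m  # = sigma2 + k * sigma_b2 at the ML optimum
    sigma_b2 = max((tau - sigma2) / k, 0.0)
    return mu, sigma_b2, sigma2


def make_intercept_only_design(y):
    """Intercept-only fixed part + random intercept for (m, k) outcomes."""
    from growthtraj.model_core import DesignMatrices

    m, k = y.shape
    spec = ModelSpec(fixed_degree=1, random_degree=0, time_center=0.0)
    return DesignMatrices(
        X=np.ones((m * k, 1)), Z=np.ones((m * k, 1)), y=y.ravel(),
        w=np.ones(m * k), time=np.zeros(m * k),
        subject_index=np.repeat(np.arange(m), k), subjects=np.arange(m),
        term_names=["(Intercept)"],
        encoding_info={"time_center": 0.0, "time_name": "t",
                       "time_range": [0.0, 0.0], "covariates": {},
                       "interaction": None, "interaction_name": None,
                       "outcome_name": "y", "subject_name": "id",
                       "n_dropped": 0},
        spec=spec,
    )


def test_fit_matches_balanced_anova_closed_form():
    rng = np.random.default_rng(21)
    m, k = 30, 4
    u = rng.normal(0, 1.0, size=m)
    y = 2.0 + u[:, None] + rng.normal(0, 0.7, size=(m, k))
    mu, sb2, s2 = _balanced_anova_ml(y)
    dm = make_intercept_only_design(y)
    fm = fit_lmm(dm, dm.spec)
    assert abs(fm.beta[0] - mu) < 1e-6
    assert abs(fm.G[0, 0] - sb2) < 1e-6
    assert abs(fm.sigma2 - s2) < 1e-6


def test_fit_weights_all_one_equals_no_weights(demo_fit):
    ds = demo_fit["ds"]
    ds2 = ds.subset(np.ones(len(ds.data), dtype=bool))
    ds2.data["w"] = 1.0
    spec = ModelSpec(fixed_degree=2, random_degree=1)
    specw = ModelSpec(fixed_degree=2, random_degree=1, weights_col="w")
    fm = fit_lmm(build_design(ds2, spec), spec)
    fmw = fit_lmm(build_design(ds2, specw), specw)
    assert abs(fm.deviance - fmw.deviance) < 1e-8
    np.testing.assert_allclose(fm.beta, fmw.beta, atol=1e-8)


def test_fit_deviance_non_increasing_in_degree():
    rng = np.random.default_rng(30)
    for rep in range(5):
        cfg = default_config(n_subjects=80)
        wide, _ = simulate_cohort(cfg, seed=100 + rep)
        ds = reshape_wide_to_long(wide, cfg.wide_spec())
        devs = []
        for D in (1, 2, 3):
            spec = ModelSpec(fixed_degree=D, random_degree=1, estimator="ML")
            devs.append(fit_lmm(build_design(ds, spec), spec).deviance)
        assert devs[0] >= devs[1] - 1e-4
        assert devs[1] >= devs[2] - 1e-4


def test_fit_V_is_inverse_information(demo_fit):
    """V equals the inverse GLS information at the fitted parameters."""
    fm, dm = demo_fit["fm"], demo_fit["dm"]
    p = fm.p
    Info = np.zeros((p, p))
    for code in range(dm.n_subjects):
        pos = np.flatnonzero(dm.subject_index == code)
        Zi = dm.Z[pos]
        Vi = Zi @ fm.G @ Zi.T + np.diag(fm.sigma2 / dm.w[pos])
        Xi = dm.X[pos]
        Info += Xi.T @ np.linalg.solve(Vi, Xi)
    Vhat = np.linalg.inv(Info)
    assert np.max(np.abs(fm.V - Vhat)) < 1e-8


def test_fit_reml_runs_and_differs_from_ml(demo_fit):
    ds = demo_fit["ds"]
    m = ModelSpec(fixed_degree=2, random_degree=1, estimator="ML")
    r = ModelSpec(fixed_degree=2, random_degree=1, estimator="REML")
    fm_ml = fit_lmm(build_design(ds, m), m)
    fm_reml = fit_lmm(build_design(ds, r), r)
    assert fm_reml.deviance != pytest.approx(fm_ml.deviance)
    # REML variance components are at least as large (bias correction)
    assert fm_reml.sigma2 > 0


def test_fit_crosschecks_statsmodels_mixedlm(demo_fit):
    """Independent fit of the same model with statsmodels MixedLM (ML)."""
    import statsmodels.formula.api as smf

    ds = demo_fit["ds"]
    spec = ModelSpec(fixed_degree=2, random_degree=1, time_center=0.0)
    dm = build_design(ds, spec)
    fm = fit_lmm(dm, spec)

    df = ds.data.dropna(subset=["age", "score"]).copy()
    df["age2"] = df["age"] ** 2
    md = smf.mixedlm("score ~ age + age2", df, groups=df["subject"],
                     re_formula="~age")
    res = md.fit(reml=False, method="lbfgs", maxiter=500)
    np.testing.assert_allclose(fm.beta, res.fe_params.to_numpy(), rtol=2e-4, atol=2e-4)
    assert abs(fm.loglik - res.llf) < 0.05


# ---------------------------------------------------------------------------
# summary tables


def test_fixed_effect_table_hand_example():
    fm = synthetic_model(beta=[2.0], V=[[1.0]])
    row = fixed_effect_table(fm).iloc[0]
    assert math.isclose(row["ci_low"], 2.0 - Z975, rel_tol=1e-9)
    assert math.isclose(row["ci_high"], 2.0 + Z975, rel_tol=1e-9)
    assert round(row["ci_low"], 3) == 0.040
    assert round(row["ci_high"], 3) == 3.960
    assert math.isclose(row["p"], 2 * stats.norm.sf(2.0), rel_tol=1e-9)


def test_fixed_effect_table_zero_se_missing_with_warning():
    fm = synthetic_model(beta=[2.0, 1.0], V=np.diag([0.0, 1.0]))
    with pytest.warns(RuntimeWarning, match="zero standard error"):
        tab = fixed_effect_table(fm)
    assert np.isnan(tab.loc[0, "z"]) and np.isnan(tab.loc[0, "p"])
    assert np.isfinite(tab.loc[1, "z"])


def test_fixed_effect_table_self_consistent(demo_fit):
    fm = demo_fit["fm"]
    tab = fixed_effect_table(fm)
    np.testing.assert_allclose(tab["estimate"], fm.beta)
    np.testing.assert_allclose(tab["se"], np.sqrt(np.diag(fm.V)))
    np.testing.assert_allclose(tab["ci_low"], fm.beta - Z975 * np.sqrt(np.diag(fm.V)))


def test_random_effect_table_hand_example():
    fm = synthetic_model(beta=[0.0, 0.0], V=np.eye(2),
                         G=[[4.0, 1.0], [1.0, 1.0]], sigma2=0.5)
    tab = random_effect_table(fm)
    assert tab.loc[0, "sd"] == 2.0
    assert tab.loc[1, "sd"] == 1.0
    pair = tab[tab["covariance_with"].notna()].iloc[0]
    assert pair["correlation"] == 0.5
    assert tab.iloc[-1]["variance"] == 0.5


def test_random_effect_table_correlation_identity(demo_fit):
    fm = demo_fit["fm"]
    tab = random_effect_table(fm)
    pairs = tab[tab["covariance_with"].notna()]
    labels = {r["term"]: i for i, r in tab.iterrows() if pd.notna(r["variance"])}
    for _, r in pairs.iterrows():
        i = ["intercept", "slope", "quadratic"].index(r["term"])
        j = ["intercept", "slope", "quadratic"].index(r["covariance_with"])
        expect = fm.G[i, j] / math.sqrt(fm.G[i, i] * fm.G[j, j])
        assert abs(r["correlation"] - expect) < 1e-12
        assert -1.0 <= r["correlation"] <= 1.0


# ---------------------------------------------------------------------------
# formula round trip


def test_formula_simple_template():
    spec = ModelSpec(fixed_degree=1, random_degree=0)
    assert formula_string(spec, "y", "t", "id") == "y ~ t + (1 | id)"


def test_formula_cubic_random_quadratic():
    spec = ModelSpec(fixed_degree=3, random_degree=2)
    assert (
        formula_string(spec, "sdq", "age", "subject")
        == "sdq ~ age + I(age^2) + I(age^3) + (1 + age + I(age^2) | subject)"
    )


def test_formula_interaction_terms():
    spec = ModelSpec(fixed_degree=2, random_degree=1,
                     interaction=("f", "continuous"))
    s = formula_string(spec, "y", "t", "id")
    assert "f + f:t + f:I(t^2)" in s


def test_formula_round_trips_through_parser():
    for spec in [
        ModelSpec(fixed_degree=1, random_degree=0),
        ModelSpec(fixed_degree=3, random_degree=2),
        ModelSpec(fixed_degree=2, random_degree=1,
                  covariates=(("ses", "continuous"),),
                  interaction=("f", "continuous")),
    ]:
        text = formula_string(spec, "sdq", "age", "subject")
        parsed, names = parse_formula(text)
        assert parsed.fixed_degree == spec.fixed_degree
        assert parsed.random_degree == spec.random_degree
        assert parsed.covariates == spec.covariates
        assert parsed.interaction == spec.interaction
        assert names == {"outcome": "sdq", "time": "age", "subject": "subject"}


# ---------------------------------------------------------------------------
# serialization


def test_model_serialization_round_trip(tmp_path, demo_fit):
    fm = demo_fit["fm"]
    path = tmp_path / "model.json"
    save_model(fm, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.beta, fm.beta)
    np.testing.assert_array_equal(back.V, fm.V)
    np.testing.assert_array_equal(back.G, fm.G)
    assert back.sigma2 == fm.sigma2
    assert back.loglik == fm.loglik
    assert back.spec == fm.spec
    assert back.term_names == fm.term_names
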