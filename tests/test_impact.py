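import numpy as np
import pytest

from campaignimpact.errors import ConfigurationError, NonEstimableError
from campaignimpact.impact import (ImpactModelConfig, StateSpaceFit,
                                   _filter_loglik, bonferroni_level,
                                   estimate_impact, fit_pre_period,
                                   predict_counterfactual, run_all_categories,
                                   summarize_effect)
from campaignimpact.lexicon import CategorySeries


def _series(values, category="Cat", group="target:all", db=None):
    values = np.asarray(values, dtype=float)
    db = db if db is not None else len(values) // 2
    return CategorySeries(category=category, group=group, days_before=db,
                          days_after=len(values) - db, values=values,
                          n_users=np.ones(len(values), dtype=int))


def test_perfect_covariate_limit():
    rng = np.random.default_rng(3)
    y = 0.1 + 0.01 * rng.standard_normal(60)
    fit = fit_pre_period(y, y)  # control equals target exactly
    pred = fit.level + fit.beta * y[-1]
    assert fit.beta == pytest.approx(1.0, abs=0.05)
    assert fit.sigma_level < 1e-4
    assert pred == pytest.approx(y[-1], abs=3 * fit.sigma_obs + 1e-6)


def test_degenerate_constant_covariate_still_fits():
    rng = np.random.default_rng(4)
    y = 0.2 + 0.02 * rng.standard_normal(40)
    x = np.full(40, 0.5)
    fit = fit_pre_period(y, x)
    assert np.isfinite([fit.sigma_obs, fit.sigma_level, fit.beta,
                        fit.level, fit.loglik]).all()
    assert fit.sigma_level < 0.5 * fit.sigma_obs  # noise goes to the obs term


def test_constant_zero_target_non_estimable():
    with pytest.raises(NonEstimableError):
        fit_pre_period(np.zeros(10), np.ones(10))


def test_short_series_rejected():
    with pytest.raises(ConfigurationError):
        fit_pre_period(np.ones(4), np.ones(4))


def test_parameter_recovery_long_series():
    """MLE consistency on simulated data at the long-series limit."""
    true = dict(s_obs=0.01, s_lvl=0.005, beta=0.8)
    ests = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        T = 200
        x = 0.1 + 0.02 * rng.standard_normal(T)
        mu = np.cumsum(true["s_lvl"] * rng.standard_normal(T))
        y = mu + true["beta"] * x + true["s_obs"] * rng.standard_normal(T)
        fit = fit_pre_period(y, x)
        ests.append((fit.sigma_obs, fit.sigma_level, fit.beta))
    mean = np.mean(ests, axis=0)
    assert mean[0] == pytest.approx(true["s_obs"], rel=0.25)
    assert mean[1] == pytest.approx(true["s_lvl"], rel=0.25)
    assert mean[2] == pytest.approx(true["beta"], rel=0.25)


def test_filter_matches_statsmodels_at_fixed_params():
    """The Kalman prediction-error likelihood agrees with an independent
    state-space implementation at the same parameter values."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    T = 80
    x = 0.3 + 0.05 * rng.standard_normal(T)
    y = np.cumsum(0.01 * rng.standard_normal(T)) + 0.7 * x \
        + 0.02 * rng.standard_normal(T)
    s2o, s2l, beta = 4e-4, 1e-4, 0.7
    mod = sm.tsa.UnobservedComponents(y, level="llevel", exog=x)
    mod.ssm.initialize_known(np.array([y[0] - beta * x[0]]), np.array([[1e7 * (s2o + s2l)]]))
    res = mod.filter([s2o, s2l, beta])
    ll_mine, a_mine, p_mine = _filter_loglik(y, x, s2o, s2l, beta)
    ll_sm = res.llf_obs[1:].sum()  # first obs initialises the diffuse state
    assert ll_mine == pytest.approx(ll_sm, rel=1e-6)
    assert a_mine == pytest.approx(res.filtered_state[0, -1], rel=1e-6)
    assert p_mine == pytest.approx(res.filtered_state_cov[0, 0, -1], rel=1e-4)


def test_noiseless_prediction_closed_form():
    fit = StateSpaceFit(sigma_obs=0.0, sigma_level=0.0, beta=2.0,
                        level=0.0, level_var=0.0, loglik=0.0)
    cfg = ImpactModelConfig(n_sim=200, seed=5)
    traj = predict_counterfactual(fit, [0.1, 0.2], cfg)
    assert traj.shape == (200, 2)
    assert np.allclose(traj, [0.2, 0.4])


def test_prediction_deterministic_for_seed():
    fit = StateSpaceFit(sigma_obs=0.05, sigma_level=0.01, beta=1.0,
                        level=0.3, level_var=0.001, loglik=0.0)
    cfg = ImpactModelConfig(n_sim=300, seed=9)
    t1 = predict_counterfactual(fit, np.linspace(0.1, 0.5, 10), cfg)
    t2 = predict_counterfactual(fit, np.linspace(0.1, 0.5, 10), cfg)
    assert np.array_equal(t1, t2)


def test_relative_effect_closed_form():
    fit = StateSpaceFit(sigma_obs=0.0, sigma_level=0.0, beta=1.0,
                        level=0.0, level_var=0.0, loglik=0.0)
    cfg = ImpactModelConfig(n_sim=100, seed=1)
    control_post = np.array([0.2, 0.2, 0.2, 0.2])
    traj = predict_counterfactual(fit, control_post, cfg)
    observed = 1.25 * control_post
    res = summarize_effect(observed, traj, cfg)
    assert res.relative_effect == pytest.approx(0.25)
    assert res.ci_low == pytest.approx(0.25)
    assert res.ci_high == pytest.approx(0.25)
    # conservation: last cumulative equals the sum of pointwise, exactly
    assert res.cumulative[-1] == pytest.approx(res.pointwise.sum(), abs=0.0)


def test_zero_effect_when_observed_equals_prediction():
    fit = StateSpaceFit(0.0, 0.0, 1.0, 0.0, 0.0, 0.0)
    cfg = ImpactModelConfig(n_sim=100, seed=1)
    control_post = np.array([0.3, 0.4])
    traj = predict_counterfactual(fit, control_post, cfg)
    res = summarize_effect(control_post.copy(), traj, cfg)
    assert res.relative_effect == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_empty_counterfactual_non_estimable():
    fit = StateSpaceFit(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    cfg = ImpactModelConfig(n_sim=100, seed=1)
    traj = predict_counterfactual(fit, np.zeros(3), cfg)
    with pytest.raises(NonEstimableError):
        summarize_effect(np.ones(3), traj, cfg)


def test_interval_brackets_point_estimate():
    rng = np.random.default_rng(0)
    target = _series(np.r_[0.1 + 0.01 * rng.standard_normal(15),
                           0.13 + 0.01 * rng.standard_normal(15)])
    control = _series(0.1 + 0.01 * rng.standard_normal(30), group="baseline:all")
    res = estimate_impact(target, control, ImpactModelConfig(seed=2))
    assert res.ci_low <= res.relative_effect <= res.ci_high
    assert 0.0 < res.p_value <= 1.0


def test_scale_equivariance():
    """Rescaling both series leaves relative effect and p-value unchanged."""
    rng = np.random.default_rng(8)
    y = np.r_[0.1 + 0.01 * rng.standard_normal(15),
              0.12 + 0.01 * rng.standard_normal(15)]
    x = 0.1 + 0.008 * rng.standard_normal(30)
    cfg = ImpactModelConfig(seed=3)
    r1 = estimate_impact(_series(y), _series(x, group="baseline:all"), cfg)
    c = 37.0
    r2 = estimate_impact(_series(c * y), _series(c * x, group="baseline:all"), cfg)
    assert r2.relative_effect == pytest.approx(r1.relative_effect, rel=1e-6, abs=1e-9)
    assert r2.p_value == pytest.approx(r1.p_value, abs=1e-12)


def test_bonferroni_levels():
    assert bonferroni_level(0.05, 51) == pytest.approx(0.05 / 51)
    assert bonferroni_level(0.05, 1) == 0.05
    with pytest.raises(ConfigurationError):
        bonferroni_level(0.05, 0)


def test_run_all_categories_flags_and_sorting():
    rng = np.random.default_rng(12)
    pairs = {}
    for i, cat in enumerate(["A", "B", "C"]):
        lift = 0.5 if cat == "B" else 0.0
        y = np.r_[0.1 + 0.005 * rng.standard_normal(15),
                  0.1 * (1 + lift) + 0.005 * rng.standard_normal(15)]
        x = 0.1 + 0.005 * rng.standard_normal(30)
        pairs[(cat, "all")] = (_series(y, category=cat),
                               _series(x, category=cat, group="baseline:all"))
    frame, results = run_all_categories(pairs, ImpactModelConfig(seed=4))
    assert list(frame["category"])[0] == "B"          # sorted by effect, lifted on top
    assert frame.loc[frame["category"] == "B", "tier"].item() == "bonferroni"
    assert (frame["relative_effect"].to_numpy()[:-1]
            >= frame["relative_effect"].to_numpy()[1:]).all()


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ImpactModelConfig(n_sim=10)
    with pytest.raises(ConfigurationError):
        ImpactModelConfig(interval_level=1.5)
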