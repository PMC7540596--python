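"""Estimator correctness: independent KKT/normal-equation oracles, limit
identities, constraint exactness, and trade-off monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fairreg as fr
from fairreg.estimators import (
    AverageConstrainedRegression,
    CovarianceConstrainedRegression,
    FittedModel,
    MRDPenalizedRegression,
    NetCompensationConstrainedRegression,
    NetCompensationPenalizedRegression,
    OLSRegression,
    WeightedAverageConstrainedRegression,
    make_estimator,
    netcomp_lambda_star,
    predict,
)

from conftest import random_instance


# ---------------------------------------------------------------------------
# Independent oracles (plain numpy; no use of the package's solver paths)
# ---------------------------------------------------------------------------

def with_intercept(X):
    return np.column_stack([np.ones(len(X)), X])


def oracle_ols(Z, y):
    return np.linalg.solve(Z.T @ Z, Z.T @ y)


def oracle_eq_constrained(Z, y, d, b):
    """Textbook KKT closed form for one linear equality constraint."""
    XtX_inv = np.linalg.inv(Z.T @ Z)
    theta = oracle_ols(Z, y)
    w = XtX_inv @ d
    return theta - w * (d @ theta - b) / (d @ w)


def oracle_netcomp_penalized(Z, y, a, lam):
    """Differentiate (1/N)[SSE + lam*sum_g residual] by hand."""
    u_g = Z[a == 1].mean(axis=0)
    return np.linalg.solve(Z.T @ Z, Z.T @ y + 0.5 * lam * a.sum() * u_g)


def oracle_mrd_penalized(Z, y, a, lam):
    """Augmented normal equations for the squared-MRD penalty."""
    v = Z[a == 1].mean(axis=0) - Z[a == 0].mean(axis=0)
    b = y[a == 1].mean() - y[a == 0].mean()
    return np.linalg.solve(Z.T @ Z + lam * np.outer(v, v), Z.T @ y + lam * b * v)


def group_mean_resid(Z, y, a, theta):
    g = a == 1
    return y[g].mean() - Z[g].mean(axis=0) @ theta


def resid_cov(Z, y, a, theta):
    r = y - Z @ theta
    return np.mean(a * r) - a.mean() * r.mean()


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def test_ols_matches_normal_equations_and_orthogonality():
    X, y, a = random_instance(1, n=50, p=4)
    est = OLSRegression().fit(X, y)
    Z = with_intercept(X)
    np.testing.assert_allclose(est.theta_, oracle_ols(Z, y), rtol=1e-8)
    np.testing.assert_allclose(Z.T @ (y - est.predict(X)), 0, atol=1e-7)


def test_ols_exact_fit_and_intercept_only():
    X, _, _ = random_instance(2, n=40, p=3)
    beta = np.array([0.5, 1.0, -2.0, 3.0])
    y = with_intercept(X) @ beta
    est = OLSRegression().fit(X, y)
    np.testing.assert_allclose(est.predict(X), y, atol=1e-8)
    assert fr.r_squared(y, est.predict(X)) == pytest.approx(100.0)
    # intercept-only design: the fitted coefficient is the outcome mean
    est0 = OLSRegression(fit_intercept=False).fit(np.ones((40, 1)), y)
    np.testing.assert_allclose(est0.predict(np.ones((40, 1))), y.mean())


def test_rank_deficient_design_is_refused_with_column_names():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 3))
    X[:, 2] = 2 * X[:, 0] - X[:, 1]
    import pandas as pd

    df = pd.DataFrame(X, columns=["u", "v", "w"])
    with pytest.raises(ValueError, match="rank-deficient"):
        OLSRegression().fit(df, rng.standard_normal(50))


# ---------------------------------------------------------------------------
# Constrained / penalized estimators vs oracles
# ---------------------------------------------------------------------------

def test_average_constrained_matches_kkt_oracle_and_zeroes_net_compensation():
    X, y, a = random_instance(3)
    est = AverageConstrainedRegression().fit(X, y, group=a)
    Z = with_intercept(X)
    d, b = Z[a == 1].mean(axis=0), y[a == 1].mean()
    np.testing.assert_allclose(est.theta_, oracle_eq_constrained(Z, y, d, b), rtol=1e-6)
    assert fr.net_compensation(y, est.predict(X), a) == pytest.approx(0.0, abs=1e-8)


def test_average_constrained_inactive_when_group_indicator_in_design():
    # group indicator as a regressor (with intercept): OLS already satisfies
    # the constraint, so the constrained fit equals OLS
    rng = np.random.default_rng(4)
    n = 120
    a = (rng.random(n) < 0.3).astype(int)
    X = np.column_stack([rng.standard_normal((n, 2)), a])
    y = X @ np.array([1.0, 2.0, 5.0]) + rng.standard_normal(n)
    t_ols = OLSRegression().fit(X, y).theta_
    t_avg = AverageConstrainedRegression().fit(X, y, group=a).theta_
    np.testing.assert_allclose(t_avg, t_ols, atol=1e-6 * max(1, np.abs(t_ols).max()))


@pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
def test_weighted_average_constrained_limits_and_oracle(alpha):
    X, y, a = random_instance(5)
    Z = with_intercept(X)
    est = WeightedAverageConstrainedRegression(alpha=alpha).fit(X, y, group=a)
    d = Z[a == 1].mean(axis=0)
    b = (1 - alpha) * y[a == 1].mean() + alpha * d @ oracle_ols(Z, y)
    np.testing.assert_allclose(est.theta_, oracle_eq_constrained(Z, y, d, b), rtol=1e-6)
    if alpha == 1.0:
        np.testing.assert_allclose(est.theta_, OLSRegression().fit(X, y).theta_,
                                   rtol=1e-6)
    if alpha == 0.0:
        np.testing.assert_allclose(
            est.theta_, AverageConstrainedRegression().fit(X, y, group=a).theta_,
            rtol=1e-6,
        )


def test_covariance_constrained_limits_binding_and_oracle():
    X, y, a = random_instance(6, group_effect=4.0)
    Z = with_intercept(X)
    t_ols = OLSRegression().fit(X, y).theta_
    c_star = resid_cov(Z, y, a, t_ols)
    assert c_star > 0  # construction: group undercompensated

    # m=1: OLS feasible, returned unchanged
    est1 = CovarianceConstrainedRegression(m=1.0).fit(X, y, group=a)
    np.testing.assert_allclose(est1.theta_, t_ols, rtol=1e-6)

    # binding case: equality at the boundary c = m c*, via the KKT oracle
    m = 0.4
    n = len(y)
    w = Z.T @ (a - a.mean()) / n
    cov_ay = (a - a.mean()) @ y / n
    t_oracle = oracle_eq_constrained(Z, y, w, cov_ay - m * c_star)
    # oracle case analysis: OLS if feasible, else boundary solution
    assert resid_cov(Z, y, a, t_ols) > m * c_star
    est = CovarianceConstrainedRegression(m=m).fit(X, y, group=a)
    np.testing.assert_allclose(est.theta_, t_oracle, rtol=1e-6)
    assert resid_cov(Z, y, a, est.theta_) == pytest.approx(m * c_star, rel=1e-6)

    # m=0 drives the covariance to (at most) zero
    est0 = CovarianceConstrainedRegression(m=0.0).fit(X, y, group=a)
    assert resid_cov(Z, y, a, est0.theta_) <= 1e-8 * np.std(y)


def test_covariance_constrained_requires_positive_c_star():
    rng = np.random.default_rng(8)
    n = 100
    a = (rng.random(n) < 0.4).astype(int)
    X = np.column_stack([rng.standard_normal((n, 2)), a])
    y = X @ np.array([1.0, 1.0, 2.0]) + rng.standard_normal(n)
    # group indicator in the design: OLS residual covariance is ~0
    with pytest.raises(ValueError, match="not undercompensated"):
        CovarianceConstrainedRegression(m=0.5).fit(X, y, group=a)


@pytest.mark.parametrize("lam", [0.0, 7.5, 10_000.0])
def test_netcomp_penalized_matches_closed_form_oracle(lam):
    X, y, a = random_instance(7)
    Z = with_intercept(X)
    est = NetCompensationPenalizedRegression(lam=lam).fit(X, y, group=a)
    np.testing.assert_allclose(est.theta_, oracle_netcomp_penalized(Z, y, a, lam),
                               rtol=1e-8, atol=1e-10)
    if lam == 0.0:
        np.testing.assert_allclose(est.theta_, OLSRegression().fit(X, y).theta_,
                                   rtol=1e-8)


def test_netcomp_penalized_group_residual_linear_in_lam_with_overshoot():
    X, y, a = random_instance(9, group_effect=4.0)
    Z = with_intercept(X)
    lam_star = netcomp_lambda_star(fr.RiskAdjustmentDataset(y=y, X=X, a=a))
    resids = []
    for t in (0.0, 0.5, 1.0, 1.5):
        est = NetCompensationPenalizedRegression(lam=t * lam_star).fit(X, y, group=a)
        resids.append(group_mean_resid(Z, y, a, est.theta_))
    # strictly decreasing, zero at lam*, negative beyond (overcompensation)
    assert np.all(np.diff(resids) < 0)
    assert resids[2] == pytest.approx(0.0, abs=1e-6 * np.std(y))
    assert resids[3] < 0


def test_netcomp_penalized_at_lambda_star_equals_average_constrained():
    """The penalized path passes exactly through the average-constrained
    solution when lam equals the net-compensation-zeroing weight."""
    X, y, a = random_instance(10)
    lam_star = netcomp_lambda_star(fr.RiskAdjustmentDataset(y=y, X=X, a=a))
    t_pen = NetCompensationPenalizedRegression(lam=lam_star).fit(X, y, group=a).theta_
    t_avg = AverageConstrainedRegression().fit(X, y, group=a).theta_
    np.testing.assert_allclose(t_pen, t_avg, rtol=1e-7, atol=1e-9)


@pytest.mark.parametrize("lam", [0.0, 123.0, 30_000.0])
def test_mrd_penalized_matches_augmented_normal_equations(lam):
    X, y, a = random_instance(12)
    Z = with_intercept(X)
    est = MRDPenalizedRegression(lam=lam).fit(X, y, group=a)
    np.testing.assert_allclose(est.theta_, oracle_mrd_penalized(Z, y, a, lam),
                               rtol=1e-7, atol=1e-9)


def test_mrd_penalized_dominating_penalty_zeroes_mrd():
    X, y, a = random_instance(13)
    est = MRDPenalizedRegression(lam=1e12).fit(X, y, group=a)
    assert fr.mean_residual_difference(y, est.predict(X), a) == pytest.approx(
        0.0, abs=1e-5 * np.std(y)
    )


def test_netcomp_constrained_inactive_binding_and_penalty_correspondence():
    X, y, a = random_instance(14, group_effect=4.0)
    Z = with_intercept(X)
    t_ols = OLSRegression().fit(X, y).theta_
    r0 = group_mean_resid(Z, y, a, t_ols)
    assert r0 > 0

    # slack bound: OLS returned
    est_slack = NetCompensationConstrainedRegression(z=2 * r0).fit(X, y, group=a)
    np.testing.assert_allclose(est_slack.theta_, t_ols, rtol=1e-6)

    # binding bound: group mean residual lands exactly on z
    z = 0.4 * r0
    est = NetCompensationConstrainedRegression(z=z).fit(X, y, group=a)
    assert group_mean_resid(Z, y, a, est.theta_) == pytest.approx(z, rel=1e-6)

    # one-to-one correspondence with the penalized form: solve the KKT
    # multiplier lam for this binding z and check the fits coincide
    u_g = Z[a == 1].mean(axis=0)
    k = u_g @ np.linalg.solve(Z.T @ Z / len(y), u_g)
    lam = 2 * (r0 - z) / (a.mean() * k)
    t_pen = NetCompensationPenalizedRegression(lam=lam).fit(X, y, group=a).theta_
    np.testing.assert_allclose(est.theta_, t_pen, rtol=1e-6)


def test_netcomp_penalized_fraction_scale():
    X, y, a = random_instance(15, group_effect=4.0)
    est = NetCompensationPenalizedRegression(lam=1.0, lam_scale="fraction").fit(
        X, y, group=a
    )
    t_avg = AverageConstrainedRegression().fit(X, y, group=a).theta_
    np.testing.assert_allclose(est.theta_, t_avg, rtol=1e-6)


# ---------------------------------------------------------------------------
# Cross-cutting properties
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_solver_and_closed_form_paths_agree(seed):
    """The scipy numeric path reproduces every closed-form/KKT solution."""
    X, y, a = random_instance(seed, group_effect=3.0)
    configs = [
        ("ols", {}),
        ("avg_constrained", {}),
        ("wavg_constrained", {"alpha": 0.3}),
        ("mrd_penalized", {"lam": 50.0}),
        ("netcomp_penalized", {"lam": 2.0}),
        ("netcomp_constrained", {"z": 0.5}),
        ("cov_constrained", {"m": 0.5}),
    ]
    for method, params in configs:
        closed = make_estimator(method, **params)
        numeric = make_estimator(method, solver="slsqp", **params)
        try:
            closed.fit(X, y, group=a)
        except ValueError:
            continue  # precondition (e.g. c* > 0) not met on this draw
        numeric.fit(X, y, group=a)
        scale = max(np.abs(closed.theta_).max(), 1.0)
        np.testing.assert_allclose(
            numeric.theta_, closed.theta_, rtol=2e-6, atol=2e-6 * scale,
            err_msg=method,
        )


def test_in_sample_sse_ordering(spending_fixture):
    """OLS minimizes the squared error; every fairness-aware fit can only
    match or increase it."""
    d = spending_fixture
    X, y, a = d.X, d.y, d.a
    sse = {}
    for method, params in [
        ("ols", {}), ("avg_constrained", {}),
        ("wavg_constrained", {"alpha": 0.4}),
        ("cov_constrained", {"m": 0.3}),
        ("mrd_penalized", {"lam": 1000.0}),
        ("netcomp_penalized", {"lam": 500.0}),
        ("netcomp_constrained", {"z": 1.0}),
    ]:
        est = make_estimator(method, **params).fit(X, y, group=a)
        r = y - est.predict(X)
        sse[method] = float(r @ r)
    assert all(sse["ols"] <= v * (1 + 1e-12) for v in sse.values())


def test_hyperparameter_continuity(spending_fixture):
    """Small hyperparameter perturbations move the coefficients little."""
    d = spending_fixture
    for make in (
        lambda h: WeightedAverageConstrainedRegression(alpha=h),
        lambda h: CovarianceConstrainedRegression(m=h),
    ):
        t1 = make(0.5).fit(d.X, d.y, group=d.a).theta_
        t2 = make(0.5 + 1e-4).fit(d.X, d.y, group=d.a).theta_
        assert np.abs(t1 - t2).max() <= 1e-2 * (np.abs(t1).max() + 1.0)
    lam0 = 500.0
    t1 = NetCompensationPenalizedRegression(lam=lam0).fit(d.X, d.y, group=d.a).theta_
    t2 = NetCompensationPenalizedRegression(lam=lam0 * 1.001).fit(
        d.X, d.y, group=d.a
    ).theta_
    assert np.abs(t1 - t2).max() <= 1e-2 * (np.abs(t1).max() + 1.0)


def test_parameter_validation_errors():
    X, y, a = random_instance(20)
    with pytest.raises(ValueError, match="alpha"):
        WeightedAverageConstrainedRegression(alpha=1.5).fit(X, y, group=a)
    with pytest.raises(ValueError, match="m must"):
        CovarianceConstrainedRegression(m=-0.1).fit(X, y, group=a)
    with pytest.raises(ValueError, match="lam"):
        MRDPenalizedRegression(lam=-1.0).fit(X, y, group=a)
    with pytest.raises(ValueError, match="lam"):
        NetCompensationPenalizedRegression(lam=-1.0).fit(X, y, group=a)
    with pytest.raises(ValueError, match="z must be positive"):
        NetCompensationConstrainedRegression(z=0.0).fit(X, y, group=a)
    with pytest.raises(ValueError, match="group"):
        AverageConstrainedRegression().fit(X, y)
    with pytest.raises(ValueError, match="unknown method"):
        make_estimator("ridge")


def test_fitted_model_roundtrip_and_predict(tmp_path):
    X, y, a = random_instance(21, n=80, p=3)
    fm = fr.fit_netcomp_penalized(fr.RiskAdjustmentDataset(y=y, X=X, a=a), lam=5.0)
    path = tmp_path / "model.json"
    fm.to_json(path)
    back = FittedModel.from_json(path)
    np.testing.assert_allclose(back.theta, fm.theta)
    assert back.method == "netcomp_penalized"
    assert back.hyperparameter == {"lam": 5.0}
    np.testing.assert_allclose(predict(back, X), predict(fm, X))
    with pytest.raises(ValueError, match="columns"):
        predict(back, X[:, :2])


def test_sklearn_get_set_params_clone():
    from sklearn.base import clone

    est = CovarianceConstrainedRegression(m=0.3, two_sided=True)
    params = est.get_params()
    assert params["m"] == 0.3 and params["two_sided"] is True
    est2 = clone(est).set_params(m=0.7)
    assert est2.m == 0.7
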