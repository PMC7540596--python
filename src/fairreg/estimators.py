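"""Fair least-squares estimators for risk adjustment.

Six linear estimators of spending share one squared-error core and differ in
how a group-fairness requirement enters:

==============================================  =======================================
Estimator                                       Fairness mechanism
==============================================  =======================================
:class:`OLSRegression`                          none (baseline)
:class:`AverageConstrainedRegression`           equality: group mean prediction equals
                                                group mean spending (net compensation
                                                for g forced to zero in-sample)
:class:`WeightedAverageConstrainedRegression`   equality: group mean prediction equals
                                                an alpha-mixture of group mean spending
                                                and the group's OLS mean prediction
:class:`CovarianceConstrainedRegression`        inequality: Cov(A, residual) <= m * c*,
                                                c* the OLS residual covariance
:class:`MRDPenalizedRegression`                 penalty: lam * (mean residual
                                                difference)^2 added to the SSE
:class:`NetCompensationPenalizedRegression`     penalty: lam * group-g mean residual
                                                added to the mean squared error
:class:`NetCompensationConstrainedRegression`   inequality: group-g mean residual <= z
==============================================  =======================================

All are scikit-learn compatible regressors: ``fit(X, y, group=a)``,
``predict(X)``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore. Every optimization problem is a convex quadratic with at
most one linear constraint, so the default solution path is the exact
closed-form / KKT solution (``solver="closed_form"``); ``solver="slsqp"``
solves the same program numerically through scipy and falls back to the
closed form (with ``solver_status_ = "solver_inaccurate"``) if the numeric
path misses the constraint by more than 1e-6 standard deviations of the
outcome.

Residual orientation: the penalties and constraints below act on the
*shortfall* residual ``y - Xθ`` (observed minus predicted), as does the fair
covariance; the reported net-compensation metric is its negative. See
:mod:`fairreg.metrics`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from . import _qp
from .data import RiskAdjustmentDataset, validate_group_indicator
from ._qp import (
    STATUS_CLOSED_FORM,
    STATUS_SOLVER_OPTIMAL,
    STATUS_SOLVER_INACCURATE,
)

__all__ = [
    "OLSRegression",
    "AverageConstrainedRegression",
    "WeightedAverageConstrainedRegression",
    "CovarianceConstrainedRegression",
    "MRDPenalizedRegression",
    "NetCompensationPenalizedRegression",
    "NetCompensationConstrainedRegression",
    "FittedModel",
    "fit_ols",
    "fit_average_constrained",
    "fit_weighted_average_constrained",
    "fit_covariance_constrained",
    "fit_mrd_penalized",
    "fit_netcomp_penalized",
    "fit_netcomp_constrained",
    "predict",
    "netcomp_lambda_star",
    "make_estimator",
    "METHODS",
]

INTERCEPT_NAME = "intercept"


class _BaseFairRegressor(RegressorMixin, BaseEstimator):
    """Shared fitting skeleton: validation, intercept handling, solve, predict."""

    method: str = ""
    requires_group: bool = True

    def __init__(self, fit_intercept=True, solver="closed_form"):
        self.fit_intercept = fit_intercept
        self.solver = solver

    # -- subclass hooks ---------------------------------------------------
    def _check_params(self):
        pass

    def _solve_closed_form(self, Z, y, a):
        raise NotImplementedError

    def _solve_slsqp(self, Z, y, a, theta0):
        """Return (theta, converged) from the numeric path."""
        raise NotImplementedError

    def _constraint_residual(self, Z, y, a, theta) -> float:
        """Violation of the estimator's constraint at theta (0 if none)."""
        return 0.0

    # ---------------------------------------------------------------------
    def _design(self, X):
        if self.fit_intercept:
            return np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y, group=None):
        if self.solver not in ("closed_form", "slsqp"):
            raise ValueError(
                f"solver must be 'closed_form' or 'slsqp', got {self.solver!r}"
            )
        self._check_params()
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns])
        X = check_array(X, dtype=float)
        y = column_or_1d(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if group is None:
            if self.requires_group:
                raise ValueError(
                    f"{type(self).__name__} requires the protected-group "
                    "indicator: fit(X, y, group=a)"
                )
            a = None
        else:
            a = validate_group_indicator(group, y.shape[0])
        self.n_features_in_ = X.shape[1]
        names = getattr(
            self, "feature_names_in_", [f"x{j}" for j in range(X.shape[1])]
        )
        cols = ([INTERCEPT_NAME] if self.fit_intercept else []) + list(names)
        Z = self._design(X)
        _qp.check_full_rank(Z, cols)

        theta = self._solve_closed_form(Z, y, a)
        status = STATUS_CLOSED_FORM
        if self.solver == "slsqp":
            cand, converged = self._solve_slsqp(Z, y, a, theta0=theta)
            tol = 1e-6 * max(float(np.std(y)), 1.0)
            if converged and self._constraint_residual(Z, y, a, cand) < tol:
                theta, status = cand, STATUS_SOLVER_OPTIMAL
            else:
                status = STATUS_SOLVER_INACCURATE  # closed form retained

        self.theta_ = theta
        self.columns_ = cols
        if self.fit_intercept:
            self.intercept_ = float(theta[0])
            self.coef_ = theta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = theta.copy()
        self.solver_status_ = status
        r = y - Z @ theta
        self.objective_value_ = float(r @ r) + self._penalty_value(Z, y, a, theta)
        self.constraint_residual_ = self._constraint_residual(Z, y, a, theta)
        return self

    def _penalty_value(self, Z, y, a, theta) -> float:
        return 0.0

    def predict(self, X):
        check_is_fitted(self, "theta_")
        if hasattr(X, "columns"):
            got = [str(c) for c in X.columns]
            want = list(getattr(self, "feature_names_in_", got))
            if got != want:
                raise ValueError(
                    f"feature-name mismatch: expected columns {want}, got {got}"
                )
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects "
                f"{self.n_features_in_} ({self.columns_})"
            )
        return self._design(X) @ self.theta_

    def _hyperparameter(self) -> dict | None:
        return None

    def to_fitted_model(self) -> "FittedModel":
        check_is_fitted(self, "theta_")
        return FittedModel(
            method=self.method,
            theta=np.asarray(self.theta_, dtype=float),
            columns=list(self.columns_),
            hyperparameter=self._hyperparameter(),
            solver_status=self.solver_status_,
            objective_value=self.objective_value_,
        )

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def _group_stats(Z, y, a):
    g = a == 1
    u_g = Z[g].mean(axis=0)
    ybar_g = float(y[g].mean())
    return g, u_g, ybar_g


class OLSRegression(_BaseFairRegressor):
    """Ordinary least squares, the current risk-adjustment baseline.

    The ``group`` argument is accepted and ignored so that OLS composes with
    the same evaluation harness as the fairness-aware estimators.
    """

    method = "ols"
    requires_group = False

    def _solve_closed_form(self, Z, y, a):
        return _qp.ols(Z, y)

    def _solve_slsqp(self, Z, y, a, theta0):
        return _qp.slsqp_quadratic(Z, y, x0=theta0)


class AverageConstrainedRegression(_BaseFairRegressor):
    """Least squares with the group mean prediction pinned to the group mean
    outcome, so the in-sample net compensation for g is exactly zero."""

    method = "avg_constrained"

    def _constraint_terms(self, Z, y, a):
        _, u_g, ybar_g = _group_stats(Z, y, a)
        return u_g, ybar_g

    def _solve_closed_form(self, Z, y, a):
        d, b = self._constraint_terms(Z, y, a)
        return _qp.equality_constrained_ls(Z, y, d, b)

    def _solve_slsqp(self, Z, y, a, theta0):
        d, b = self._constraint_terms(Z, y, a)
        return _qp.slsqp_quadratic(Z, y, eq=(d, b), x0=theta0)

    def _constraint_residual(self, Z, y, a, theta):
        d, b = self._constraint_terms(Z, y, a)
        return abs(float(d @ theta) - b)


class WeightedAverageConstrainedRegression(AverageConstrainedRegression):
    """Group mean prediction pinned to an alpha-weighted compromise between
    the group's observed mean (alpha=0, average-constrained) and its OLS
    mean prediction (alpha=1, plain OLS)."""

    method = "wavg_constrained"

    def __init__(self, alpha=0.5, fit_intercept=True, solver="closed_form"):
        super().__init__(fit_intercept=fit_intercept, solver=solver)
        self.alpha = alpha

    def _check_params(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")

    def _constraint_terms(self, Z, y, a):
        _, u_g, ybar_g = _group_stats(Z, y, a)
        theta_ols = _qp.ols(Z, y)
        b = (1.0 - self.alpha) * ybar_g + self.alpha * float(u_g @ theta_ols)
        return u_g, b

    def _hyperparameter(self):
        return {"alpha": self.alpha}


class CovarianceConstrainedRegression(_BaseFairRegressor):
    """Least squares with the covariance between the protected-group
    indicator and the shortfall residual bounded above by ``m * c_star``.

    ``c_star`` is the residual covariance of the OLS fit on the same
    training data; it must be positive (group g undercompensated under OLS)
    for the one-sided bound to be meaningful. The covariance is computed
    with the population divisor N, the same scale as the fair-covariance
    metric. ``two_sided=True`` additionally imposes the lower bound
    ``>= -m * c_star``; with a positive bound the upper side is the one
    that binds, so the default one-sided form gives the same optimum.
    """

    method = "cov_constrained"

    def __init__(self, m=0.5, two_sided=False, fit_intercept=True, solver="closed_form"):
        super().__init__(fit_intercept=fit_intercept, solver=solver)
        self.m = m
        self.two_sided = two_sided

    def _check_params(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must lie in [0, 1], got {self.m}")

    def _cov_terms(self, Z, y, a):
        n = Z.shape[0]
        p_bar = a.mean()
        centered = a - p_bar
        w = Z.T @ centered / n            # Cov(A, Z theta) = w . theta
        cov_ay = float(centered @ y) / n  # Cov(A, Y)
        theta_ols = _qp.ols(Z, y)
        c_star = cov_ay - float(w @ theta_ols)
        return w, cov_ay, c_star, theta_ols

    def _solve_closed_form(self, Z, y, a):
        w, cov_ay, c_star, theta_ols = self._cov_terms(Z, y, a)
        if c_star <= 0:
            raise ValueError(
                "OLS residual covariance c* is non-positive "
                f"({c_star:.6g}): group g is not undercompensated under OLS "
                "on this data, so the one-sided covariance constraint is not "
                "meaningful"
            )
        self.c_star_ = c_star
        c = self.m * c_star
        if c_star <= c:  # m = 1: OLS already feasible
            return theta_ols
        # Bind the upper side: Cov(A, Y - Z theta) = c.
        return _qp.equality_constrained_ls(Z, y, w, cov_ay - c)

    def _solve_slsqp(self, Z, y, a, theta0):
        w, cov_ay, c_star, _ = self._cov_terms(Z, y, a)
        c = self.m * c_star
        # Cov <= c  <=>  -w . theta <= c - cov_ay
        ineq = [(-w, c - cov_ay)]
        if self.two_sided:
            ineq.append((w, cov_ay + c))  # Cov >= -c
        return _qp.slsqp_quadratic(Z, y, ineq_le=ineq, x0=theta0)

    def _constraint_residual(self, Z, y, a, theta):
        w, cov_ay, c_star, _ = self._cov_terms(Z, y, a)
        cov = cov_ay - float(w @ theta)
        viol = max(cov - self.m * c_star, 0.0)
        if self.two_sided:
            viol = max(viol, -(cov + self.m * c_star), 0.0)
        return viol

    def _hyperparameter(self):
        return {"m": self.m}


class MRDPenalizedRegression(_BaseFairRegressor):
    """Squared-error objective plus ``lam`` times the squared mean residual
    difference between g and its complement.

    Objective: sum_k (y_k - x_k.theta)^2 + lam * MRD(theta)^2 where
    MRD(theta) = mean_g(y - x.theta) - mean_gc(y - x.theta). The penalty is
    a rank-one PSD quadratic, so the minimizer solves the augmented normal
    equations (X'X + lam v v') theta = X'y + lam b v with v the difference
    of group mean design rows and b the difference of group mean outcomes.
    """

    method = "mrd_penalized"

    def __init__(self, lam=0.0, fit_intercept=True, solver="closed_form"):
        super().__init__(fit_intercept=fit_intercept, solver=solver)
        self.lam = lam

    def _check_params(self):
        if self.lam < 0:
            raise ValueError(f"lam must be non-negative, got {self.lam}")

    def _mrd_terms(self, Z, y, a):
        g = a == 1
        v = Z[g].mean(axis=0) - Z[~g].mean(axis=0)
        b = float(y[g].mean() - y[~g].mean())
        return v, b

    def _solve_closed_form(self, Z, y, a):
        v, b = self._mrd_terms(Z, y, a)
        XtX = Z.T @ Z + self.lam * np.outer(v, v)
        rhs = Z.T @ y + self.lam * b * v
        return _qp.solve_normal_equations(XtX, rhs)

    def _solve_slsqp(self, Z, y, a, theta0):
        v, b = self._mrd_terms(Z, y, a)
        return _qp.slsqp_quadratic(
            Z, y, quad_rank1=(v, b, self.lam), x0=theta0
        )

    def _penalty_value(self, Z, y, a, theta):
        v, b = self._mrd_terms(Z, y, a)
        return self.lam * (b - float(v @ theta)) ** 2

    def _hyperparameter(self):
        return {"lam": self.lam}


class NetCompensationPenalizedRegression(_BaseFairRegressor):
    """Squared-error objective plus a linear penalty on the group-g total
    shortfall residual, both normalized by the sample size.

    Objective: (1/N) [ sum_k (y_k - x_k.theta)^2
                       + lam * sum_{i in g} (y_i - x_i.theta) ].
    Penalizing the group *total* (rather than mean) residual alongside the
    per-person squared error keeps ``lam`` on the outcome (dollar) scale
    and makes the penalty's pull proportional to the group's size: the
    closed form is theta = (X'X)^{-1} (X'y + (lam*n_g/2) u_g) with u_g the
    group mean design row, and the lam that exactly zeroes the in-sample
    group mean residual is ``netcomp_lambda_star``, independent of N.
    Because the penalty is linear, lam beyond that point pushes group g
    into overcompensation rather than saturating.

    With ``lam_scale="fraction"``, ``lam`` is interpreted as a fraction of
    the training data's lambda-star (computed from the training fold only),
    which makes hyperparameter grids portable across outcome scales.
    """

    method = "netcomp_penalized"

    def __init__(self, lam=0.0, lam_scale="absolute", fit_intercept=True,
                 solver="closed_form"):
        super().__init__(fit_intercept=fit_intercept, solver=solver)
        self.lam = lam
        self.lam_scale = lam_scale

    def _check_params(self):
        if self.lam < 0:
            raise ValueError(f"lam must be non-negative, got {self.lam}")
        if self.lam_scale not in ("absolute", "fraction"):
            raise ValueError(
                f"lam_scale must be 'absolute' or 'fraction', got {self.lam_scale!r}"
            )

    def _effective_lam(self, Z, y, a) -> float:
        if self.lam_scale == "absolute":
            return float(self.lam)
        lam_star = _lambda_star(Z, y, a)
        return float(self.lam) * lam_star

    def _solve_closed_form(self, Z, y, a):
        lam = self._effective_lam(Z, y, a)
        self.effective_lam_ = lam
        _, u_g, _ = _group_stats(Z, y, a)
        XtX = Z.T @ Z
        rhs = Z.T @ y + 0.5 * lam * a.sum() * u_g
        return _qp.solve_normal_equations(XtX, rhs)

    def _solve_slsqp(self, Z, y, a, theta0):
        lam = self._effective_lam(Z, y, a)
        _, u_g, _ = _group_stats(Z, y, a)
        # penalty lam * sum_g(y - Z theta) = const - lam*n_g*u_g.theta on
        # the sum-of-squares scale used by the numeric backend
        return _qp.slsqp_quadratic(
            Z, y, linear_term=-lam * a.sum() * u_g, x0=theta0
        )

    def _penalty_value(self, Z, y, a, theta):
        lam = getattr(self, "effective_lam_", self.lam)
        _, u_g, ybar_g = _group_stats(Z, y, a)
        # on the same (sum) scale as the recorded SSE term
        return lam * a.sum() * (ybar_g - float(u_g @ theta))

    def _hyperparameter(self):
        h = {"lam": self.lam}
        if self.lam_scale != "absolute":
            h["lam_scale"] = self.lam_scale
            if hasattr(self, "effective_lam_"):
                h["effective_lam"] = self.effective_lam_
        return h


class NetCompensationConstrainedRegression(_BaseFairRegressor):
    """Least squares subject to the group-g mean shortfall residual being at
    most ``z`` (dollars). Equivalent, when binding, to the penalized form at
    a matched lam; when OLS already satisfies the bound it returns OLS."""

    method = "netcomp_constrained"

    def __init__(self, z=1.0, fit_intercept=True, solver="closed_form"):
        super().__init__(fit_intercept=fit_intercept, solver=solver)
        self.z = z

    def _check_params(self):
        if not self.z > 0:
            raise ValueError(f"z must be positive, got {self.z}")

    def _solve_closed_form(self, Z, y, a):
        _, u_g, ybar_g = _group_stats(Z, y, a)
        theta_ols = _qp.ols(Z, y)
        if ybar_g - float(u_g @ theta_ols) <= self.z:
            return theta_ols
        # Bind: mean_g(y - Z theta) = z  <=>  u_g.theta = ybar_g - z
        return _qp.equality_constrained_ls(Z, y, u_g, ybar_g - self.z)

    def _solve_slsqp(self, Z, y, a, theta0):
        _, u_g, ybar_g = _group_stats(Z, y, a)
        # mean_g residual <= z  <=>  -u_g.theta <= z - ybar_g
        return _qp.slsqp_quadratic(
            Z, y, ineq_le=[(-u_g, self.z - ybar_g)], x0=theta0
        )

    def _constraint_residual(self, Z, y, a, theta):
        _, u_g, ybar_g = _group_stats(Z, y, a)
        return max(ybar_g - float(u_g @ theta) - self.z, 0.0)

    def _hyperparameter(self):
        return {"z": self.z}


def _lambda_star(Z, y, a) -> float:
    """The penalty weight at which the net-compensation penalized fit has
    exactly zero in-sample group-g mean residual (equals the
    average-constrained solution)."""
    _, u_g, ybar_g = _group_stats(Z, y, a)
    theta_ols = _qp.ols(Z, y)
    resid_g = ybar_g - float(u_g @ theta_ols)
    if resid_g <= 0:
        raise ValueError(
            "group g is not undercompensated under OLS on this data "
            f"(group mean residual {resid_g:.6g}); lambda-star is undefined"
        )
    S = Z.T @ Z / Z.shape[0]
    k = float(u_g @ _qp.solve_normal_equations(S, u_g))
    p_g = a.mean()
    return 2.0 * resid_g / (p_g * k)


def netcomp_lambda_star(data: RiskAdjustmentDataset, fit_intercept=True) -> float:
    """Dollar-scale lambda zeroing the in-sample net compensation for g."""
    Z = np.column_stack([np.ones(data.n), data.X]) if fit_intercept else data.X
    return _lambda_star(Z, data.y, data.a)


# ---------------------------------------------------------------------------
# FittedModel plumbing and functional wrappers
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted coefficient vector with provenance."""

    method: str
    theta: np.ndarray
    columns: list[str]
    hyperparameter: dict | None = None
    solver_status: str = STATUS_CLOSED_FORM
    objective_value: float | None = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape[0] != len(self.columns):
            raise ValueError("theta length does not match number of columns")

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["theta"] = self.theta.tolist()
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "FittedModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(**d)


def predict(model: FittedModel, X) -> np.ndarray:
    """Predict spending: Yhat = X theta (an intercept column is added when
    the model was fit with one)."""
    X = np.asarray(X, dtype=float)
    has_intercept = model.columns and model.columns[0] == INTERCEPT_NAME
    expected = len(model.columns) - (1 if has_intercept else 0)
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(
            f"X must have {expected} columns "
            f"({[c for c in model.columns if c != INTERCEPT_NAME]})"
        )
    Z = np.column_stack([np.ones(X.shape[0]), X]) if has_intercept else X
    return Z @ model.theta


_ESTIMATORS = {
    "ols": OLSRegression,
    "avg_constrained": AverageConstrainedRegression,
    "wavg_constrained": WeightedAverageConstrainedRegression,
    "cov_constrained": CovarianceConstrainedRegression,
    "mrd_penalized": MRDPenalizedRegression,
    "netcomp_penalized": NetCompensationPenalizedRegression,
    "netcomp_constrained": NetCompensationConstrainedRegression,
}

METHODS = tuple(_ESTIMATORS)


def make_estimator(method: str, **params) -> _BaseFairRegressor:
    """Build an estimator by method name (the names used in reports/CLI)."""
    try:
        cls = _ESTIMATORS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(METHODS)}"
        ) from None
    return cls(**params)


def _fit(method, data: RiskAdjustmentDataset, **params) -> FittedModel:
    import pandas as pd

    est = make_estimator(method, **params)
    X_df = pd.DataFrame(data.X, columns=data.columns)
    est.fit(X_df, data.y, group=data.a)
    return est.to_fitted_model()


def fit_ols(data, **kw) -> FittedModel:
    """Ordinary least squares on a RiskAdjustmentDataset."""
    return _fit("ols", data, **kw)


def fit_average_constrained(data, **kw) -> FittedModel:
    """Least squares with in-sample net compensation for g forced to zero."""
    return _fit("avg_constrained", data, **kw)


def fit_weighted_average_constrained(data, alpha, **kw) -> FittedModel:
    """Weighted average constrained regression with weight ``alpha``."""
    return _fit("wavg_constrained", data, alpha=alpha, **kw)


def fit_covariance_constrained(data, m, **kw) -> FittedModel:
    """Covariance constrained regression with bound ``m * c_star``."""
    return _fit("cov_constrained", data, m=m, **kw)


def fit_mrd_penalized(data, lam, **kw) -> FittedModel:
    """Mean-residual-difference penalized regression with weight ``lam``."""
    return _fit("mrd_penalized", data, lam=lam, **kw)


def fit_netcomp_penalized(data, lam, **kw) -> FittedModel:
    """Net-compensation penalized regression with weight ``lam``."""
    return _fit("netcomp_penalized", data, lam=lam, **kw)


def fit_netcomp_constrained(data, z, **kw) -> FittedModel:
    """Net-compensation constrained regression with bound ``z``."""
    return _fit("netcomp_constrained", data, z=z, **kw)
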