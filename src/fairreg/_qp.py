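"""Internal solution paths for the constrained / penalized least-squares fits.

Every estimator in this package minimizes a convex quadratic in the
coefficient vector, optionally subject to a single linear equality or
inequality, so each has an exact closed-form (KKT) solution. That closed form
is the default solution path. An independent numeric path solves the same
program with scipy's SLSQP in QR-whitened coordinates; it exists so the two
routes can be cross-checked and as a fallback surface for non-quadratic
extensions.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

STATUS_CLOSED_FORM = "closed_form"
STATUS_SOLVER_OPTIMAL = "solver_optimal"
STATUS_SOLVER_INACCURATE = "solver_inaccurate"


def check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    """Refuse rank-deficient designs, naming the offending columns.

    Risk-adjustment coefficients are policy-interpreted, so a non-unique
    solution is an error rather than a silent pseudo-inverse.
    """
    n, p = X.shape
    if n < p:
        raise ValueError(f"design has more columns ({p}) than rows ({n})")
    # Column-pivoted QR: trailing pivots with negligible |R_jj| are the
    # columns that lie (numerically) in the span of earlier ones.
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = [columns[piv[j]] for j in range(p) if diag[j] <= tol]
    if bad:
        raise ValueError(
            "design matrix is rank-deficient; linearly dependent columns: "
            + ", ".join(map(str, bad))
        )


def ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares solution via QR (design already checked full rank)."""
    theta, *_ = linalg.lstsq(X, y, lapack_driver="gelsd")
    return theta


def solve_normal_equations(XtX: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    c, low = linalg.cho_factor(XtX)
    return linalg.cho_solve((c, low), rhs)


def equality_constrained_ls(
    X: np.ndarray, y: np.ndarray, d: np.ndarray, b: float
) -> np.ndarray:
    """Minimize ||y - X theta||^2 subject to d^T theta = b (single constraint).

    KKT solution: theta = theta_OLS - (X'X)^{-1} d [d'(X'X)^{-1} d]^{-1}
    (d' theta_OLS - b).
    """
    if not np.any(d):
        raise ValueError(
            "constraint direction is the zero vector; the equality "
            "constraint is infeasible or vacuous"
        )
    XtX = X.T @ X
    theta_ols = ols(X, y)
    c, low = linalg.cho_factor(XtX)
    w = linalg.cho_solve((c, low), d)  # (X'X)^{-1} d
    gap = float(d @ theta_ols - b)
    return theta_ols - w * (gap / float(d @ w))


def _whiten(X: np.ndarray):
    """Economic QR of X; returns (Q, R). Optimization runs over phi = R theta,
    where the quadratic term is the well-conditioned ||Q phi - y||^2."""
    Q, R = linalg.qr(X, mode="economic")
    return Q, R


def slsqp_quadratic(
    X: np.ndarray,
    y: np.ndarray,
    linear_term: np.ndarray | None = None,
    quad_rank1: tuple[np.ndarray, float, float] | None = None,
    eq: tuple[np.ndarray, float] | None = None,
    ineq_le: list[tuple[np.ndarray, float]] | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Numerically minimize a (possibly augmented) least-squares objective.

    Objective: ||y - X theta||^2 / s  +  linear_term . theta / s
               + w * (v . theta - t)^2 / s      (rank-1 quadratic penalty)
    with s = sum(y^2) a pure scale factor, subject to optional
    eq: d . theta = b and ineq_le: each (d, b) meaning d . theta <= b.

    Returns (theta, converged).
    """
    n, p = X.shape
    Q, R = _whiten(X)
    Qty = Q.T @ y
    yty = float(y @ y)
    s = yty if yty > 0 else 1.0
    Rinv = linalg.solve_triangular(R, np.eye(p))

    lin_phi = Rinv.T @ linear_term if linear_term is not None else None
    if quad_rank1 is not None:
        v, t, w = quad_rank1
        v_phi = Rinv.T @ v

    def fun(phi):
        r = phi - Qty
        val = float(r @ r) + yty - float(Qty @ Qty)
        grad = 2.0 * r
        if lin_phi is not None:
            val += float(lin_phi @ phi)
            grad = grad + lin_phi
        if quad_rank1 is not None:
            e = float(v_phi @ phi) - t
            val += w * e * e
            grad = grad + 2.0 * w * e * v_phi
        return val / s, grad / s

    constraints = []
    scale = max(np.sqrt(yty / n), 1.0)
    if eq is not None:
        d, b = eq
        d_phi = Rinv.T @ d
        constraints.append(
            {
                "type": "eq",
                "fun": lambda phi, d_phi=d_phi, b=b: (float(d_phi @ phi) - b) / scale,
                "jac": lambda phi, d_phi=d_phi: d_phi / scale,
            }
        )
    for d, b in ineq_le or []:
        d_phi = Rinv.T @ d
        constraints.append(
            {
                # SLSQP convention: fun >= 0, so encode d.theta <= b
                "type": "ineq",
                "fun": lambda phi, d_phi=d_phi, b=b: (b - float(d_phi @ phi)) / scale,
                "jac": lambda phi, d_phi=d_phi: -d_phi / scale,
            }
        )

    phi0 = R @ x0 if x0 is not None else Qty.copy()
    res = optimize.minimize(
        fun,
        phi0,
        jac=True,
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    theta = linalg.solve_triangular(R, res.x)
    return theta, bool(res.success)
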