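"""Group-fairness and global-fit metrics for risk-adjustment predictions.

All metrics are functions of an observed outcome vector ``y``, a prediction
vector ``y_hat``, and a binary protected-group indicator ``a`` (1 = member of
group g, the potentially undercompensated group; its complement is gc).

Sign conventions
----------------
Two residual orientations coexist in the risk-adjustment literature and both
are kept here exactly:

* Net compensation and the mean residual difference average the *payment*
  residual ``y_hat - y``: a negative value means the group is paid less than
  it costs (undercompensation).
* The fair covariance uses the *shortfall* residual ``y - y_hat`` (see
  :func:`residuals`): a positive covariance with ``a`` means group g's costs
  systematically exceed its predictions — again undercompensation.

The covariance uses the population divisor N (not N-1), matching the 1/N
approximation used when the same quantity appears as an estimator constraint,
so metric and constraint are on an identical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .data import validate_group_indicator

__all__ = [
    "residuals",
    "net_compensation",
    "mean_residual_difference",
    "predictive_ratio",
    "fair_covariance",
    "scaled_fair_covariance",
    "r_squared",
    "compute_report",
    "FairnessReport",
    "REPORT_COLUMNS",
]

#: Fixed serialization column order for metric tables.
REPORT_COLUMNS = [
    "R2",
    "PR_g",
    "PR_gc",
    "NC_g",
    "NC_gc",
    "MRD",
    "FairCov",
    "ScaledFairCov",
]


def _validate(y, y_hat, a):
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.ndim != 1 or y_hat.ndim != 1:
        raise ValueError("y and y_hat must be one-dimensional")
    if y.shape[0] != y_hat.shape[0]:
        raise ValueError(
            f"length mismatch: y has {y.shape[0]} entries, y_hat has {y_hat.shape[0]}"
        )
    if y.shape[0] < 2:
        raise ValueError("need at least two observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_hat))):
        raise ValueError("y/y_hat contain non-finite values")
    a = validate_group_indicator(a, y.shape[0])
    return y, y_hat, a


def residuals(y, y_hat) -> np.ndarray:
    """Shortfall residual ``y - y_hat`` (observed minus predicted).

    Positive values mean spending exceeded the prediction. This is the
    orientation used by the fair covariance and by the estimator penalties;
    net compensation uses its negative.
    """
    return np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)


def _group_mask(a: np.ndarray, which_group: str) -> np.ndarray:
    if which_group == "g":
        return a == 1
    if which_group == "gc":
        return a == 0
    raise ValueError(f"which_group must be 'g' or 'gc', got {which_group!r}")


def net_compensation(y, y_hat, a, which_group: str = "g") -> float:
    """Mean of (predicted - observed) spending over the requested group.

    Negative values indicate the group is undercompensated: on average the
    formula pays less than the group's observed spending.
    """
    y, y_hat, a = _validate(y, y_hat, a)
    mask = _group_mask(a, which_group)
    if not mask.any():
        raise ValueError(f"requested group {which_group!r} is empty")
    return float(np.mean(y_hat[mask] - y[mask]))


def mean_residual_difference(y, y_hat, a) -> float:
    """Net compensation of g minus net compensation of gc.

    Zero indicates parity in mean payment residuals between the two groups.
    """
    return net_compensation(y, y_hat, a, "g") - net_compensation(y, y_hat, a, "gc")


def predictive_ratio(y, y_hat, a, which_group: str = "g") -> float:
    """Group sum of predictions over group sum of observations.

    1 means exact group-level compensation; below 1, undercompensation.
    """
    y, y_hat, a = _validate(y, y_hat, a)
    mask = _group_mask(a, which_group)
    if not mask.any():
        raise ValueError(f"requested group {which_group!r} is empty")
    denom = float(np.sum(y[mask]))
    if denom == 0.0:
        raise ZeroDivisionError(
            f"observed spending sums to zero in group {which_group!r}; "
            "predictive ratio is undefined"
        )
    return float(np.sum(y_hat[mask])) / denom


def fair_covariance(y, y_hat, a) -> float:
    """Empirical covariance Cov(A, Y - Yhat) with population divisor N.

    Positive values mean group g's shortfall residuals run systematically
    high — the empirical signal of undercompensation. For binary A this
    equals ``P(1-P) * (mean residual in g - mean residual in gc)`` with
    P the in-sample group proportion.
    """
    y, y_hat, a = _validate(y, y_hat, a)
    r = residuals(y, y_hat)
    a_f = a.astype(float)
    # validate_group_indicator guarantees a is non-constant
    return float(np.mean(a_f * r) - np.mean(a_f) * np.mean(r))


def scaled_fair_covariance(y, y_hat, a, c_star: float) -> float:
    """Fair covariance scaled by a reference covariance ``c_star``.

    ``c_star`` is conventionally the fair covariance of the OLS fit on the
    same data; the scaled measure is then 1 for OLS itself, falls toward 0
    as fairness improves, and goes negative if the evaluated model
    overshoots into overcompensating group g.
    """
    if c_star == 0.0:
        raise ZeroDivisionError(
            "c_star is zero: the reference model is already exactly fair and "
            "the scaled fair covariance is undefined"
        )
    return fair_covariance(y, y_hat, a) / c_star


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SSE/SST, returned as a percent.

    SST is taken around the overall mean of ``y``. Out-of-sample predictions
    can yield negative values.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch between y and y_hat")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ZeroDivisionError("y has zero variance; R^2 is undefined")
    sse = float(np.sum((y - y_hat) ** 2))
    return 100.0 * (1.0 - sse / sst)


@dataclass
class FairnessReport:
    """The five-measure suite for one prediction vector.

    Currency-valued fields (net compensations, mean residual difference,
    fair covariance) are kept at full precision; rounding to whole dollars
    happens only at presentation time.
    """

    r2: float
    net_compensation_g: float
    net_compensation_gc: float
    predictive_ratio_g: float
    predictive_ratio_gc: float
    mean_residual_difference: float
    fair_covariance: float
    scaled_fair_covariance: float | None = None
    c_star: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_row(self) -> dict:
        """Fixed-name column mapping used for CSV/JSON tables."""
        return {
            "R2": self.r2,
            "PR_g": self.predictive_ratio_g,
            "PR_gc": self.predictive_ratio_gc,
            "NC_g": self.net_compensation_g,
            "NC_gc": self.net_compensation_gc,
            "MRD": self.mean_residual_difference,
            "FairCov": self.fair_covariance,
            "ScaledFairCov": self.scaled_fair_covariance,
        }


def compute_report(y, y_hat, a, c_star: float | None = None) -> FairnessReport:
    """Assemble the full metric suite for one prediction vector.

    ``scaled_fair_covariance`` is populated only when a reference ``c_star``
    is supplied (typically the OLS fair covariance on the same data).
    """
    nc_g = net_compensation(y, y_hat, a, "g")
    nc_gc = net_compensation(y, y_hat, a, "gc")
    fc = fair_covariance(y, y_hat, a)
    return FairnessReport(
        r2=r_squared(y, y_hat),
        net_compensation_g=nc_g,
        net_compensation_gc=nc_gc,
        predictive_ratio_g=predictive_ratio(y, y_hat, a, "g"),
        predictive_ratio_gc=predictive_ratio(y, y_hat, a, "gc"),
        mean_residual_difference=nc_g - nc_gc,
        fair_covariance=fc,
        scaled_fair_covariance=(
            scaled_fair_covariance(y, y_hat, a, c_star) if c_star is not None else None
        ),
        c_star=c_star,
    )
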