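"""Fivefold cross-validated evaluation of estimator/hyperparameter grids.

For every configuration the dataset is split into k folds, each fold's
predictions come from a model fit on the other folds, the held-out
predictions are pooled into one vector covering every person exactly once,
and the full fairness-metric suite is computed on that pooled vector. OLS is
always evaluated as the reference configuration; its pooled residual
covariance with the group indicator supplies the c* used to scale the fair
covariance of every other configuration.

Folds are stratified on the protected-group indicator by default, which
guarantees both groups are present in every training split (a requirement
for the group-constrained estimators).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .data import RiskAdjustmentDataset
from .estimators import FittedModel, make_estimator
from .metrics import FairnessReport, compute_report, fair_covariance

__all__ = [
    "CVPlan",
    "CVResult",
    "make_folds",
    "cross_validate",
    "frontier_table",
    "select_configuration",
    "config_label",
    "default_grid",
]


Configuration = tuple[str, dict]


def config_label(method: str, params: dict | None) -> str:
    """Stable human-readable name for a (method, hyperparameters) pair."""
    params = {
        k: v for k, v in (params or {}).items()
        if k not in ("fit_intercept", "solver")
    }
    if not params:
        return method
    inner = ",".join(f"{k}={params[k]:g}" if isinstance(params[k], float)
                     else f"{k}={params[k]}" for k in sorted(params))
    return f"{method}({inner})"


@dataclass
class CVPlan:
    """Evaluation recipe: folds, seed, and the estimator grid."""

    configurations: list[Configuration]
    n_folds: int = 5
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not self.configurations:
            raise ValueError("configuration grid is empty")


@dataclass
class CVResult:
    """Pooled held-out predictions and fairness reports per configuration."""

    labels: list[str]
    reports: dict[str, FairnessReport]
    predictions: dict[str, np.ndarray]
    models: dict[str, list[FittedModel]]
    fold_assignment: np.ndarray
    c_star_reference: float
    plan: CVPlan | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Summary layout: one row per configuration, sorted on net
        compensation for g (descending, fairest first)."""
        rows = []
        for label in self.labels:
            row = {"method": label}
            row.update(self.reports[label].to_row())
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values("NC_g", ascending=False, kind="mergesort").reset_index(
            drop=True
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        d = {
            "c_star_reference": self.c_star_reference,
            "configurations": {
                label: self.reports[label].to_dict() for label in self.labels
            },
        }
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def make_folds(n: int, k: int, seed: int, stratify_by=None) -> np.ndarray:
    """Deterministic balanced fold assignment: one fold id in [0, k) per person.

    Fold sizes differ by at most one. When ``stratify_by`` is given, the
    partition is additionally balanced within each of its classes.
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} observations")
    if stratify_by is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), np.asarray(stratify_by))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    assignment = np.full(n, -1, dtype=int)
    for fold_id, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = fold_id
    return assignment


def cross_validate(
    data: RiskAdjustmentDataset, plan: CVPlan, on_error: str = "raise"
) -> CVResult:
    """Run the full CV protocol for every configuration in the plan.

    OLS is prepended to the grid if absent: it is the reference that defines
    c*. All configurations share one fold assignment, so their pooled
    metrics are directly comparable. With ``on_error="skip"``, a
    configuration whose preconditions fail on some training fold (e.g. the
    covariance constraint when the group is not undercompensated there) is
    dropped with a warning instead of aborting the whole run.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    configs: list[Configuration] = list(plan.configurations)
    if not any(m == "ols" for m, _ in configs):
        configs = [("ols", {})] + configs

    assignment = make_folds(
        data.n, plan.n_folds, plan.seed,
        stratify_by=data.a if plan.stratify else None,
    )
    for fold in range(plan.n_folds):
        train_a = data.a[assignment != fold]
        if train_a.sum() == 0 or train_a.sum() == train_a.size:
            raise ValueError(
                f"training split for fold {fold} contains only one group; "
                "use stratified folds (stratify=True)"
            )

    X_df = pd.DataFrame(data.X, columns=data.columns)
    labels, predictions, models = [], {}, {}
    for method, params in configs:
        label = config_label(method, params)
        if label in predictions:  # duplicate configuration: identical result
            continue
        pooled = np.full(data.n, np.nan)
        fold_models = []
        try:
            for fold in range(plan.n_folds):
                train = assignment != fold
                test = ~train
                est = make_estimator(method, **params)
                est.fit(X_df[train], data.y[train], group=data.a[train])
                pooled[test] = est.predict(X_df[test])
                fold_models.append(est.to_fitted_model())
        except ValueError:
            if on_error == "skip" and method != "ols":
                warnings.warn(f"skipping configuration {label}: preconditions "
                              "failed on a training fold", stacklevel=2)
                continue
            raise
        assert not np.isnan(pooled).any(), "pooled predictions must cover everyone"
        labels.append(label)
        predictions[label] = pooled
        models[label] = fold_models

    c_star = fair_covariance(data.y, predictions["ols"], data.a)
    reports = {
        label: compute_report(
            data.y, predictions[label], data.a,
            c_star=c_star if c_star != 0.0 else None,
        )
        for label in labels
    }
    return CVResult(
        labels=labels,
        reports=reports,
        predictions=predictions,
        models=models,
        fold_assignment=assignment,
        c_star_reference=c_star,
        plan=plan,
    )


def frontier_table(result: CVResult) -> pd.DataFrame:
    """(configuration, R2, PR_g) table for fit-vs-fairness frontier plots,
    sorted on net compensation for g like the main table."""
    df = result.to_frame()
    return df[["method", "R2", "PR_g", "NC_g"]].copy()


def select_configuration(
    result: CVResult, max_relative_r2_loss: float = 0.10
) -> str:
    """Pick the configuration maximizing the group predictive ratio subject
    to a relative cross-validated R-squared loss below the ceiling
    (default 10%). Returns its label."""
    r2_ols = result.reports["ols"].r2
    best, best_pr = "ols", result.reports["ols"].predictive_ratio_g
    for label in result.labels:
        rep = result.reports[label]
        if r2_ols > 0 and (r2_ols - rep.r2) / r2_ols > max_relative_r2_loss:
            continue
        if rep.predictive_ratio_g > best_pr:
            best, best_pr = label, rep.predictive_ratio_g
    return best


def default_grid(n: int) -> list[Configuration]:
    """The hyperparameter grid used in the spending application: four values
    each of m and alpha, and lambda values proportional to the sample size
    (the lambda = N/10 guideline)."""
    lams = [n / 100, n / 10, n / 5, 3 * n / 10]
    grid: list[Configuration] = [("ols", {}), ("avg_constrained", {})]
    grid += [("cov_constrained", {"m": m}) for m in (0.2, 0.4, 0.6, 0.8)]
    grid += [("wavg_constrained", {"alpha": a}) for a in (0.2, 0.4, 0.6, 0.8)]
    grid += [("netcomp_penalized", {"lam": l}) for l in lams]
    grid += [("mrd_penalized", {"lam": l}) for l in lams]
    return grid
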