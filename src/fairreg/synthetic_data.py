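"""Synthetic claims-like data and simulation scenarios.

Two generators make every estimator and metric testable without access to
proprietary claims data:

* :func:`generate_spending_population` emulates a private-insurance claims
  sample: ~100 000 enrollees with sex, age, 62 binary condition indicators,
  a protected group of ~13.8% prevalence with roughly doubled mean spending,
  and a heavily right-skewed annual spending outcome. Spending follows a
  two-part model (Bernoulli any-spending x lognormal positive spending) whose
  per-group location and shape parameters are solved numerically so the
  group-wise mean and median match the calibration targets in conditional
  expectation. A ``group_signal_leakage`` knob controls how much of the
  group's spending shift flows through the observable condition indicators:
  at leakage 1 the indicators carry the whole group mean shift, at 0 the
  shift is entirely a latent group effect that a regression on the
  indicators cannot see - which is what makes OLS undercompensate the group.

* :func:`generate_simulation_population` builds a population with covariates
  X1..X9, a complex (Y1) or simpler (Y2) continuous outcome, and two
  distinct, partially overlapping protected classes A1 and A2 derived from
  the covariates. Scenario 1 pairs the complex outcome with estimators that
  omit a key covariate; scenario 2 pairs the simpler outcome with estimators
  given extra pure-noise covariates and nothing omitted.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import RiskAdjustmentDataset
from .cross_validation import CVPlan, config_label, cross_validate

__all__ = [
    "SpendingGeneratorConfig",
    "generate_spending_population",
    "save_population",
    "ScenarioConfig",
    "generate_simulation_population",
    "draw_replicates",
    "draw_replicate",
    "run_scenario",
    "ScenarioResult",
    "simulation_default_grid",
]


# ---------------------------------------------------------------------------
# Claims-like spending population
# ---------------------------------------------------------------------------

#: Calibration moments of the emulated sample (currency units).
DEFAULT_TARGET_MOMENTS = {
    "overall_mean": 6651.0,
    "overall_median": 1511.0,
    "group_mean": 11520.0,
    "complement_mean": 5880.0,
    "group_median": 3744.0,
    "complement_median": 1274.0,
}


@dataclass
class SpendingGeneratorConfig:
    """Recipe for the claims-like spending population.

    Defaults reproduce the emulated sample: 52% female, ages 21-63 with
    median 45, 62 condition indicators whose prevalences are log-spaced so
    the rarest has >= 30 carriers at n=100 000, a 13.8%-prevalence protected
    group, and the calibration moments in ``DEFAULT_TARGET_MOMENTS``.

    ``p_any_spending`` is the probability of nonzero annual spending (the
    first part of the two-part model); ``group_signal_leakage`` in [0, 1]
    sets the fraction of the group's log-mean spending shift mediated by the
    condition indicators.
    """

    n: int = 100_000
    seed: int = 0
    p_female: float = 0.52
    age_range: tuple[int, int] = (21, 63)
    n_conditions: int = 62
    condition_prevalences: np.ndarray | None = None
    p_group: float = 0.138
    target_moments: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_MOMENTS))
    group_signal_leakage: float = 0.5
    n_group_linked_conditions: int = 3
    p_any_spending: float = 0.88

    def __post_init__(self):
        for name in ("p_female", "p_group", "p_any_spending"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 <= self.group_signal_leakage <= 1.0:
            raise ValueError("group_signal_leakage must be in [0, 1]")
        t = self.target_moments
        if any(v <= 0 for v in t.values()):
            raise ValueError("target moments must be positive")
        if t["group_mean"] <= t["complement_mean"]:
            raise ValueError(
                "infeasible targets: group mean spending must exceed the "
                "complement's"
            )
        for grp in ("group", "complement"):
            if t[f"{grp}_mean"] <= t[f"{grp}_median"]:
                raise ValueError(
                    f"infeasible targets: {grp} mean must exceed its median "
                    "(right-skewed spending)"
                )
        if self.condition_prevalences is None:
            # log-spaced; the floor keeps >=50 expected carriers per condition
            # at any n (at the default n=100 000 it is 5e-4, i.e. 50 carriers
            # - the analogue of retaining only conditions with >=30 enrollees),
            # capped at 2% so tiny fixtures keep a realistic prevalence spread
            floor = max(5e-4, min(50.0 / self.n, 0.02))
            self.condition_prevalences = np.geomspace(floor, 0.15, self.n_conditions)
        else:
            self.condition_prevalences = np.asarray(
                self.condition_prevalences, dtype=float
            )
            if self.condition_prevalences.shape != (self.n_conditions,):
                raise ValueError("condition_prevalences length != n_conditions")
            if np.any(
                (self.condition_prevalences <= 0) | (self.condition_prevalences >= 1)
            ):
                raise ValueError("condition prevalences must be in (0, 1)")


def _condition_effects(prev: np.ndarray) -> np.ndarray:
    """Log-spending effect per condition: rarer conditions are costlier.

    Linear in log-prevalence from 0.9 (rarest) down to 0.15 (commonest).
    """
    lo, hi = np.log(prev.min()), np.log(prev.max())
    t = (np.log(prev) - lo) / (hi - lo) if hi > lo else np.zeros_like(prev)
    return 0.9 - 0.75 * t


#: Log-cost effect assigned to the group-linked marker conditions: moderate
#: cost, so the group signal they carry comes mostly from their elevated
#: within-group prevalence (sharp identification) rather than their price.
LINKED_CONDITION_EFFECT = 0.4


def _linked_condition_indices(prev: np.ndarray, k: int) -> np.ndarray:
    """Pick ``k`` group-linked conditions from the 0.5%-3% base-prevalence
    range: the analogue of the handful of diagnosis categories that
    identify a clinical group like MHSUD (rare outside the group, common
    within it once boosted)."""
    lo = int(np.searchsorted(prev, 0.005))
    hi = max(int(np.searchsorted(prev, 0.03)), lo + 1)
    hi = min(hi, prev.size - 1)
    return np.unique(np.linspace(lo, hi, k).round().astype(int))


def _boosted_prevalence(
    prev: np.ndarray, gamma: float, linked: np.ndarray
) -> np.ndarray:
    """Odds-scale prevalence boost applied to the linked conditions only,
    so the group's observable signal is concentrated rather than diffuse."""
    out = prev.copy()
    odds = prev[linked] / (1 - prev[linked]) * np.exp(gamma)
    out[linked] = odds / (1 + odds)
    return out


def _solve_condition_boost(
    prev: np.ndarray, beta: np.ndarray, linked: np.ndarray, target_ratio: float
) -> float:
    """Solve the odds boost gamma so the linked condition indicators
    multiply the group's expected exp(log-effect) by ``target_ratio``
    (independence approximation: E[exp(H beta)] factorizes across
    conditions)."""
    if target_ratio <= 1.0:
        return 0.0
    base = 1 - prev[linked] + prev[linked] * np.exp(beta[linked])

    def log_ratio(gamma):
        pg = _boosted_prevalence(prev, gamma, linked)[linked]
        return float(np.sum(np.log((1 - pg + pg * np.exp(beta[linked])) / base)))

    target = np.log(target_ratio)
    hi = 1.0
    while log_ratio(hi) < target:
        hi *= 2.0
        if hi > 64:
            raise ValueError("cannot reach the requested group mean ratio")
    return optimize.brentq(lambda g: log_ratio(g) - target, 0.0, hi, xtol=1e-10)


def _calibrate_lognormal(
    eta: np.ndarray, pi: float, mean_target: float, median_target: float
) -> tuple[float, float]:
    """Solve (c, sigma) of the two-part lognormal so the group's expected
    sample mean and population median hit their targets, conditional on the
    realized covariate log-effects ``eta``.

    Mean: pi * exp(sigma^2/2) * mean(exp(c + eta)) = mean_target gives c in
    closed form for any sigma; sigma is then found by a root solve on the
    mixture-CDF median equation
    (1 - pi) + pi * mean_i Phi((log m - c - eta_i)/sigma) = 1/2.
    """
    if pi <= 0.5:
        raise ValueError(
            "p_any_spending must exceed 0.5 for a positive median"
        )
    log_mean_exp_eta = float(np.log(np.mean(np.exp(eta))))
    log_m = np.log(median_target)

    def c_of(sigma):
        return np.log(mean_target / pi) - 0.5 * sigma**2 - log_mean_exp_eta

    def median_gap(sigma):
        z = (log_m - c_of(sigma) - eta) / sigma
        return (1 - pi) + pi * float(np.mean(stats.norm.cdf(z))) - 0.5

    lo, hi = 0.05, 6.0
    f_lo, f_hi = median_gap(lo), median_gap(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            "cannot calibrate spending distribution to the requested "
            "mean/median pair (targets too close or too far apart)"
        )
    sigma = optimize.brentq(median_gap, lo, hi, xtol=1e-12)
    return float(c_of(sigma)), float(sigma)


def generate_spending_population(
    config: SpendingGeneratorConfig | None = None, **overrides
) -> RiskAdjustmentDataset:
    """Generate the claims-like spending population.

    Returns a :class:`RiskAdjustmentDataset` whose design columns are
    ``female``, ``age`` and the condition indicators ``H001..H0NN`` - the
    protected-group indicator is deliberately *not* a design column, which
    is what allows a fitted formula to undercompensate the group.
    """
    if config is None:
        config = SpendingGeneratorConfig(**overrides)
    elif overrides:
        config = SpendingGeneratorConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)
    n = config.n
    t = config.target_moments

    female = (rng.random(n) < config.p_female).astype(float)
    lo_age, hi_age = config.age_range
    # Beta-shaped ages: right-of-center mode so the median lands at 45
    age = np.floor(lo_age + (hi_age + 1 - lo_age) * rng.beta(2.29, 1.8, size=n))
    age = np.clip(age, lo_age, hi_age)
    group = (rng.random(n) < config.p_group).astype(int)
    if group.sum() == 0 or group.sum() == n:
        raise ValueError("degenerate draw: one of the groups is empty")

    prev = config.condition_prevalences
    beta = _condition_effects(prev)
    # Leakage: conditions carry ratio^leakage of the group/complement mean
    # ratio; the per-group calibration constant absorbs the remainder.
    ratio = t["group_mean"] / t["complement_mean"]
    linked = _linked_condition_indices(prev, config.n_group_linked_conditions)
    beta[linked] = LINKED_CONDITION_EFFECT
    gamma = _solve_condition_boost(
        prev, beta, linked, ratio**config.group_signal_leakage
    )
    p_rows = np.where(
        group[:, None] == 1,
        _boosted_prevalence(prev, gamma, linked)[None, :],
        prev[None, :],
    )
    H = (rng.random((n, prev.size)) < p_rows).astype(float)

    eta = (
        H @ beta
        - 0.05 * (female - config.p_female)
        + 0.2 * (age - 45.0) / (hi_age - lo_age)
    )

    pi = config.p_any_spending
    positive = rng.random(n) < pi
    z = rng.standard_normal(n)
    y = np.zeros(n)
    for mask, mean_t, median_t in (
        (group == 1, t["group_mean"], t["group_median"]),
        (group == 0, t["complement_mean"], t["complement_median"]),
    ):
        c, sigma = _calibrate_lognormal(eta[mask], pi, mean_t, median_t)
        y[mask] = positive[mask] * np.exp(c + eta[mask] + sigma * z[mask])

    columns = ["female", "age"] + [f"H{i + 1:03d}" for i in range(prev.size)]
    X = np.column_stack([female, age, H])
    return RiskAdjustmentDataset(y=y, X=X, a=group, columns=columns)


def save_population(
    data: RiskAdjustmentDataset, path, config=None, seed: int | None = None
) -> None:
    """Write a generated population as CSV (person_id, design columns,
    group, y) with a JSON sidecar recording the generating recipe."""
    df = data.to_frame()
    df.insert(0, "person_id", np.arange(data.n))
    df.to_csv(path, index=False)
    if config is not None:
        sidecar = {"config": _jsonable(asdict(config)), "seed": seed
                   if seed is not None else getattr(config, "seed", None)}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, dict):
            out[k] = _jsonable(v)
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# Simulation scenarios
# ---------------------------------------------------------------------------

def _default_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x1": rng.standard_normal(n),
            "x2": rng.standard_normal(n),
            "x3": rng.standard_normal(n),
            "x4": (rng.random(n) < 0.30).astype(float),
            "x5": (rng.random(n) < 0.20).astype(float),
            "x6": (rng.random(n) < 0.25).astype(float),
            "x7": rng.standard_normal(n),
            "x8": rng.random(n),
            "x9": (rng.random(n) < 0.50).astype(float),
        }
    )


def _outcome_y1(X: pd.DataFrame, rng, noise_scale: float) -> np.ndarray:
    """Complex form: nonlinearity, interactions, a strong x6 effect, and
    heteroscedastic noise."""
    eps = rng.standard_normal(len(X)) * noise_scale * (1.0 + 0.6 * X["x4"])
    return (
        8.0
        + 2.0 * X["x1"]
        + 1.5 * X["x2"]
        - 1.0 * X["x3"]
        + 2.5 * X["x4"]
        + 10.0 * X["x6"]
        + 1.2 * X["x1"] * X["x4"]
        + 0.8 * X["x2"] ** 2
        + eps
    ).to_numpy()


def _outcome_y2(X: pd.DataFrame, rng, noise_scale: float) -> np.ndarray:
    """Simpler form: linear plus one mild interaction and homoscedastic
    noise; x6..x9 never enter."""
    eps = rng.standard_normal(len(X)) * noise_scale
    return (
        5.0
        + 2.0 * X["x1"]
        + 1.5 * X["x2"]
        - 1.0 * X["x3"]
        + 2.0 * X["x4"]
        + 1.5 * X["x5"]
        + 1.2 * X["x5"] * X["x1"]
        + eps
    ).to_numpy()


def _outcome_linear(X: pd.DataFrame, rng, noise_scale: float) -> np.ndarray:
    """Purely linear benchmark form (well-specified limit)."""
    eps = rng.standard_normal(len(X)) * noise_scale
    return (
        5.0
        + 2.0 * X["x1"]
        + 1.5 * X["x2"]
        - 1.0 * X["x3"]
        + 2.0 * X["x4"]
        + 1.5 * X["x5"]
        + eps
    ).to_numpy()


_OUTCOMES = {
    "Y1_complex": _outcome_y1,
    "Y2_simple": _outcome_y2,
    "linear": _outcome_linear,
}


def _rule_a1(X: pd.DataFrame) -> np.ndarray:
    return ((X["x6"] == 1) | ((X["x5"] == 1) & (X["x1"] > 0.5))).to_numpy().astype(int)


def _rule_a2(X: pd.DataFrame) -> np.ndarray:
    return ((X["x5"] == 1) | ((X["x6"] == 1) & (X["x2"] > 0.25))).to_numpy().astype(int)


@dataclass
class ScenarioConfig:
    """Simulation recipe.

    ``outcome`` selects the data-generating functional form;
    ``estimator_covariates`` is the (mis)specified covariate set handed to
    the estimators - scenario 1 omits x6, the main driver of both the
    complex outcome and protected class A1; scenario 2 includes every
    covariate, four of which are pure noise for the simple outcome.
    ``protected_class_rules`` maps the covariate frame to the two binary
    classes.
    """

    population_size: int = 100_000
    outcome: str = "Y1_complex"
    noise_scale: float = 2.0
    estimator_covariates: tuple[str, ...] = ("x1", "x2", "x3", "x4", "x5")
    protected_class_rules: dict = field(
        default_factory=lambda: {"A1": _rule_a1, "A2": _rule_a2}
    )
    n_sample: int = 1000
    replicates: int = 500
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self):
        if self.outcome not in _OUTCOMES:
            raise ValueError(
                f"outcome must be one of {sorted(_OUTCOMES)}, got {self.outcome!r}"
            )
        if self.n_sample > self.population_size:
            raise ValueError("n_sample exceeds the population size")
        if set(self.protected_class_rules) != {"A1", "A2"}:
            raise ValueError("protected_class_rules must define A1 and A2")

    @classmethod
    def scenario1(cls, **overrides) -> "ScenarioConfig":
        """Complex outcome, omitted-covariate misspecification."""
        kw = dict(
            outcome="Y1_complex",
            estimator_covariates=("x1", "x2", "x3", "x4", "x5"),
            name="scenario1",
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def scenario2(cls, **overrides) -> "ScenarioConfig":
        """Simpler outcome, extra noise covariates, nothing omitted."""
        kw = dict(
            outcome="Y2_simple",
            estimator_covariates=(
                "x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "x9"
            ),
            name="scenario2",
        )
        kw.update(overrides)
        return cls(**kw)


def generate_simulation_population(config: ScenarioConfig) -> pd.DataFrame:
    """Population frame with columns x1..x9, y, A1, A2 (deterministic given
    the config seed)."""
    rng = np.random.default_rng(config.seed)
    X = _default_covariates(rng, config.population_size)
    y = _OUTCOMES[config.outcome](X, rng, config.noise_scale)
    a1 = np.asarray(config.protected_class_rules["A1"](X)).astype(int)
    a2 = np.asarray(config.protected_class_rules["A2"](X)).astype(int)
    for name, a in (("A1", a1), ("A2", a2)):
        if a.sum() == 0 or a.sum() == len(X):
            raise ValueError(f"degenerate protected-class rule: {name} is "
                             "empty or universal")
    if not (a1 & a2).any():
        raise ValueError("protected classes A1 and A2 do not overlap")
    if not (a1 ^ a2).any():
        raise ValueError("protected classes A1 and A2 are identical")
    out = X.copy()
    out["y"] = y
    out["A1"] = a1
    out["A2"] = a2
    return out


def draw_replicate(
    population: pd.DataFrame, n_sample: int, seed: int, r: int
) -> pd.DataFrame:
    """Replicate ``r``: a without-replacement sample reproducible in
    isolation from (seed, r)."""
    if n_sample > len(population):
        raise ValueError("n_sample exceeds the population size")
    rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
    idx = rng.choice(len(population), size=n_sample, replace=False)
    return population.iloc[idx].reset_index(drop=True)


def draw_replicates(
    population: pd.DataFrame, n_sample: int, replicates: int, seed: int
):
    """Yield ``replicates`` independent without-replacement samples."""
    for r in range(replicates):
        yield draw_replicate(population, n_sample, seed, r)


def simulation_default_grid(n_sample: int) -> list[tuple[str, dict]]:
    """Default estimator grid for the simulation study: OLS, the two hard
    constrained methods over their multiplier/weight grids, the
    net-compensation penalty on the fraction-of-lambda-star scale (portable
    across outcome scales), and the MRD penalty on the sample-size-scaled
    grid."""
    grid: list[tuple[str, dict]] = [("ols", {}), ("avg_constrained", {})]
    grid += [("cov_constrained", {"m": m}) for m in (0.2, 0.4, 0.6, 0.8)]
    grid += [("wavg_constrained", {"alpha": a}) for a in (0.2, 0.4, 0.6, 0.8)]
    grid += [
        ("netcomp_penalized", {"lam": f, "lam_scale": "fraction"})
        for f in (0.05, 0.1, 0.3, 0.6)
    ]
    grid += [
        ("mrd_penalized", {"lam": l})
        for l in (n_sample / 100, n_sample / 10, n_sample / 5, 3 * n_sample / 10)
    ]
    return grid


@dataclass
class ScenarioResult:
    """Replicate-level metric table, per-configuration summary, and the
    fit-loss-filtered frontier."""

    replicate_table: pd.DataFrame
    summary: pd.DataFrame
    frontier: pd.DataFrame
    config: ScenarioConfig


def summarize_replicates(
    table: pd.DataFrame, max_relative_r2_loss: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and spread of each metric per configuration, plus the frontier:
    OLS and every configuration that improved the group-fairness measure
    (smaller mean |NC_g| than OLS) with a relative mean R2 loss within the
    ceiling."""
    metric_cols = [c for c in table.columns if c not in ("replicate", "method")]
    grouped = table.groupby("method", sort=False)[metric_cols]
    summary = grouped.mean()
    summary.columns = [f"{c}_mean" for c in metric_cols]
    spread = grouped.std()
    spread.columns = [f"{c}_sd" for c in metric_cols]
    summary = summary.join(spread).reset_index()

    by = summary.set_index("method")
    r2_ols = by.loc["ols", "R2_mean"]
    nc_ols = abs(by.loc["ols", "NC_g_mean"])
    keep = ["ols"] + [
        m
        for m in by.index
        if m != "ols"
        and np.isfinite(by.loc[m, "R2_mean"])
        and abs(by.loc[m, "NC_g_mean"]) < nc_ols
        and (r2_ols - by.loc[m, "R2_mean"]) <= max_relative_r2_loss * abs(r2_ols)
    ]
    frontier = summary[summary["method"].isin(keep)].reset_index(drop=True)
    return summary, frontier


def run_scenario(
    config: ScenarioConfig,
    grid: list[tuple[str, dict]] | None = None,
    n_folds: int = 5,
    protected_class: str = "A1",
    max_relative_r2_loss: float = 0.10,
) -> ScenarioResult:
    """Draw replicates from the scenario population, cross-validate the
    estimator grid on each against the chosen protected class, and apply
    the relative-R2-loss frontier filter to the across-replicate summary.

    Configurations whose preconditions fail on a replicate (for example the
    covariance constraint when the class is not undercompensated in a
    training fold) are recorded as missing for that replicate.
    """
    population = generate_simulation_population(config)
    if grid is None:
        grid = simulation_default_grid(config.n_sample)
    features = list(config.estimator_covariates)

    rows = []
    for r, sample in enumerate(
        draw_replicates(population, config.n_sample, config.replicates, config.seed)
    ):
        data = RiskAdjustmentDataset(
            y=sample["y"].to_numpy(),
            X=sample[features],
            a=sample[protected_class].to_numpy(),
        )
        for method, params in grid:
            label = config_label(method, params)
            plan = CVPlan(
                configurations=[(method, params)], n_folds=n_folds, seed=config.seed + r
            )
            try:
                res = cross_validate(data, plan)
                rep = res.reports[label]
                row = {"replicate": r, "method": label}
                row.update(rep.to_row())
            except (ValueError, ZeroDivisionError):
                row = {"replicate": r, "method": label}
            rows.append(row)
    table = pd.DataFrame(rows)
    summary, frontier = summarize_replicates(table, max_relative_r2_loss)
    return ScenarioResult(
        replicate_table=table, summary=summary, frontier=frontier, config=config
    )
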