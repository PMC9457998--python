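"""Derringer-Suich desirability optimization over the coded factor cube.

Each response's prediction is mapped to a desirability d in [0, 1] by a ramp
determined by its goal (maximize, minimize, target, in-range); the overall
desirability D is the importance-weighted geometric mean of the d_i.  D is
maximized over the coded cube [-1, 1]^k by a multistart Nelder-Mead local
search seeded from a Latin-hypercube sample, which suits the smooth but
non-concave product landscape a set of quadratic models produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy.stats import qmc

from biorsm.errors import ConfigurationError
from biorsm.rsm import FittedModel, predict

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "desirability_value",
    "overall_desirability",
    "optimize",
    "ramp_report",
]

_GOAL_KINDS = ("maximize", "minimize", "target", "in_range", "none")


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal for one response: how its prediction maps to a desirability.

    ``lower``/``upper`` default to the observed response min/max when built
    via :func:`goals_from_design`.  ``weight`` shapes the ramp (1 = linear);
    ``importance`` is the response's exponent in the geometric mean.
    """

    response_name: str
    goal_kind: str = "maximize"
    lower: float = 0.0
    upper: float = 100.0
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.goal_kind not in _GOAL_KINDS:
            raise ConfigurationError(
                f"goal_kind must be one of {_GOAL_KINDS}, got {self.goal_kind!r}"
            )
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"{self.response_name}: lower ({self.lower}) must be < upper ({self.upper})"
            )
        if self.weight < 0.1:
            raise ConfigurationError("weight must be >= 0.1")
        if self.importance < 1:
            raise ConfigurationError("importance must be >= 1")
        if self.goal_kind == "target" and self.target is None:
            raise ConfigurationError("target goal requires a target value")


def desirability_value(goal: DesirabilityGoal, yhat) -> np.ndarray | float:
    """Per-response desirability d in [0, 1] for predicted value(s) ``yhat``."""
    y = np.asarray(yhat, dtype=float)
    L, U, w = goal.lower, goal.upper, goal.weight
    if goal.goal_kind == "maximize":
        d = np.clip((y - L) / (U - L), 0.0, 1.0) ** w
    elif goal.goal_kind == "minimize":
        d = np.clip((U - y) / (U - L), 0.0, 1.0) ** w
    elif goal.goal_kind == "target":
        T = float(goal.target)
        up = np.clip((y - L) / (T - L), 0.0, 1.0) ** w
        down = np.clip((U - y) / (U - T), 0.0, 1.0) ** w
        d = np.where(y <= T, up, down)
    elif goal.goal_kind == "in_range":
        d = ((y >= L) & (y <= U)).astype(float)
    else:  # "none"
        d = np.ones_like(y)
    return d if d.ndim else float(d)


def overall_desirability(d_values: Sequence[float], importances: Sequence[float] | None = None) -> float:
    """Importance-weighted geometric mean of per-response desirabilities.

    Returns 0 as soon as any d_i is 0 (one unacceptable response annihilates
    the compromise).
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise ConfigurationError("overall desirability of an empty set is undefined")
    if np.any((d < 0) | (d > 1)):
        raise ConfigurationError("desirabilities must lie in [0, 1]")
    imp = np.ones_like(d) if importances is None else np.asarray(importances, dtype=float)
    if imp.shape != d.shape:
        raise ConfigurationError("importances must match desirabilities in length")
    if np.any(d == 0.0):
        return 0.0
    return float(np.exp(np.sum(imp * np.log(d)) / np.sum(imp)))


def goals_from_design(design, response_names: Sequence[str], goal_kind: str = "maximize") -> dict[str, DesirabilityGoal]:
    """Build default goals with bounds at each response's observed min/max."""
    goals = {}
    for name in response_names:
        y = design.response(name)
        goals[name] = DesirabilityGoal(
            response_name=name, goal_kind=goal_kind,
            lower=float(y.min()), upper=float(y.max()),
        )
    return goals


@dataclass
class OptimizationResult:
    """Best point of a multistart desirability maximization."""

    x_coded: np.ndarray
    x_actual: np.ndarray
    factor_names: list[str]
    predictions: dict[str, float]
    desirabilities: dict[str, float]
    overall: float
    n_starts: int
    converged: bool
    start_results: pd.DataFrame = field(repr=False)


def _overall_at(x: np.ndarray, models: Mapping[str, FittedModel], goals: Mapping[str, DesirabilityGoal]) -> float:
    d, imp = [], []
    for name, goal in goals.items():
        if goal.goal_kind == "none":
            continue
        yhat = float(predict(models[name], x[None, :])[0])
        d.append(desirability_value(goal, yhat))
        imp.append(goal.importance)
    return overall_desirability(d, imp)


def optimize(
    models: Mapping[str, FittedModel],
    goals: Mapping[str, DesirabilityGoal],
    n_starts: int = 32,
    seed: int | None = None,
    x0: Sequence[float] | None = None,
) -> OptimizationResult:
    """Maximize overall desirability over the coded cube [-1, 1]^k.

    Runs Nelder-Mead from ``n_starts`` Latin-hypercube points (plus ``x0``
    when given); candidate points are projected onto the cube, so the
    returned optimum always lies inside it.  Deterministic given ``seed``.
    """
    active = [n for n, g in goals.items() if g.goal_kind != "none"]
    if not active:
        raise ConfigurationError("at least one goal must not be 'none'")
    missing = [n for n in active if n not in models]
    if missing:
        raise ConfigurationError(f"no fitted model for goal response(s): {missing}")
    k = len(next(iter(models.values())).factors)
    factors = next(iter(models.values())).factors

    def neg_d(x: np.ndarray) -> float:
        return -_overall_at(np.clip(x, -1.0, 1.0), models, goals)

    sampler = qmc.LatinHypercube(d=k, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), [-1.0] * k, [1.0] * k)
    if x0 is not None:
        starts = np.vstack([np.asarray(x0, dtype=float)[None, :], starts])

    records = []
    best_x, best_d, any_conv = None, -np.inf, False
    for s in starts:
        res = sciopt.minimize(
            neg_d, s, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        x = np.clip(res.x, -1.0, 1.0)
        d_val = -neg_d(x)
        records.append({**{f"x{i}": xi for i, xi in enumerate(x)},
                        "D": d_val, "converged": bool(res.success)})
        any_conv = any_conv or bool(res.success)
        if d_val > best_d:
            best_d, best_x = d_val, x

    preds = {n: float(predict(models[n], best_x[None, :])[0]) for n in active}
    desirs = {n: float(desirability_value(goals[n], preds[n])) for n in active}
    x_actual = np.array([f.decode(c) for f, c in zip(factors, best_x)])
    return OptimizationResult(
        x_coded=best_x,
        x_actual=x_actual,
        factor_names=[f.name for f in factors],
        predictions=preds,
        desirabilities=desirs,
        overall=best_d,
        n_starts=len(starts),
        converged=any_conv,
        start_results=pd.DataFrame(records),
    )


def ramp_report(result: OptimizationResult, goals: Mapping[str, DesirabilityGoal]) -> pd.DataFrame:
    """Ramp-style summary: one row per factor setting, one per response.

    Mirrors the layout of numerical-optimization ramp plots: factors carry
    their optimal coded/actual settings; responses carry the prediction, its
    goal bounds and the per-response desirability; the final row holds the
    overall desirability (2 dp in the formatted column).
    """
    rows = []
    for name, coded, actual in zip(result.factor_names, result.x_coded, result.x_actual):
        rows.append({"kind": "factor", "name": name, "coded": coded,
                     "value": actual, "lower": np.nan, "upper": np.nan,
                     "desirability": np.nan})
    for name, yhat in result.predictions.items():
        g = goals[name]
        rows.append({"kind": "response", "name": name, "coded": np.nan,
                     "value": yhat, "lower": g.lower, "upper": g.upper,
                     "desirability": result.desirabilities[name]})
    rows.append({"kind": "overall", "name": "D", "coded": np.nan,
                 "value": result.overall, "lower": np.nan, "upper": np.nan,
                 "desirability": result.overall})
    out = pd.DataFrame(rows)
    out["formatted"] = [
        f"{r['value']:.2f}" if r["kind"] != "factor" else f"{r['value']:g}"
        for _, r in out.iterrows()
    ]
    return out
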