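"""Three-factor Box-Behnken designs and coded/actual factor-unit conversion.

A Box-Behnken design (BBD) for three factors places runs at the midpoints of
the edges of the factor cube: each pair of factors visits the four (+/-1, +/-1)
combinations while the third factor sits at its centre, giving 12 edge runs,
followed by replicated centre runs used to estimate pure error.  Factor levels
are handled in *coded units*: the low/centre/high actual levels map to
-1/0/+1 through ``coded = (actual - centre) / half_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from biorsm.errors import ConfigurationError

__all__ = [
    "FactorSpec",
    "DesignTable",
    "make_bbd",
    "code_point",
    "decode_point",
    "validate_design",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its coded-unit mapping.

    Parameters
    ----------
    name
        Short label, e.g. ``"pH"`` or ``"OLR"``.
    low, high
        Actual-unit levels assigned to coded -1 and +1.  The centre level
        (coded 0) is the arithmetic midpoint.
    units
        Free-text unit string, e.g. ``"kgCOD·m⁻³·day⁻¹"`` or ``"%"``.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ConfigurationError(f"factor {self.name!r}: levels must be finite")
        if not self.low < self.high:
            raise ConfigurationError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual):
        """Map actual units to coded units."""
        return (np.asarray(actual, dtype=float) - self.center) / self.half_range

    def decode(self, coded):
        """Map coded units back to actual units."""
        return np.asarray(coded, dtype=float) * self.half_range + self.center


def _coded_col(name: str) -> str:
    return f"coded_{name}"


@dataclass
class DesignTable:
    """A designed experiment: runs x factors in actual and coded units.

    ``data`` holds one row per run with columns ``run_id``, one actual-unit
    column per factor (named after the factor), one coded column per factor
    (``coded_<name>``) and any number of response columns (percent removal,
    0-100).  Extra columns are carried through untouched.
    """

    factors: Sequence[FactorSpec]
    data: pd.DataFrame
    responses: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = list(self.factors)
        missing = [f.name for f in self.factors if f.name not in self.data.columns]
        if missing:
            raise ConfigurationError(f"design data lacks factor columns: {missing}")
        for f in self.factors:
            col = _coded_col(f.name)
            if col not in self.data.columns:
                self.data[col] = f.code(self.data[f.name].to_numpy())
        absent = [r for r in self.responses if r not in self.data.columns]
        if absent:
            raise ConfigurationError(f"design data lacks response columns: {absent}")

    @property
    def n_runs(self) -> int:
        return len(self.data)

    def coded_matrix(self) -> np.ndarray:
        """Runs x factors array of coded levels."""
        cols = [_coded_col(f.name) for f in self.factors]
        return self.data[cols].to_numpy(dtype=float)

    def actual_matrix(self) -> np.ndarray:
        """Runs x factors array of actual-unit levels."""
        return self.data[[f.name for f in self.factors]].to_numpy(dtype=float)

    def response(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ConfigurationError(f"no response column {name!r} in design table")
        return self.data[name].to_numpy(dtype=float)


def make_bbd(factors: Sequence[FactorSpec], n_center: int = 3) -> DesignTable:
    """Construct a three-factor Box-Behnken design.

    Runs are emitted in a fixed canonical order: factor pairs (1,2), (1,3),
    (2,3), each pair in the level order (-,-), (+,-), (-,+), (+,+) with the
    off-pair factor at 0, followed by ``n_center`` centre runs.  ``run_id``
    is 1..N.  A 3-factor BBD with c centre points has 12 + c runs.
    """
    factors = list(factors)
    if len(factors) != 3:
        raise ConfigurationError(
            f"Box-Behnken construction requires exactly 3 factors, got {len(factors)}"
        )
    if n_center < 1:
        raise ConfigurationError("n_center must be >= 1")
    coded_rows: list[list[float]] = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for xi, xj in ((-1, -1), (1, -1), (-1, 1), (1, 1)):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = float(xi), float(xj)
            coded_rows.append(row)
    coded_rows.extend([[0.0, 0.0, 0.0]] * n_center)
    coded = np.array(coded_rows)
    data = {"run_id": np.arange(1, len(coded) + 1)}
    for k, f in enumerate(factors):
        data[f.name] = f.decode(coded[:, k])
        data[_coded_col(f.name)] = coded[:, k]
    return DesignTable(factors, pd.DataFrame(data))


def code_point(
    factors: Sequence[FactorSpec], actual_levels: Sequence[float]
) -> tuple[np.ndarray, bool]:
    """Convert one point from actual to coded units.

    Returns ``(coded_levels, extrapolation)`` where ``extrapolation`` is True
    when any coded coordinate falls outside [-1, 1] (out-of-cube points are
    allowed, only flagged).
    """
    actual = np.asarray(actual_levels, dtype=float)
    if actual.shape != (len(factors),):
        raise ConfigurationError(
            f"expected {len(factors)} levels, got shape {actual.shape}"
        )
    if not np.all(np.isfinite(actual)):
        raise ConfigurationError("actual levels must be finite")
    coded = np.array([f.code(a) for f, a in zip(factors, actual)])
    return coded, bool(np.any(np.abs(coded) > 1.0))


def decode_point(
    factors: Sequence[FactorSpec], coded_levels: Sequence[float]
) -> np.ndarray:
    """Convert one point from coded to actual units (exact inverse of code_point)."""
    coded = np.asarray(coded_levels, dtype=float)
    if coded.shape != (len(factors),):
        raise ConfigurationError(
            f"expected {len(factors)} levels, got shape {coded.shape}"
        )
    return np.array([f.decode(c) for f, c in zip(factors, coded)])


def validate_design(design: DesignTable, atol: float = 1e-9) -> Mapping[str, object]:
    """Check the orthogonality structure of a (nominally) Box-Behnken design.

    Never raises on imbalance; returns a report dict with per-check booleans,
    the list of failed checks and the number of replicated centre runs.

    Checks
    ------
    * ``column_balance`` — every coded column sums to 0;
    * ``linear_quadratic_orthogonality`` — sum x_i * x_j^2 = 0 for i != j;
    * ``interaction_orthogonality`` — sum x_i * x_j = 0 for i < j;
    * ``coding_consistency`` — coded = (actual - centre)/half_range cellwise;
    * ``bbd_structure`` — levels in {-1,0,+1}, 12 edge runs of the BBD
      pattern plus >= 1 centre run.
    """
    X = design.coded_matrix()
    k = X.shape[1]
    checks: dict[str, bool] = {}
    checks["column_balance"] = bool(np.all(np.abs(X.sum(axis=0)) <= atol))
    lq = all(
        abs(float(np.sum(X[:, i] * X[:, j] ** 2))) <= atol
        for i in range(k)
        for j in range(k)
        if i != j
    )
    checks["linear_quadratic_orthogonality"] = lq
    inter = all(
        abs(float(np.sum(X[:, i] * X[:, j]))) <= atol
        for i in range(k)
        for j in range(i + 1, k)
    )
    checks["interaction_orthogonality"] = inter
    recoded = np.column_stack(
        [f.code(design.data[f.name].to_numpy()) for f in design.factors]
    )
    checks["coding_consistency"] = bool(np.allclose(recoded, X, atol=1e-12, rtol=0))
    center_mask = np.all(np.abs(X) <= atol, axis=1)
    n_center = int(center_mask.sum())
    three_level = bool(
        np.all(np.min(np.abs(X[:, :, None] - np.array([-1.0, 0.0, 1.0])), axis=2) <= atol)
    )
    edge = X[~center_mask]
    edge_pattern = three_level and len(edge) == 12 and bool(
        np.all(np.sum(np.abs(np.round(edge)), axis=1) == 2)
    )
    checks["bbd_structure"] = edge_pattern and n_center >= 1
    return {
        "checks": checks,
        "failed": sorted(name for name, ok in checks.items() if not ok),
        "n_center_runs": n_center,
        "ok": all(checks.values()),
    }
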