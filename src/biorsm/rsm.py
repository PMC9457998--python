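"""Second-order response-surface models on coded factors.

The response surface is the quadratic polynomial

    Y = b0 + sum_i bi x_i + sum_i bii x_i^2 + sum_{i<j} bij x_i x_j + e

fitted by ordinary least squares in coded units, where x_i in [-1, 1] are the
coded factor levels.  The module fits full or reduced term sets, converts the
coded polynomial to an algebraically identical actual-unit equation, performs
Type-III (partial) ANOVA with a lack-of-fit test from replicated centre
points, and computes the Design-of-Experiments fit statistics (R2 family,
PRESS/predicted R2, coefficient of variation, adequate precision).

Terms are named by factor letters in design order: ``A``, ``B``, ``C`` for
the linear effects, ``AB``/``AC``/``BC`` for interactions, ``A2``/``B2``/
``C2`` for the pure quadratics, and ``1`` for the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from biorsm.doe import DesignTable, FactorSpec
from biorsm.errors import ConfigurationError, SingularModelError

__all__ = [
    "FULL_QUADRATIC",
    "LINEAR_INTERACTION",
    "ModelSpec",
    "FittedModel",
    "AnovaTable",
    "FitStats",
    "build_model_matrix",
    "fit_ols",
    "coded_to_actual",
    "predict",
    "reduce_model",
    "anova",
    "fit_stats",
    "residual_diagnostics",
]

_LETTERS = "ABC"
#: Canonical term order for the 3-factor quadratic model.
_CANONICAL = ("1", "A", "B", "C", "AB", "AC", "BC", "A2", "B2", "C2")

FULL_QUADRATIC: tuple[str, ...] = _CANONICAL
LINEAR_INTERACTION: tuple[str, ...] = ("1", "A", "B", "C", "AB", "AC", "BC")


def _factor_indices(term: str) -> tuple[int, ...]:
    """Factor indices a term involves, with multiplicity ('A2' -> (0, 0))."""
    if term == "1":
        return ()
    if len(term) == 1 and term in _LETTERS:
        return (_LETTERS.index(term),)
    if len(term) == 2 and term[0] in _LETTERS and term[1] == "2":
        i = _LETTERS.index(term[0])
        return (i, i)
    if len(term) == 2 and term[0] in _LETTERS and term[1] in _LETTERS:
        return (_LETTERS.index(term[0]), _LETTERS.index(term[1]))
    raise ConfigurationError(f"unknown model term {term!r}")


def _parents(term: str) -> tuple[str, ...]:
    """Lower-order terms a term implies under model hierarchy."""
    idx = _factor_indices(term)
    if len(idx) < 2:
        return ()
    return tuple(dict.fromkeys(_LETTERS[i] for i in idx))


@dataclass(frozen=True)
class ModelSpec:
    """An ordered subset of the quadratic term taxonomy; intercept always present."""

    terms: tuple[str, ...] = FULL_QUADRATIC

    def __post_init__(self) -> None:
        seen = []
        for t in self.terms:
            _factor_indices(t)  # validates
            if t not in seen:
                seen.append(t)
        if "1" not in seen:
            seen.insert(0, "1")
        ordered = tuple(sorted(seen, key=_CANONICAL.index))
        object.__setattr__(self, "terms", ordered)

    def __len__(self) -> int:
        return len(self.terms)

    def drop(self, term: str) -> "ModelSpec":
        return ModelSpec(tuple(t for t in self.terms if t != term))

    def hierarchy_violations(self) -> list[tuple[str, str]]:
        """(term, missing parent) pairs; empty when the spec is hierarchical."""
        return [
            (t, p)
            for t in self.terms
            for p in _parents(t)
            if p not in self.terms
        ]

    def is_droppable(self, term: str) -> bool:
        """True when removing ``term`` keeps the spec hierarchical."""
        if term == "1":
            return False
        return all(term not in _parents(t) for t in self.terms if t != term)


def _as_spec(spec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    return ModelSpec(tuple(spec))


def _term_columns(coded: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    n, k = coded.shape
    cols = []
    for t in terms:
        idx = _factor_indices(t)
        for i in idx:
            if i >= k:
                raise ConfigurationError(
                    f"term {t!r} references factor index {i} but design has {k} factors"
                )
        col = np.ones(n)
        for i in idx:
            col = col * coded[:, i]
        cols.append(col)
    return np.column_stack(cols)


def build_model_matrix(design: DesignTable, spec=FULL_QUADRATIC) -> np.ndarray:
    """Model matrix of coded term columns (one column per term, runs as rows)."""
    return _term_columns(design.coded_matrix(), _as_spec(spec).terms)


@dataclass
class FittedModel:
    """An OLS response-surface fit in coded units.

    ``coef_coded``/``se_coded`` are indexed by term name.  ``coef_actual``
    is the algebraically expanded actual-unit polynomial over the full
    quadratic basis; it predicts identically to the coded form.
    """

    spec: ModelSpec
    factors: list[FactorSpec]
    response_name: str
    coef_coded: pd.Series
    se_coded: pd.Series
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    _X: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)

    @property
    def p(self) -> int:
        return len(self.spec)

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def mse(self) -> float:
        return self.rss / (self.n - self.p)

    @property
    def coef_actual(self) -> pd.Series:
        return coded_to_actual(self)

    def equation(self, units: str = "coded", ndigits: int = 4) -> str:
        """Human-readable model equation string."""
        coef = self.coef_coded if units == "coded" else self.coef_actual
        parts = []
        for term, b in coef.items():
            if units == "actual" and b == 0.0 and term != "1":
                continue
            mono = "" if term == "1" else term
            parts.append(f"{b:+.{ndigits}g}{('·' + mono) if mono else ''}")
        return f"{self.response_name} = " + " ".join(parts)


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        bad = sorted(terms[i] for i in piv[rank:])
        raise SingularModelError(bad)


def fit_ols(design: DesignTable, response_name: str, spec=FULL_QUADRATIC) -> FittedModel:
    """Fit the quadratic response model by ordinary least squares in coded units.

    Standard errors come from the MSE * (X'X)^-1 diagonal; the fit is
    deterministic and requires more runs than terms.
    """
    spec = _as_spec(spec)
    y = design.response(response_name)
    X = build_model_matrix(design, spec)
    if design.n_runs <= len(spec):
        raise ConfigurationError(
            f"{design.n_runs} runs cannot identify {len(spec)} terms plus error"
        )
    _check_rank(X, spec.terms)
    res = sm.OLS(y, X).fit()
    return FittedModel(
        spec=spec,
        factors=list(design.factors),
        response_name=response_name,
        coef_coded=pd.Series(res.params, index=list(spec.terms)),
        se_coded=pd.Series(res.bse, index=list(spec.terms)),
        n=design.n_runs,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        _X=X,
        _y=y,
    )


def coded_to_actual(model: FittedModel) -> pd.Series:
    """Expand the coded polynomial into actual units.

    Substituting x_i = (X_i - centre_i)/half_range_i into each coded term and
    collecting monomials yields an actual-unit polynomial over the full
    quadratic basis that predicts identically at every point.
    """
    a = np.array([1.0 / f.half_range for f in model.factors])
    b = np.array([-f.center / f.half_range for f in model.factors])
    out = {t: 0.0 for t in _CANONICAL[: 1 + 3 * len(model.factors)]}

    def letter(i: int) -> str:
        return _LETTERS[i]

    for term, beta in model.coef_coded.items():
        idx = _factor_indices(term)
        if len(idx) == 0:
            out["1"] += beta
        elif len(idx) == 1:
            i = idx[0]
            out[letter(i)] += beta * a[i]
            out["1"] += beta * b[i]
        elif idx[0] == idx[1]:
            i = idx[0]
            out[letter(i) + "2"] += beta * a[i] ** 2
            out[letter(i)] += 2.0 * beta * a[i] * b[i]
            out["1"] += beta * b[i] ** 2
        else:
            i, j = idx
            key = letter(i) + letter(j)
            out[key] += beta * a[i] * a[j]
            out[letter(i)] += beta * a[i] * b[j]
            out[letter(j)] += beta * a[j] * b[i]
            out["1"] += beta * b[i] * b[j]
    return pd.Series(out)


def predict(
    model: FittedModel,
    points,
    units: str = "coded",
    return_extrapolation: bool = False,
):
    """Evaluate the fitted polynomial at points given in coded or actual units.

    ``points`` is (m, k) or a single length-k point.  With
    ``return_extrapolation=True`` also returns a boolean mask of points whose
    coded coordinates fall outside the [-1, 1] cube.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != len(model.factors):
        raise ConfigurationError(
            f"points must have {len(model.factors)} columns, got {pts.shape[1]}"
        )
    if units == "actual":
        coded = np.column_stack(
            [f.code(pts[:, i]) for i, f in enumerate(model.factors)]
        )
    elif units == "coded":
        coded = pts
    else:
        raise ConfigurationError(f"units must be 'coded' or 'actual', got {units!r}")
    X = _term_columns(coded, model.spec.terms)
    yhat = X @ model.coef_coded.to_numpy()
    if return_extrapolation:
        return yhat, np.any(np.abs(coded) > 1.0 + 1e-12, axis=1)
    return yhat


def reduce_model(
    design: DesignTable,
    response_name: str,
    alpha: float = 0.05,
    start=FULL_QUADRATIC,
) -> ModelSpec:
    """Backward elimination of insignificant terms at level ``alpha``.

    Starting from ``start`` (default full quadratic), each round refits and
    drops the hierarchy-respecting non-intercept term with the largest
    coefficient p-value above ``alpha``; ties break by reverse canonical term
    order (highest-order term first).  Stops when every droppable term is
    significant; may return the full model.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    spec = _as_spec(start)
    while True:
        model = fit_ols(design, response_name, spec)
        tvals = model.coef_coded / model.se_coded
        df = model.n - model.p
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        candidates = [
            (p_val, -_CANONICAL.index(t), t)
            for t, p_val in zip(spec.terms, pvals)
            if spec.is_droppable(t) and p_val > alpha
        ]
        if not candidates:
            return spec
        candidates.sort(reverse=True)
        spec = spec.drop(candidates[0][2])


@dataclass
class AnovaTable:
    """ANOVA decomposition with per-term partial SS and a lack-of-fit test."""

    table: pd.DataFrame
    ss_type: str
    lack_of_fit_available: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def _replicate_groups(design: DesignTable) -> list[np.ndarray]:
    coded = np.round(design.coded_matrix(), 10)
    keys = [tuple(row) for row in coded]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return [np.array(v) for v in groups.values() if len(v) > 1]


def anova(
    design: DesignTable,
    response_name: str,
    spec=FULL_QUADRATIC,
    ss_type: str = "partial",
) -> AnovaTable:
    """ANOVA for the response model: per-term SS, F and p, plus lack of fit.

    ``ss_type='partial'`` (Type III, default) charges each term the increase
    in residual SS when it alone is removed; ``'sequential'`` (Type I) charges
    terms in model order.  Pure error comes from replicated design points
    (the centre replicates in a BBD); without replicates the lack-of-fit rows
    are marked unavailable rather than raising.
    """
    if ss_type not in ("partial", "sequential"):
        raise ConfigurationError(f"ss_type must be 'partial' or 'sequential': {ss_type!r}")
    spec = _as_spec(spec)
    model = fit_ols(design, response_name, spec)
    y = design.response(response_name)
    n = len(y)
    ss_res = model.rss
    df_res = n - model.p
    mse = ss_res / df_res
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_model = ss_tot - ss_res
    df_model = model.p - 1

    rows = []
    f_model = (ss_model / df_model) / mse if mse > 0 else np.inf
    rows.append(
        ("Model", ss_model, df_model, ss_model / df_model,
         f_model, float(stats.f.sf(f_model, df_model, df_res)))
    )
    nonint = [t for t in spec.terms if t != "1"]
    if ss_type == "partial":
        for t in nonint:
            sub = fit_ols(design, response_name, ModelSpec(tuple(x for x in spec.terms if x != t)))
            ss_t = max(sub.rss - ss_res, 0.0)
            f_t = ss_t / mse if mse > 0 else np.inf
            rows.append((t, ss_t, 1, ss_t, f_t, float(stats.f.sf(f_t, 1, df_res))))
    else:
        prev_rss = ss_tot
        built: list[str] = ["1"]
        for t in nonint:
            built.append(t)
            sub = fit_ols(design, response_name, ModelSpec(tuple(built)))
            ss_t = max(prev_rss - sub.rss, 0.0)
            prev_rss = sub.rss
            f_t = ss_t / mse if mse > 0 else np.inf
            rows.append((t, ss_t, 1, ss_t, f_t, float(stats.f.sf(f_t, 1, df_res))))
    rows.append(("Residual", ss_res, df_res, mse, np.nan, np.nan))

    groups = _replicate_groups(design)
    lof_available = bool(groups)
    if lof_available:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups))
        df_pe = int(sum(len(g) - 1 for g in groups))
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        if df_lof > 0 and df_pe > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof, p_lof = np.nan, np.nan
        rows.append(("Lack of Fit", ss_lof, df_lof, ss_lof / df_lof if df_lof else np.nan, f_lof, p_lof))
        rows.append(("Pure Error", ss_pe, df_pe, ss_pe / df_pe if df_pe else np.nan, np.nan, np.nan))
    rows.append(("Cor Total", ss_tot, n - 1, np.nan, np.nan, np.nan))

    table = pd.DataFrame(rows, columns=["source", "ss", "df", "ms", "F", "p"])
    return AnovaTable(table=table, ss_type=ss_type, lack_of_fit_available=lof_available)


@dataclass(frozen=True)
class FitStats:
    """Design-of-experiments fit statistics for one fitted response model."""

    r2: float
    adj_r2: float
    pred_r2: float
    adeq_precision: float
    std_dev: float
    mean: float
    cv_percent: float
    press: float


def fit_stats(design: DesignTable, response_name: str, spec=FULL_QUADRATIC) -> FitStats:
    """R2 family, PRESS, CV%% and adequate precision for the model.

    * predicted R2 uses the leave-one-out identity PRESS = sum (e_i/(1-h_ii))^2
      with h the OLS leverage;
    * adequate precision is the signal-to-noise ratio
      (max yhat - min yhat) / sqrt(p * MSE / n) over the design points.
    """
    model = fit_ols(design, response_name, spec)
    y = model._y
    n, p = model.n, model.p
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = model.rss
    res = sm.OLS(y, model._X).fit()
    h = OLSInfluence(res).hat_matrix_diag
    press = float(np.sum((model.residuals / (1.0 - h)) ** 2))
    std_dev = float(np.sqrt(ss_res / (n - p)))
    mean = float(y.mean())
    yhat = model.fitted
    adeq = float((yhat.max() - yhat.min()) / np.sqrt(p * model.mse / n)) if ss_res > 0 else np.inf
    return FitStats(
        r2=1.0 - ss_res / ss_tot,
        adj_r2=1.0 - (ss_res / (n - p)) / (ss_tot / (n - 1)),
        pred_r2=1.0 - press / ss_tot,
        adeq_precision=adeq,
        std_dev=std_dev,
        mean=mean,
        cv_percent=100.0 * std_dev / mean,
        press=press,
    )


def residual_diagnostics(model: FittedModel) -> pd.DataFrame:
    """Data for normal-probability and predicted-vs-actual diagnostic plots.

    Internally studentized residuals are paired with normal quantiles from
    the (i - 0.375)/(n + 0.25) plotting positions, sorted ascending; the
    observed and fitted responses are carried alongside (run order preserved
    in the ``run_index`` column).  No rendering is done here.
    """
    n = model.n
    if model.rss <= 1e-12 * max(1.0, float(model._y @ model._y)):
        stud = np.zeros(n)
    else:
        res = sm.OLS(model._y, model._X).fit()
        stud = np.asarray(OLSInfluence(res).resid_studentized_internal)
    order = np.argsort(stud, kind="stable")
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return pd.DataFrame(
        {
            "run_index": order,
            "normal_quantile": stats.norm.ppf(probs),
            "studentized_residual": stud[order],
            "observed": model._y[order],
            "predicted": model.fitted[order],
        }
    )
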