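"""Readers, writers and the end-to-end reference pipeline.

The design CSV dialect has a header row with ``run_id``, one actual-unit
column per factor and any number of response columns (UTF-8, "." decimal).
``run_reference_pipeline`` ties the stages together on the bundled
antibiotic-digestion case study (or any user-supplied design): OLS fits of
the per-response term sets, coded and actual-unit coefficients, ANOVA and
fit statistics, prediction diagnostics and the desirability optimization
ramp, all written as deterministic CSV/text files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from biorsm import datasets, desirability, rsm
from biorsm.doe import DesignTable, FactorSpec
from biorsm.errors import ConfigurationError

__all__ = [
    "AnalysisConfig",
    "read_factor_config",
    "read_design_csv",
    "write_design_csv",
    "write_report",
    "run_reference_pipeline",
]

log = logging.getLogger("biorsm")


@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end analysis run."""

    factors: list[FactorSpec] = field(default_factory=datasets.antibiotic_factors)
    design_csv: str | None = None  # None -> bundled case-study table
    term_sets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(datasets.DEFAULT_TERM_SETS)
    )
    prediction_term_sets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(datasets.PREDICTION_TERM_SETS)
    )
    alpha: float = 0.05
    n_starts: int = 32
    seed: int = 0
    outdir: str = "biorsm_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")


def read_factor_config(path) -> list[FactorSpec]:
    """Read factor specifications from a YAML/JSON file (name/low/high/units)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    entries = cfg["factors"] if isinstance(cfg, dict) else cfg
    return [
        FactorSpec(name=f["name"], low=float(f["low"]), high=float(f["high"]),
                   units=f.get("units", ""))
        for f in entries
    ]


def read_design_csv(path, factors: Sequence[FactorSpec]) -> DesignTable:
    """Read a design/response CSV, validate levels and attach coded columns.

    Non-factor, non-``run_id`` numeric columns become responses; other extra
    columns are carried through as passthrough metadata with a logged
    warning.  Non-numeric factor/response cells raise a parse error naming
    the row and column.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ConfigurationError(f"{path}: empty or headerless CSV") from exc
    if raw.empty:
        raise ConfigurationError(f"{path}: no data rows")
    factor_names = [f.name for f in factors]
    missing = [n for n in factor_names if n not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing factor columns {missing}")
    responses, passthrough = [], []
    for col in raw.columns:
        if col in factor_names or col == "run_id" or col.startswith("coded_"):
            continue
        if pd.api.types.is_numeric_dtype(raw[col]):
            responses.append(col)
        else:
            passthrough.append(col)
    if passthrough:
        log.warning("non-numeric columns carried as metadata: %s", passthrough)
    for col in factor_names + responses:
        bad = raw[pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
        if len(bad):
            raise ConfigurationError(
                f"{path}: non-numeric value in column {col!r}, row {bad.index[0] + 2}"
            )
        if raw[col].isna().any():
            row = int(raw[raw[col].isna()].index[0]) + 2
            raise ConfigurationError(f"{path}: missing value in column {col!r}, row {row}")
    if "run_id" not in raw.columns:
        raw.insert(0, "run_id", np.arange(1, len(raw) + 1))
    table = DesignTable(list(factors), raw, responses=responses)
    extrapolated = np.any(np.abs(table.coded_matrix()) > 1.0 + 1e-9, axis=1)
    if extrapolated.any():
        log.warning("rows outside the factor cube: %s",
                    raw.loc[extrapolated, "run_id"].tolist())
    return table


def write_design_csv(design: DesignTable, path) -> None:
    """Write a design table (actual units, coded columns and responses)."""
    design.data.to_csv(path, index=False)


def _float_fmt(x) -> str:
    return "" if pd.isna(x) else repr(float(x))


def write_report(results: Mapping[str, object], outdir) -> list[Path]:
    """Write analysis results as deterministic CSV/text files.

    Recognised keys: ``coefficients``, ``anova_<resp>``, ``fit_stats``,
    ``predicted_vs_actual``, ``diagnostics_<resp>``, ``ramp`` (DataFrames)
    and ``summary`` (str).  Numeric cells are written with ``repr`` so
    repeated runs are byte-identical; empty frames yield header-only files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for key in sorted(results):
        value = results[key]
        if isinstance(value, str):
            path = out / f"{key}.txt"
            path.write_text(value, encoding="utf-8")
        elif isinstance(value, pd.DataFrame):
            path = out / f"{key}.csv"
            value.to_csv(path, index=False, float_format=None,
                         encoding="utf-8")
        else:
            raise ConfigurationError(f"cannot serialize result {key!r} of type {type(value)}")
        written.append(path)
        log.info("wrote %s", path)
    return written


def run_reference_pipeline(config: AnalysisConfig | None = None) -> dict[str, object]:
    """Fit, analyse and optimize the case-study (or configured) design.

    Returns the result bundle (also suitable for :func:`write_report`):
    coded/actual coefficients, per-response ANOVA, fit statistics,
    predicted-vs-actual values, residual diagnostics, the desirability
    optimization ramp and a plain-text summary.
    """
    config = config or AnalysisConfig()
    if config.design_csv is None:
        design = datasets.antibiotic_design_table()
    else:
        design = read_design_csv(config.design_csv, config.factors)
    missing = [r for r in config.term_sets if r not in design.data.columns]
    if missing:
        raise ConfigurationError(f"design has no response column(s) {missing}")
    log.info("design: %d runs, responses %s", design.n_runs, list(config.term_sets))

    results: dict[str, object] = {}
    coef_rows, stat_rows, pva = [], [], {"run_id": design.data["run_id"].to_numpy()}
    pred_models = {}
    for resp, terms in config.term_sets.items():
        model = rsm.fit_ols(design, resp, terms)
        actual = model.coef_actual
        for term in rsm.FULL_QUADRATIC:
            coef_rows.append({
                "response": resp, "term": term,
                "coef_coded": model.coef_coded.get(term, np.nan),
                "se_coded": model.se_coded.get(term, np.nan),
                "coef_actual": actual.get(term, 0.0),
            })
        results[f"anova_{resp}"] = rsm.anova(design, resp, terms).table
        st = rsm.fit_stats(design, resp, terms)
        stat_rows.append({"response": resp, "R2": st.r2, "AdjR2": st.adj_r2,
                          "PredR2": st.pred_r2, "AdeqPrecision": st.adeq_precision,
                          "StdDev": st.std_dev, "Mean": st.mean,
                          "CVpct": st.cv_percent, "PRESS": st.press})
        results[f"diagnostics_{resp}"] = rsm.residual_diagnostics(model)
        pred_terms = config.prediction_term_sets.get(resp, terms)
        pmodel = rsm.fit_ols(design, resp, pred_terms)
        pred_models[resp] = pmodel
        pva[f"{resp}_obs"] = design.response(resp)
        pva[f"{resp}_pred"] = pmodel.fitted
        log.info("%s: %s", resp, pmodel.equation(units="actual"))
    results["coefficients"] = pd.DataFrame(coef_rows)
    results["fit_stats"] = pd.DataFrame(stat_rows)
    results["predicted_vs_actual"] = pd.DataFrame(pva)

    goals = desirability.goals_from_design(design, list(config.term_sets))
    opt = desirability.optimize(pred_models, goals,
                                n_starts=config.n_starts, seed=config.seed)
    results["ramp"] = desirability.ramp_report(opt, goals)

    lines = ["Response surface summary", "========================", ""]
    for resp in config.term_sets:
        st = next(r for r in stat_rows if r["response"] == resp)
        lines.append(f"{resp}: R2={st['R2']:.4f}  AdjR2={st['AdjR2']:.4f}  "
                     f"CV%={st['CVpct']:.2f}  Mean={st['Mean']:.2f}")
    lines.append("")
    lines.append("Optimum (coded): " + np.array2string(opt.x_coded, precision=3))
    lines.append("Optimum (actual): " + ", ".join(
        f"{n}={v:.3g}" for n, v in zip(opt.factor_names, opt.x_actual)))
    lines.append("Predicted at optimum: " + ", ".join(
        f"{n}={v:.1f}%" for n, v in opt.predictions.items()))
    lines.append(f"Overall desirability D = {opt.overall:.2f}")
    results["summary"] = "\n".join(lines) + "\n"
    return results
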