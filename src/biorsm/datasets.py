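"""Bundled reference data: a published 15-run antibiotic-digestion BBD study.

The packaged case study is a three-factor Box-Behnken experiment on the
anaerobic biodegradation of two fluoroquinolone antibiotics: pH (6-8),
organic loading rate (2-6 kgCOD·m⁻³·day⁻¹) and dosed antibiotic
concentration (10-100% of stock) against observed percent removal of
ciprofloxacin (CIP), enrofloxacin (ENRO) and chemical oxygen demand (COD).
Removal percentages are stored exactly as published (integers); the
``*_pred`` columns carry the originally reported model predictions as
reference metadata and take no part in any fit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from biorsm.doe import DesignTable, FactorSpec

__all__ = [
    "antibiotic_factors",
    "antibiotic_design_table",
    "DEFAULT_TERM_SETS",
    "PREDICTION_TERM_SETS",
    "KINETICS_PRESETS",
]

#: Term sets under which the published coefficient tables were produced.
DEFAULT_TERM_SETS = {
    "CIP": ("1", "A", "B", "C", "AB", "AC", "BC", "A2", "B2", "C2"),
    "ENRO": ("1", "A", "B", "C", "AB", "AC", "BC", "A2", "B2"),
    "COD": ("1", "A", "B", "C", "AB", "AC", "BC", "A2", "B2", "C2"),
}

#: Term sets that generated the published per-run predictions and the
#: reported optimum; ENRO's predictions come from the further-reduced
#: linear + interaction model (its quadratic terms were dropped in the
#: published prediction equation).
PREDICTION_TERM_SETS = {
    "CIP": DEFAULT_TERM_SETS["CIP"],
    "ENRO": ("1", "A", "B", "C", "AB", "AC", "BC"),
    "COD": DEFAULT_TERM_SETS["COD"],
}

#: Published first-order kinetics presets for simulating decay series:
#: (c0, k [day^-1], plateau), concentrations in mg/L.
KINETICS_PRESETS = {
    "ENRO": {"c0": 2270.0, "k": 0.0958, "plateau": 10.0},
    "CIP": {"c0": 2242.0, "k": 0.148, "plateau": 8.0},
}


def _data_path(name: str):
    return resources.files("biorsm").joinpath("data", name)


def antibiotic_factors() -> list[FactorSpec]:
    """The three factor specifications of the bundled case study."""
    with _data_path("antibiotic_factors.yaml").open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return [
        FactorSpec(name=f["name"], low=float(f["low"]), high=float(f["high"]),
                   units=f.get("units", ""))
        for f in cfg["factors"]
    ]


def antibiotic_design_table() -> DesignTable:
    """The bundled 15-run design with observed CIP/ENRO/COD removal (%).

    Runs 3, 5 and 9 are replicated centre points (pH 7, OLR 4, ANT 55)
    providing the pure-error estimate.
    """
    with _data_path("antibiotic_bbd_design.csv").open("r", encoding="utf-8") as fh:
        data = pd.read_csv(fh)
    return DesignTable(antibiotic_factors(), data, responses=["CIP", "ENRO", "COD"])
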