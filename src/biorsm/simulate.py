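"""Synthetic data with known ground truth for the RSM and kinetics pipelines.

Responses on a Box-Behnken design are simulated as the coded quadratic
polynomial plus i.i.d. homoscedastic Gaussian noise — exactly the error
structure the second-order response model assumes — so refitting at zero
noise must recover the generating coefficients to numerical precision.
Decay series are simulated from plateaued first-order kinetics with additive
Gaussian noise scaled to the initial concentration.  Every generator draws
from a single ``numpy.random.default_rng(seed)``; identical configurations
produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from biorsm.doe import DesignTable, FactorSpec, make_bbd
from biorsm.errors import ConfigurationError
from biorsm.kinetics import DecayDataset
from biorsm.rsm import ModelSpec, _term_columns

__all__ = ["SimulationConfig", "simulate_bbd_responses", "simulate_decay"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth for a simulated BBD response.

    ``true_coefficients`` maps term names (``"1"``, ``"A"``, ``"AB"``,
    ``"A2"``, ...) to coded-unit values; ``noise_sd`` is the response-scale
    standard deviation of the additive Gaussian error.
    """

    true_coefficients: Mapping[str, float]
    noise_sd: float = 0.0
    seed: int | None = None
    n_center: int = 3
    response_name: str = "Y"
    clip: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        ModelSpec(tuple(self.true_coefficients))  # validates term names


def simulate_bbd_responses(
    config: SimulationConfig,
    factors: Sequence[FactorSpec],
    design: DesignTable | None = None,
) -> DesignTable:
    """Simulate a BBD response column from known coded coefficients.

    Builds a fresh canonical BBD (``config.n_center`` centre runs) unless an
    existing ``design`` is passed, then adds the polynomial value plus
    Normal(0, noise_sd) noise per run.  Responses are clipped to [0, 100]
    only when ``config.clip`` is set (off by default so zero-noise OLS
    recovery stays exact).
    """
    if design is None:
        design = make_bbd(factors, n_center=config.n_center)
    terms = tuple(config.true_coefficients)
    X = _term_columns(design.coded_matrix(), terms)
    beta = np.array([config.true_coefficients[t] for t in terms], dtype=float)
    rng = np.random.default_rng(config.seed)
    y = X @ beta + rng.normal(0.0, config.noise_sd, size=design.n_runs)
    if config.clip:
        y = np.clip(y, 0.0, 100.0)
    out = design.data.copy()
    out[config.response_name] = y
    return DesignTable(list(design.factors), out, responses=[config.response_name])


def simulate_decay(
    c0: float,
    k: float,
    plateau: float = 0.0,
    times: Sequence[float] | None = None,
    noise_fraction: float = 0.0,
    seed: int | None = None,
    label: str = "",
    units: str = "mg/L",
) -> DecayDataset:
    """Simulate plateaued first-order decay with additive Gaussian noise.

    C(t) = plateau + (c0 - plateau) e^{-kt} + Normal(0, noise_fraction * c0).
    ``times`` defaults to daily sampling over a 28-day batch (0..28).
    Negative noisy draws are floored at 0 and flagged on the dataset.
    """
    if k <= 0:
        raise ConfigurationError(f"rate constant must be positive, got {k}")
    if noise_fraction < 0:
        raise ConfigurationError("noise_fraction must be >= 0")
    t = np.arange(0.0, 29.0) if times is None else np.asarray(times, dtype=float)
    clean = plateau + (c0 - plateau) * np.exp(-k * t)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_fraction * c0, size=t.shape)
    clipped = bool(np.any(noisy < 0))
    return DecayDataset(
        times=t,
        concentrations=np.maximum(noisy, 0.0),
        label=label,
        units=units,
        clipped=clipped,
    )
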