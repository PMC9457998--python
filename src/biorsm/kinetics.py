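"""Degradation kinetics: first-order and modified-Gompertz fits, half-lives.

Antibiotic disappearance in an anaerobic digester is usually well described
by first-order decay,

    dC/dt = -k C   =>   C(t) = C0 * exp(-k t),

optionally with a residual plateau C(t) = plateau + (C0 - plateau) e^{-kt}
for the non-degradable fraction.  A modified Gompertz form adds a lag phase
for the microbial-adaptation period.  All fits are nonlinear least squares
(Levenberg-Marquardt) initialized deterministically from a log-linear
regression, so repeated fits are reproducible without random restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from biorsm.errors import ConfigurationError, DomainError, FitConvergenceError

__all__ = [
    "DecayDataset",
    "KineticsFit",
    "fit_first_order",
    "fit_gompertz",
    "half_life",
    "percent_reduction",
    "goodness",
]


@dataclass
class DecayDataset:
    """A concentration-time series for one analyte.

    Times are in days, strictly increasing and non-negative; concentrations
    are non-negative in the recorded ``units`` (mg/L or ug/L).
    """

    times: np.ndarray
    concentrations: np.ndarray
    label: str = ""
    units: str = "mg/L"
    clipped: bool = False  # True when negative simulated draws were floored

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ConfigurationError("times and concentrations must be equal-length 1-D")
        if np.any(self.times < 0):
            raise ConfigurationError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ConfigurationError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class KineticsFit:
    """Result of a kinetics fit.

    ``half_life`` is ln2/k for the first-order kinds; for the Gompertz model
    it is the time at which the curve crosses half the fitted amplitude.
    """

    model_kind: str
    c0: float
    k: float
    plateau: float
    lag: float | None
    rss: float
    r2: float
    adj_r2: float
    half_life: float
    se: dict = field(default_factory=dict)
    n: int = 0
    n_params: int = 0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model_kind in ("first_order", "first_order_plateau"):
            return _first_order(t, self.c0, self.k, self.plateau)
        return _gompertz(t, self.c0, self.k, self.lag)


def _first_order(t, c0, k, plateau=0.0):
    return plateau + (c0 - plateau) * np.exp(-k * t)


def _gompertz(t, c0, k, lag):
    # decreasing sigmoid: remaining = c0 - degraded, with the degraded amount
    # following the modified Gompertz curve of amplitude c0, max rate k, lag.
    u = (k * math.e / c0) * (lag - t) + 1.0
    return c0 * (1.0 - np.exp(-np.exp(u)))


def _gof(obs: np.ndarray, pred: np.ndarray, n_params: int) -> tuple[float, float, float]:
    rss = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    n = len(obs)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params) if n > n_params else np.nan
    return rss, r2, adj


def _loglinear_init(t: np.ndarray, c: np.ndarray, plateau: float) -> tuple[float, float]:
    """Slope/intercept start values from OLS on (t, ln(C - plateau)).

    Values at or below the plateau are shifted just above it so the log is
    always defined; the result only seeds the nonlinear fit.
    """
    shifted = c - plateau
    floor = max(1e-12, 1e-6 * max(shifted.max(), 1.0))
    z = np.log(np.maximum(shifted, floor))
    slope, intercept = np.polyfit(t, z, 1)
    k0 = max(-slope, 1e-6)
    c0 = float(np.exp(intercept)) + plateau
    return c0, k0


def fit_first_order(data: DecayDataset, with_plateau: bool = False) -> KineticsFit:
    """Fit C(t) = plateau + (C0 - plateau) e^{-kt} by nonlinear least squares.

    With ``with_plateau=False`` the plateau is fixed at 0 (pure first-order
    decay).  Initialization: plateau guess = min(C) (when free), then a
    log-linear regression for C0 and k.  Raises on a constant series (no
    decay signal) and on optimizer failure.
    """
    n_params = 3 if with_plateau else 2
    if len(data) < n_params + 1:
        raise ConfigurationError(
            f"need at least {n_params + 1} points for a {n_params}-parameter fit"
        )
    t, c = data.times, data.concentrations
    if np.ptp(c) == 0:
        raise ConfigurationError("concentration series is constant: no decay signal")
    p_guess = float(c.min()) if with_plateau else 0.0
    c0_guess, k_guess = _loglinear_init(t, c, p_guess)
    try:
        if with_plateau:
            popt, pcov = curve_fit(
                _first_order, t, c, p0=[c0_guess, k_guess, p_guess],
                method="lm", maxfev=20000,
            )
            c0_hat, k_hat, plat_hat = popt
            names = ("c0", "k", "plateau")
        else:
            popt, pcov = curve_fit(
                lambda tt, c0, k: _first_order(tt, c0, k, 0.0), t, c,
                p0=[c0_guess, k_guess], method="lm", maxfev=20000,
            )
            c0_hat, k_hat = popt
            plat_hat = 0.0
            names = ("c0", "k")
    except RuntimeError as exc:  # pragma: no cover - pathological series
        raise FitConvergenceError(f"first-order fit did not converge: {exc}") from exc
    if k_hat <= 0:
        raise FitConvergenceError(
            f"fitted rate constant is non-positive (k = {k_hat:.4g}): no decay signal"
        )
    pred = _first_order(t, c0_hat, k_hat, plat_hat)
    rss, r2, adj = _gof(c, pred, n_params)
    se = dict(zip(names, np.sqrt(np.diag(pcov))))
    return KineticsFit(
        model_kind="first_order_plateau" if with_plateau else "first_order",
        c0=float(c0_hat), k=float(k_hat), plateau=float(plat_hat), lag=None,
        rss=rss, r2=r2, adj_r2=adj, half_life=half_life(float(k_hat)),
        se=se, n=len(data), n_params=n_params,
    )


def fit_gompertz(data: DecayDataset) -> KineticsFit:
    """Fit the decreasing modified-Gompertz curve (amplitude, max rate, lag).

    The remaining concentration is modelled as
    C(t) = C0 * (1 - exp(-exp((k e / C0)(lag - t) + 1))), i.e. the degraded
    amount follows the modified Gompertz sigmoid with amplitude C0, maximum
    degradation rate k (concentration/day) and lag time lambda (days).
    """
    if len(data) < 5:
        raise ConfigurationError("Gompertz fit needs at least 5 points")
    t, c = data.times, data.concentrations
    if np.ptp(c) == 0:
        raise ConfigurationError("concentration series is constant: no decay signal")
    c0_guess = float(c.max())
    grad = np.gradient(c, t)
    k_guess = max(float(-grad.min()), 1e-3)
    lag_guess = float(t[int(np.argmin(grad))])
    try:
        popt, pcov = curve_fit(
            _gompertz, t, c, p0=[c0_guess, k_guess, lag_guess],
            method="lm", maxfev=50000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"Gompertz fit did not converge: {exc}") from exc
    c0_hat, k_hat, lag_hat = popt
    if k_hat <= 0 or c0_hat <= 0:
        raise FitConvergenceError(
            f"Gompertz fit degenerate (c0 = {c0_hat:.4g}, k = {k_hat:.4g})"
        )
    pred = _gompertz(t, c0_hat, k_hat, lag_hat)
    rss, r2, adj = _gof(c, pred, 3)
    # time at which the curve crosses c0/2: exp(-exp(u)) = 1/2 at u = ln ln 2
    t_half = float(lag_hat + (1.0 - math.log(math.log(2.0))) * c0_hat / (k_hat * math.e))
    se = dict(zip(("c0", "k", "lag"), np.sqrt(np.diag(pcov))))
    return KineticsFit(
        model_kind="gompertz",
        c0=float(c0_hat), k=float(k_hat), plateau=0.0, lag=float(lag_hat),
        rss=rss, r2=r2, adj_r2=adj, half_life=t_half,
        se=se, n=len(data), n_params=3,
    )


def half_life(k: float) -> float:
    """First-order half-life t1/2 = ln 2 / k (days for k in day^-1)."""
    if k <= 0:
        raise DomainError(f"rate constant must be positive, got {k}")
    return math.log(2.0) / k


def percent_reduction(c0: float, ct: float) -> float:
    """Percent removal 100 * (C0 - Ct) / C0 of a contaminant."""
    if c0 <= 0:
        raise DomainError(f"initial concentration must be positive, got {c0}")
    if ct < 0:
        raise DomainError(f"final concentration must be >= 0, got {ct}")
    return 100.0 * (c0 - ct) / c0


def goodness(fit: KineticsFit, data: DecayDataset) -> tuple[float, float, float]:
    """(RSS, R2, adjusted R2) of ``fit`` evaluated on ``data``."""
    pred = fit.predict(data.times)
    return _gof(data.concentrations, pred, fit.n_params)
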