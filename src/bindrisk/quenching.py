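"""Fluorescence quenching and binding-constant estimation.

Three classical models are fitted to a concentration–intensity series
``{[Q] -> F}`` that includes the zero-quencher intensity F0:

Stern–Volmer
    ``F0/F = 1 + Ksv·[Q] = 1 + kq·τ0·[Q]`` — quenching efficiency. Ksv is
    the through-origin least-squares slope of ``F0/F − 1`` on ``[Q]``; the
    bimolecular quenching rate constant is ``kq = Ksv/τ0`` with the
    unquenched fluorophore lifetime τ0 = 1e-8 s by default. kq values far
    above the diffusion-limited ~2e10 L/(mol·s) indicate static
    (complex-forming) quenching.

Double-log (Scatchard-type)
    ``log10((F0−F)/F) = log10(Ka) + n·log10([Q])`` — association constant Ka
    and apparent number of binding sites n, for quenching series.

Fluorescence enhancement
    ``(F∞−F0)/(Fx−F0) = 1 + 1/(Ka·[Q])`` — Ka for ligands that enhance
    rather than quench emission, fitted as the double-reciprocal line
    ``1/(Fx−F0) = a + b/[Q]`` with ``Ka = a/b`` and ``F∞ = F0 + 1/a``.

Each model is exposed as a scikit-learn-style regressor (``fit``/``predict``
on concentration arrays) and as a function returning a result dataclass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from bindrisk.spectra import monotonic_trend

__all__ = [
    "BindingFit",
    "DoubleLogBindingRegressor",
    "EnhancementBindingRegressor",
    "QuenchFit",
    "SternVolmerRegressor",
    "classify_quenching",
    "double_log_fit",
    "enhancement_fit",
    "ka_in_optimal_range",
    "select_binding_model",
    "stern_volmer_fit",
]

#: Unquenched fluorophore lifetime (s) used to derive kq from Ksv.
DEFAULT_TAU0 = 1e-8
#: Diffusion-limited collisional quenching ceiling, L/(mol·s).
KQ_DIFFUSION_LIMIT = 2e10
#: Relative tolerance above F0 at which a "quenching" point is flagged as
#: enhancement-like.
_ENHANCEMENT_TOL = 1e-9


@dataclass(frozen=True)
class QuenchFit:
    """Stern–Volmer fit result.

    ``kq == ksv / tau0`` exactly by construction. ``r2`` is computed on the
    transformed variables (F0/F − 1 vs [Q]). ``free_slope``/``free_intercept``
    report a diagnostic unconstrained line, not used for Ksv.
    """

    ksv: float
    kq: float
    r2: float
    n_points: int
    temperature: float
    tau0: float = DEFAULT_TAU0
    free_slope: float = float("nan")
    free_intercept: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a Stern–Volmer fit needs at least 3 nonzero concentrations")

    @property
    def ksv_1e4(self) -> float:
        """Ksv in the conventional ×10⁴ L/mol reporting scale."""
        return self.ksv / 1e4

    @property
    def kq_1e12(self) -> float:
        """kq in the conventional ×10¹² L/(mol·s) reporting scale."""
        return self.kq / 1e12


@dataclass(frozen=True)
class BindingFit:
    """Binding-constant fit from the double-log or enhancement model.

    ``n_sites`` is the apparent number of binding sites (double-log model
    only); ``f_inf`` is the saturation intensity (enhancement model only).
    Logarithms in the double-log model are base 10.
    """

    ka: float
    model: Literal["double_log", "enhancement"]
    r2: float
    temperature: float
    n_sites: float | None = None
    f_inf: float | None = None
    log_base: int = 10

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("ka must be positive")
        if self.model == "double_log" and (self.n_sites is None or self.n_sites <= 0):
            raise ValueError("double_log fits require n_sites > 0")

    @property
    def ka_1e4(self) -> float:
        """Ka in the conventional ×10⁴ L/mol reporting scale."""
        return self.ka / 1e4


def _split_series(series: Mapping[float, float]) -> tuple[float, np.ndarray, np.ndarray]:
    """Return (F0, nonzero concentrations, intensities) from a conc->F map."""
    if 0 not in series and 0.0 not in series:
        raise ValueError("series must contain the zero-concentration intensity F0")
    f0 = float(series[0] if 0 in series else series[0.0])
    concs = np.array(sorted(c for c in series if c > 0), dtype=float)
    if np.any(np.array(list(series)) < 0):
        raise ValueError("concentrations must be non-negative")
    if concs.size < 3:
        raise ValueError("at least 3 nonzero concentrations are required")
    f = np.array([series[c] for c in concs], dtype=float)
    return f0, concs, f


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def stern_volmer_fit(
    series: Mapping[float, float],
    temperature: float = 298.0,
    tau0: float = DEFAULT_TAU0,
) -> QuenchFit:
    """Fit the Stern–Volmer quenching constant Ksv and derive kq = Ksv/τ0.

    The regression is through the origin on the transformed variables
    (``y = F0/F − 1`` vs ``x = [Q]``), since the model has no free intercept.
    A diagnostic free-intercept line is reported alongside.

    Raises if any intensity is non-positive, or if any treated intensity
    exceeds F0 (an enhancement-like series is not a quenching series).
    """
    f0, concs, f = _split_series(series)
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    if np.any(f <= 0):
        raise ValueError("all intensities must be positive")
    if np.any(f >= f0 * (1 + _ENHANCEMENT_TOL)):
        raise ValueError("enhancement-like, Stern–Volmer invalid: F exceeds F0 at Q > 0")
    y = f0 / f - 1.0
    x = concs
    ksv = float(np.dot(x, y) / np.dot(x, x))
    r2 = _r2(y, ksv * x)
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        lin = stats.linregress(x, y)
        free_slope, free_intercept = float(lin.slope), float(lin.intercept)
    else:
        free_slope, free_intercept = float("nan"), float("nan")
    return QuenchFit(
        ksv=ksv,
        kq=ksv / tau0,
        r2=r2,
        n_points=int(concs.size),
        temperature=float(temperature),
        tau0=float(tau0),
        free_slope=free_slope,
        free_intercept=free_intercept,
    )


def classify_quenching(
    fit_low_T: QuenchFit,
    fit_high_T: QuenchFit,
    kq_limit: float = KQ_DIFFUSION_LIMIT,
) -> Literal["static", "dynamic", "indeterminate"]:
    """Classify the quenching mechanism from fits at two temperatures.

    Static (ground-state complex): kq above the diffusion limit at both
    temperatures AND Ksv falling with temperature. Dynamic (collisional):
    kq at or below the limit at both temperatures AND Ksv rising.
    Conflicting evidence is "indeterminate".
    """
    if not fit_low_T.temperature < fit_high_T.temperature:
        raise ValueError("fit_low_T must be at the lower temperature")
    kq_high = fit_low_T.kq > kq_limit and fit_high_T.kq > kq_limit
    kq_low = fit_low_T.kq <= kq_limit and fit_high_T.kq <= kq_limit
    ksv_falls = fit_high_T.ksv < fit_low_T.ksv
    ksv_rises = fit_high_T.ksv > fit_low_T.ksv
    if kq_high and ksv_falls:
        return "static"
    if kq_low and ksv_rises:
        return "dynamic"
    return "indeterminate"


def double_log_fit(series: Mapping[float, float], temperature: float = 298.0) -> BindingFit:
    """Fit Ka and n from the double-log (Scatchard-type) plot.

    Ordinary least squares of ``log10((F0−F)/F)`` on ``log10([Q])``;
    ``Ka = 10**intercept`` and ``n = slope``. Requires a genuine quenching
    series (F < F0 at every Q > 0).
    """
    f0, concs, f = _split_series(series)
    if np.any(f >= f0):
        raise ValueError("not a quenching series: F must be below F0 at every Q > 0")
    if np.any(f <= 0):
        raise ValueError("all intensities must be positive")
    x = np.log10(concs)
    y = np.log10((f0 - f) / f)
    lin = stats.linregress(x, y)
    ka = 10.0 ** float(lin.intercept)
    r2 = float(lin.rvalue) ** 2 if not math.isnan(lin.rvalue) else 1.0
    return BindingFit(
        ka=ka, model="double_log", r2=r2, temperature=float(temperature),
        n_sites=float(lin.slope),
    )


def enhancement_fit(series: Mapping[float, float], temperature: float = 298.0) -> BindingFit:
    """Fit Ka and F∞ from a fluorescence-enhancement series.

    Double-reciprocal least squares ``1/(Fx−F0) = a + b/[Q]`` with
    ``Ka = a/b`` and ``F∞ = F0 + 1/a``. Requires Fx > F0 at every Q > 0 and
    a saturating response (both fitted coefficients positive).

    The line is fitted with inverse-variance weights ``w ∝ (Fx−F0)⁴``:
    under noise that scales with the signal, var(1/(Fx−F0)) ∝ 1/(Fx−F0)⁴,
    so an unweighted fit is dominated by the noisiest low-concentration
    points (the classic reciprocal-plot pathology). Weighting changes
    nothing on exact data.
    """
    f0, concs, f = _split_series(series)
    if np.any(f <= f0):
        raise ValueError("not an enhancement series: Fx must exceed F0 at every Q > 0")
    x = 1.0 / concs
    y = 1.0 / (f - f0)
    w = (f - f0) ** 4
    A = np.column_stack([np.ones_like(x), x])
    awa = A.T @ (w[:, None] * A)
    coef = np.linalg.solve(awa, A.T @ (w * y))
    a, b = float(coef[0]), float(coef[1])
    if a <= 0 or b <= 0:
        raise ValueError("no saturating enhancement: double-reciprocal fit yielded a <= 0 or b <= 0")
    yhat = A @ coef
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BindingFit(
        ka=a / b, model="enhancement", r2=r2, temperature=float(temperature),
        f_inf=f0 + 1.0 / a,
    )


def ka_in_optimal_range(ka: float, lo: float = 1e4, hi: float = 1e6) -> bool:
    """Whether Ka lies in the physiologically relevant window [lo, hi] L/mol.

    Binding constants in roughly 1e4–1e6 L/mol are strong enough to perturb
    receptor function yet reversible; bounds are inclusive and strict.
    """
    if ka <= 0:
        raise ValueError("ka must be positive")
    return lo <= ka <= hi


def select_binding_model(series: Mapping[float, float]) -> Literal["double_log", "enhancement"]:
    """Choose the binding model from the dose–response direction.

    Decreasing intensity selects the double-log quenching model; increasing
    selects the enhancement model; a non-monotone series is ambiguous and
    raises.
    """
    trend = monotonic_trend(series)
    if trend == "decreasing":
        return "double_log"
    if trend == "increasing":
        return "enhancement"
    raise ValueError("series is not monotone in concentration; no binding model applies")


# ---------------------------------------------------------------------------
# scikit-learn style estimators


class _SeriesRegressor(BaseEstimator, RegressorMixin):
    """Shared validation for regressors on (concentration, intensity) data."""

    @staticmethod
    def _to_series(X, y) -> dict[float, float]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single concentration column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y must have the same length")
        series = {float(c): float(v) for c, v in zip(X, y)}
        if len(series) != X.size:
            raise ValueError("duplicate concentrations")
        return series


class SternVolmerRegressor(_SeriesRegressor):
    """Stern–Volmer quenching model as a scikit-learn regressor.

    ``fit(X, y)`` takes concentrations (mol/L, including 0) and intensities;
    ``predict(X)`` returns ``F0/(1 + Ksv·[Q])``.

    Attributes (after fit): ``ksv_``, ``kq_``, ``r2_``, ``f0_``, ``n_points_``.
    """

    def __init__(self, temperature: float = 298.0, tau0: float = DEFAULT_TAU0):
        self.temperature = temperature
        self.tau0 = tau0

    def fit(self, X, y):
        series = self._to_series(X, y)
        fit = stern_volmer_fit(series, temperature=self.temperature, tau0=self.tau0)
        self.f0_ = float(series[min(series)])
        self.ksv_ = fit.ksv
        self.kq_ = fit.kq
        self.r2_ = fit.r2
        self.n_points_ = fit.n_points
        self.result_ = fit
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        q = X[:, 0] if X.ndim == 2 else X
        return self.f0_ / (1.0 + self.ksv_ * q)


class DoubleLogBindingRegressor(_SeriesRegressor):
    """Double-log (Scatchard-type) binding model as a scikit-learn regressor.

    Attributes (after fit): ``ka_``, ``n_sites_``, ``r2_``, ``f0_``.
    ``predict`` inverts the fitted double-log line:
    ``F = F0/(1 + Ka·[Q]**n)``.
    """

    def __init__(self, temperature: float = 298.0):
        self.temperature = temperature

    def fit(self, X, y):
        series = self._to_series(X, y)
        fit = double_log_fit(series, temperature=self.temperature)
        self.f0_ = float(series[min(series)])
        self.ka_ = fit.ka
        self.n_sites_ = fit.n_sites
        self.r2_ = fit.r2
        self.result_ = fit
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        q = X[:, 0] if X.ndim == 2 else X
        return self.f0_ / (1.0 + self.ka_ * np.power(q, self.n_sites_))


class EnhancementBindingRegressor(_SeriesRegressor):
    """Fluorescence-enhancement binding model as a scikit-learn regressor.

    Attributes (after fit): ``ka_``, ``f_inf_``, ``r2_``, ``f0_``.
    ``predict`` returns ``F0 + (F∞−F0)·Ka·[Q]/(1 + Ka·[Q])``.
    """

    def __init__(self, temperature: float = 298.0):
        self.temperature = temperature

    def fit(self, X, y):
        series = self._to_series(X, y)
        fit = enhancement_fit(series, temperature=self.temperature)
        self.f0_ = float(series[min(series)])
        self.ka_ = fit.ka
        self.f_inf_ = fit.f_inf
        self.r2_ = fit.r2
        self.result_ = fit
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        q = X[:, 0] if X.ndim == 2 else X
        kq = self.ka_ * q
        return self.f0_ + (self.f_inf_ - self.f0_) * kq / (1.0 + kq)
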