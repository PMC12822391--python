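"""Cellular thermal shift assay (CETSA) melt-curve analysis.

CETSA measures the soluble fraction of a target protein that survives a
brief heat challenge across a temperature gradient. Ligand binding
stabilizes the folded state, shifting the melting midpoint Tm50 — the
temperature at which half of the protein has precipitated — to higher
temperatures. The per-sample descending Boltzmann sigmoid

    f(T) = bottom + (top − bottom) / (1 + exp((T − tm50)/slope))

is fitted by nonlinear least squares to band intensities normalized to the
lowest-temperature point, and ΔTm50 = Tm50(treated) − Tm50(control)
quantifies stabilization (positive = stabilized).

Temperatures are in °C throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MeltCurve",
    "MeltCurveRegressor",
    "MeltFit",
    "delta_tm50",
    "fit_melt_curve",
    "isothermal_stabilization",
    "melt_fits_frame",
    "normalize_melt",
    "read_melt_csv",
    "write_melt_csv",
]

#: Bounds on the normalized plateau parameters; densitometry rarely reaches
#: exactly 0 or 1, so the plateaus are free within a generous band.
_PLATEAU_BOUNDS = (-0.2, 1.5)


@dataclass(frozen=True)
class MeltCurve:
    """Soluble-fraction (band intensity) vs temperature for one sample."""

    sample: str
    temps: np.ndarray
    soluble: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=float)
        s = np.asarray(self.soluble, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise ValueError("temps and soluble must be 1-D and the same length")
        if t.size < 4:
            raise ValueError("a melt curve needs at least 4 temperatures")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("band intensities must be non-negative")
        object.__setattr__(self, "temps", t)
        object.__setattr__(self, "soluble", s)


@dataclass(frozen=True)
class MeltFit:
    """Fitted Boltzmann melt curve.

    ``tm50`` is the sigmoid midpoint where f = (top+bottom)/2;
    ``tm50_interp`` additionally reports the linear interpolation of the
    50% crossing on the raw points, for comparison with the midpoint
    definition. ``slope`` (°C) is positive for a descending transition.
    """

    sample: str
    tm50: float
    slope: float
    top: float
    bottom: float
    r2: float
    tm50_interp: float | None = None


def _boltzmann(T, tm50, slope, top, bottom):
    return bottom + (top - bottom) / (1.0 + np.exp((T - tm50) / slope))


def normalize_melt(curve: MeltCurve) -> MeltCurve:
    """Normalize band intensities to the lowest-temperature point.

    Idempotent for an already-normalized curve. The first point must be
    positive.
    """
    if curve.soluble[0] <= 0:
        raise ValueError("cannot normalize: band intensity at the lowest temperature is not positive")
    return replace(curve, soluble=curve.soluble / curve.soluble[0])


def _interp_crossing(temps: np.ndarray, soluble: np.ndarray, half: float) -> float | None:
    """First linear interpolation of the descending crossing of `half`."""
    for i in range(temps.size - 1):
        y0, y1 = soluble[i], soluble[i + 1]
        if y0 >= half >= y1 and y0 != y1:
            frac = (y0 - half) / (y0 - y1)
            return float(temps[i] + frac * (temps[i + 1] - temps[i]))
    return None


def fit_melt_curve(curve: MeltCurve, normalize: bool = True) -> MeltFit:
    """Fit the descending Boltzmann sigmoid to a melt curve.

    The curve is normalized to its first point unless ``normalize=False``.
    Initialization: top = max, bottom = min, tm50 = temperature of the point
    nearest the half-range, slope = 1 °C. Plateaus are bounded to
    [−0.2, 1.5]; tm50 is constrained to the sampled temperature range.

    Raises if the curve shows no decline (no melt transition) or the
    optimizer fails to converge.
    """
    if normalize:
        curve = normalize_melt(curve)
    T, y = curve.temps, curve.soluble
    if y[-1] >= y[0]:
        raise ValueError(f"no melt transition: curve for {curve.sample!r} does not decline")
    half = 0.5 * (y.max() + y.min())
    p0 = [float(T[np.argmin(np.abs(y - half))]), 1.0, float(y.max()), float(y.min())]
    lo = [float(T[0]), 1e-3, _PLATEAU_BOUNDS[0], _PLATEAU_BOUNDS[0]]
    hi = [float(T[-1]), 50.0, _PLATEAU_BOUNDS[1], _PLATEAU_BOUNDS[1]]
    try:
        popt, _ = curve_fit(_boltzmann, T, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        raise ValueError(f"melt-curve fit for {curve.sample!r} did not converge: {err}") from err
    tm50, slope, top, bottom = (float(v) for v in popt)
    yhat = _boltzmann(T, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MeltFit(
        sample=curve.sample,
        tm50=tm50,
        slope=slope,
        top=top,
        bottom=bottom,
        r2=r2,
        tm50_interp=_interp_crossing(T, y, 0.5 * (top + bottom)),
    )


def delta_tm50(treated: MeltFit, control: MeltFit) -> float:
    """Thermal shift ΔTm50 = Tm50(treated) − Tm50(control), °C.

    Positive values indicate ligand-induced thermal stabilization.
    """
    return treated.tm50 - control.tm50


def isothermal_stabilization(treated_band: float, control_band: float) -> float:
    """Fold soluble protein retained at a single challenge temperature.

    The single-temperature variant of CETSA (e.g. a 46 °C challenge):
    the ratio of treated to control soluble band intensity, > 1 meaning
    stabilization.
    """
    if control_band <= 0:
        raise ValueError("control band intensity must be positive")
    return treated_band / control_band


class MeltCurveRegressor(BaseEstimator, RegressorMixin):
    """Boltzmann melt-curve model as a scikit-learn regressor.

    ``fit(X, y)`` takes temperatures (°C) and band intensities;
    intensities are normalized to the first point when ``normalize=True``.

    Attributes (after fit): ``tm50_``, ``slope_``, ``top_``, ``bottom_``,
    ``r2_``, ``tm50_interp_``.
    """

    def __init__(self, normalize: bool = True):
        self.normalize = normalize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        t = X[:, 0] if X.ndim == 2 else X
        order = np.argsort(t)
        curve = MeltCurve(sample="<array>", temps=t[order], soluble=np.asarray(y, float)[order])
        res = fit_melt_curve(curve, normalize=self.normalize)
        self.tm50_ = res.tm50
        self.slope_ = res.slope
        self.top_ = res.top
        self.bottom_ = res.bottom
        self.r2_ = res.r2
        self.tm50_interp_ = res.tm50_interp
        self.result_ = res
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        t = X[:, 0] if X.ndim == 2 else X
        return _boltzmann(t, self.tm50_, self.slope_, self.top_, self.bottom_)


# ---------------------------------------------------------------------------
# CSV interface: sample, replicate, temp_C, band_intensity. Replicates are
# averaged per temperature before fitting.


def read_melt_csv(path) -> list[MeltCurve]:
    """Read melt curves from a long CSV (sample, replicate, temp_C, band_intensity)."""
    df = pd.read_csv(path)
    required = {"sample", "temp_C", "band_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"melt CSV missing columns: {sorted(missing)}")
    curves = []
    for sample, group in df.groupby("sample", sort=True):
        mean = group.groupby("temp_C", sort=True)["band_intensity"].mean()
        curves.append(
            MeltCurve(sample=str(sample), temps=mean.index.to_numpy(), soluble=mean.to_numpy())
        )
    return curves


def write_melt_csv(curves: Sequence[MeltCurve], path) -> None:
    rows = [
        (c.sample, 1, t, s) for c in curves for t, s in zip(c.temps, c.soluble)
    ]
    pd.DataFrame(rows, columns=["sample", "replicate", "temp_C", "band_intensity"]).to_csv(
        path, index=False
    )


def melt_fits_frame(fits: Sequence[MeltFit], control: str | None = None) -> pd.DataFrame:
    """Tabulate melt fits, with ΔTm50 against a named control sample."""
    ctrl = next((f for f in fits if f.sample == control), None) if control else None
    rows = []
    for f in fits:
        rows.append(
            {
                "sample": f.sample,
                "tm50_C": f.tm50,
                "slope_C": f.slope,
                "top": f.top,
                "bottom": f.bottom,
                "r2": f.r2,
                "tm50_interp_C": f.tm50_interp if f.tm50_interp is not None else float("nan"),
                "delta_tm50_C": delta_tm50(f, ctrl) if ctrl is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)
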