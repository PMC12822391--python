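"""Emission-spectrum containers and spectral feature extraction.

A titration experiment records one emission spectrum of the protein per
quencher (ligand) concentration at a fixed temperature. Downstream quenching
and binding fits consume the intensity read at a single observation
wavelength; this module locates emission maxima, extracts those
concentration–intensity series, and classifies spectral shifts and
dose–response direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "characterize_spectrum",
    "classify_shift",
    "extract_intensity_series",
    "monotonic_trend",
    "read_titration_csv",
    "write_titration_csv",
]

#: Sentinel for :func:`extract_intensity_series`: read each spectrum at its
#: own emission maximum instead of a fixed wavelength.
PER_SPECTRUM_MAX = "per-spectrum-max"


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission scan at a fixed quencher concentration and temperature.

    Parameters
    ----------
    wavelengths : array-like of float
        Emission wavelengths in nm, strictly increasing, at least 3 points.
    intensities : array-like of float
        Fluorescence intensities (arbitrary units), non-negative, same length.
    quencher_conc : float
        Quencher concentration in mol/L (0 for the untreated control scan).
    temperature : float
        Temperature in K.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    quencher_conc: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValueError("wavelengths and intensities must be 1-D and the same length")
        if wl.size < 3:
            raise ValueError("a spectrum needs at least 3 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        if self.quencher_conc < 0:
            raise ValueError("quencher concentration must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)


@dataclass(frozen=True)
class TitrationSeries:
    """Spectra of one protein–ligand pair across quencher concentrations.

    Exactly one spectrum must have ``quencher_conc == 0`` (the F0 scan);
    concentrations must be unique and all spectra share one temperature.
    """

    protein: str
    ligand: str
    spectra: tuple[EmissionSpectrum, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        if not spectra:
            raise ValueError("a titration series needs at least one spectrum")
        concs = [s.quencher_conc for s in spectra]
        if len(set(concs)) != len(concs):
            raise ValueError("quencher concentrations must be unique")
        if sum(c == 0 for c in concs) != 1:
            raise ValueError("exactly one zero-concentration (F0) spectrum is required")
        temps = {s.temperature for s in spectra}
        if len(temps) != 1:
            raise ValueError("all spectra in a series must share one temperature")
        object.__setattr__(self, "spectra", tuple(sorted(spectra, key=lambda s: s.quencher_conc)))

    @property
    def temperature(self) -> float:
        return self.spectra[0].temperature

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.quencher_conc for s in self.spectra])

    @property
    def control(self) -> EmissionSpectrum:
        """The zero-quencher (F0) spectrum."""
        return self.spectra[0]


def characterize_spectrum(spectrum: EmissionSpectrum) -> tuple[float, float]:
    """Locate the global emission maximum of a spectrum.

    Returns ``(lambda_max, peak_intensity)``. Ties are broken toward the
    smallest wavelength. An all-zero spectrum has no peak and raises.
    """
    it = spectrum.intensities
    if np.all(it == 0):
        raise ValueError("no peak: all intensities are zero")
    idx = int(np.argmax(it))  # argmax returns the first (smallest-wavelength) maximum
    return float(spectrum.wavelengths[idx]), float(it[idx])


def extract_intensity_series(
    series: TitrationSeries,
    lambda_ref: float | str = PER_SPECTRUM_MAX,
) -> dict[float, float]:
    """Extract one intensity per concentration from a titration series.

    Parameters
    ----------
    series : TitrationSeries
    lambda_ref : float or ``"per-spectrum-max"``
        A numeric reference wavelength reads every spectrum at the sampled
        wavelength nearest to it (the Stern–Volmer convention of a fixed
        observation wavelength); the string sentinel reads each spectrum at
        its own emission maximum (the dose-plot convention).

    Returns
    -------
    dict mapping concentration (mol/L) to intensity, in ascending
    concentration order; the entry at 0 is F0.
    """
    out: dict[float, float] = {}
    if isinstance(lambda_ref, str):
        if lambda_ref != PER_SPECTRUM_MAX:
            raise ValueError(f"unknown lambda_ref {lambda_ref!r}")
        for s in series.spectra:
            out[float(s.quencher_conc)] = characterize_spectrum(s)[1]
        return out
    lam = float(lambda_ref)
    for s in series.spectra:
        if lam < s.wavelengths[0] or lam > s.wavelengths[-1]:
            raise ValueError(
                f"lambda_ref {lam} nm outside spectral range "
                f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]"
            )
        idx = int(np.argmin(np.abs(s.wavelengths - lam)))
        out[float(s.quencher_conc)] = float(s.intensities[idx])
    return out


def classify_shift(
    lambda_control: float, lambda_treated: float, threshold: float = 2.0
) -> Literal["red", "blue", "none"]:
    """Classify an emission-maximum shift of the treated vs control spectrum.

    A move to shorter wavelength by at least ``threshold`` nm is a blue
    shift; to longer wavelength, a red shift; anything smaller is "none".
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    delta = lambda_treated - lambda_control
    if -delta >= threshold:
        return "blue"
    if delta >= threshold:
        return "red"
    return "none"


def monotonic_trend(
    series: Mapping[float, float], rtol: float = 1e-6
) -> Literal["increasing", "decreasing", "none"]:
    """Direction of the dose–response of intensity vs concentration.

    "decreasing" requires strictly decreasing intensities in concentration
    order (quenching), "increasing" strictly increasing (enhancement); ties
    within relative tolerance ``rtol`` break strict monotonicity and yield
    "none". Needs at least 3 concentrations.
    """
    if len(series) < 3:
        raise ValueError("monotonic_trend needs at least 3 concentrations")
    concs = sorted(series)
    vals = np.array([series[c] for c in concs], dtype=float)
    diffs = np.diff(vals)
    scale = np.maximum(np.abs(vals[:-1]), np.abs(vals[1:]))
    tied = np.abs(diffs) <= rtol * np.maximum(scale, 1e-300)
    if np.all(~tied & (diffs < 0)):
        return "decreasing"
    if np.all(~tied & (diffs > 0)):
        return "increasing"
    return "none"


# ---------------------------------------------------------------------------
# CSV interface (long format: protein, ligand, temperature_K, conc_M,
# wavelength_nm, intensity). Wavelength grids may differ between spectra;
# no interpolation is performed.

_COLUMNS = ["protein", "ligand", "temperature_K", "conc_M", "wavelength_nm", "intensity"]


def read_titration_csv(path) -> list[TitrationSeries]:
    """Read long-format titration spectra into TitrationSeries objects.

    One series is built per (protein, ligand, temperature_K) group.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"titration CSV missing columns: {missing}")
    out = []
    for (protein, ligand, temp), group in df.groupby(
        ["protein", "ligand", "temperature_K"], sort=True
    ):
        spectra = []
        for conc, scan in group.groupby("conc_M", sort=True):
            scan = scan.sort_values("wavelength_nm")
            spectra.append(
                EmissionSpectrum(
                    wavelengths=scan["wavelength_nm"].to_numpy(),
                    intensities=scan["intensity"].to_numpy(),
                    quencher_conc=float(conc),
                    temperature=float(temp),
                )
            )
        out.append(TitrationSeries(protein=str(protein), ligand=str(ligand), spectra=tuple(spectra)))
    return out


def write_titration_csv(series_list: list[TitrationSeries], path) -> None:
    """Write TitrationSeries to the long CSV format read by :func:`read_titration_csv`."""
    rows = []
    for ts in series_list:
        for s in ts.spectra:
            for wl, it in zip(s.wavelengths, s.intensities):
                rows.append((ts.protein, ts.ligand, s.temperature, s.quencher_conc, wl, it))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
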