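"""Seeded synthetic-data generators for every pipeline input.

Each generator produces data under the same forward model its analysis
stage assumes, with known ground truth, so that fits can be validated by
round-trip recovery:

- titration spectra under the static-quenching law F(Q) = F0/(1 + Ksv·Q)
  or the saturable enhancement law F(Q) = F0 + (F∞−F0)·Ka·Q/(1+Ka·Q),
  shaped as a single Gaussian emission peak over 300–400 nm;
- paired CETSA melt curves: descending sigmoids with midpoints Tm and
  Tm + ΔTm on a configurable temperature grid;
- differential-expression tables with a planted consensus gene set that
  (and only that) survives strict |log2FC| > 1, p < 0.05 filtering in
  every condition and membership in the disease list;
- random chemicals × metrics tables, optionally with a chemical made
  strictly dominant on every metric.

Noise is multiplicative Gaussian on intensities (fluorescence and
densitometry noise scale with signal), truncated at zero. Identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from bindrisk.cetsa import MeltCurve, write_melt_csv
from bindrisk.spectra import EmissionSpectrum, TitrationSeries, write_titration_csv
from bindrisk.toxpi import MetricSpec, MetricTable

__all__ = [
    "DEFAULT_CONCS",
    "DEFAULT_MELT_TEMPS",
    "SimConfig",
    "gen_deg_tables",
    "gen_enhancement_series",
    "gen_melt_table",
    "gen_metric_table",
    "gen_titration_series",
    "simulate_bundle",
]

#: Default titration series, mol/L (0, 1, 5, 10, 15, 20 µM).
DEFAULT_CONCS = (0.0, 1e-6, 5e-6, 10e-6, 15e-6, 20e-6)

#: Default CETSA temperature gradient, °C.
DEFAULT_MELT_TEMPS = (43.5, 45.0, 46.8, 48.6, 50.4, 52.2, 54.0)


class SimConfig(BaseModel):
    """Shared simulation settings.

    noise_sd is the standard deviation of the multiplicative Gaussian noise
    as a fraction of signal (0 = noiseless); n_points is the number of
    wavelength samples per emission spectrum.
    """

    seed: int = 0
    noise_sd: float = Field(default=0.0, ge=0.0)
    n_points: int = Field(default=101, ge=2)
    temperature_K: float = Field(default=298.0, gt=0.0)

    model_config = {"frozen": True}

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    if noise_sd == 0:
        return values
    return np.clip(values * (1.0 + rng.normal(0.0, noise_sd, size=values.shape)), 0.0, None)


def _gaussian_spectrum(
    wavelengths: np.ndarray, peak: float, lambda_max: float, width: float
) -> np.ndarray:
    return peak * np.exp(-0.5 * ((wavelengths - lambda_max) / width) ** 2)


def _check_concs(concs: Sequence[float]) -> np.ndarray:
    concs = np.asarray(list(concs), dtype=float)
    if concs.size == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    if 0.0 not in concs:
        raise ValueError("concentration list must include 0 (the F0 scan)")
    return concs


def gen_titration_series(
    ksv_true: float,
    f0: float = 1000.0,
    lambda_max: float = 335.0,
    concs: Sequence[float] = DEFAULT_CONCS,
    cfg: SimConfig = SimConfig(),
    peak_width: float = 25.0,
    protein: str = "PR-LBD",
    ligand: str = "SIM",
) -> TitrationSeries:
    """Simulate a static-quenching titration: peak intensity F0/(1 + Ksv·Q).

    Spectra are Gaussian peaks centred at ``lambda_max`` (nm) with standard
    deviation ``peak_width`` on a uniform 300–400 nm grid of
    ``cfg.n_points`` samples; multiplicative noise of ``cfg.noise_sd`` is
    applied per point.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if ksv_true < 0:
        raise ValueError("ksv_true must be non-negative")
    concs = _check_concs(concs)
    rng = cfg.rng()
    wavelengths = np.linspace(300.0, 400.0, cfg.n_points)
    spectra = []
    for q in concs:
        peak = f0 / (1.0 + ksv_true * q)
        intens = _gaussian_spectrum(wavelengths, peak, lambda_max, peak_width)
        intens = _apply_noise(intens, rng, cfg.noise_sd)
        spectra.append(
            EmissionSpectrum(wavelengths, intens, quencher_conc=float(q),
                             temperature=cfg.temperature_K)
        )
    return TitrationSeries(protein=protein, ligand=ligand, spectra=tuple(spectra))


def gen_enhancement_series(
    ka_true: float,
    f0: float = 1000.0,
    f_inf: float = 3000.0,
    concs: Sequence[float] = DEFAULT_CONCS,
    cfg: SimConfig = SimConfig(),
    lambda_max: float = 335.0,
    peak_width: float = 25.0,
    protein: str = "PR-LBD",
    ligand: str = "SIM",
) -> TitrationSeries:
    """Simulate a fluorescence-enhancement titration.

    Peak intensity follows the saturable law
    ``F(Q) = F0 + (F∞−F0)·Ka·Q/(1 + Ka·Q)`` (the algebraic inversion of the
    double-reciprocal enhancement model).
    """
    if f_inf <= f0:
        raise ValueError("f_inf must exceed f0 for an enhancement series")
    if ka_true <= 0:
        raise ValueError("ka_true must be positive")
    concs = _check_concs(concs)
    rng = cfg.rng()
    wavelengths = np.linspace(300.0, 400.0, cfg.n_points)
    spectra = []
    for q in concs:
        kq = ka_true * q
        peak = f0 + (f_inf - f0) * kq / (1.0 + kq)
        intens = _gaussian_spectrum(wavelengths, peak, lambda_max, peak_width)
        intens = _apply_noise(intens, rng, cfg.noise_sd)
        spectra.append(
            EmissionSpectrum(wavelengths, intens, quencher_conc=float(q),
                             temperature=cfg.temperature_K)
        )
    return TitrationSeries(protein=protein, ligand=ligand, spectra=tuple(spectra))


def gen_melt_table(
    tm_control: float,
    delta_tm: float,
    temps: Sequence[float] = DEFAULT_MELT_TEMPS,
    cfg: SimConfig = SimConfig(),
    slope: float = 1.5,
) -> tuple[MeltCurve, MeltCurve]:
    """Simulate paired CETSA melt curves (control, treated).

    Soluble fractions follow descending sigmoids
    ``1/(1 + exp((T − Tm)/slope))`` with midpoints ``tm_control`` and
    ``tm_control + delta_tm``; fractions lie in [0, 1] before noise.
    """
    temps = np.asarray(list(temps), dtype=float)
    if temps.size < 4:
        raise ValueError("melt curves need at least 4 temperatures")
    if not np.all(np.diff(temps) > 0):
        raise ValueError("temperatures must be strictly increasing")
    rng = cfg.rng()
    curves = []
    for sample, tm in (("control", tm_control), ("treated", tm_control + delta_tm)):
        frac = 1.0 / (1.0 + np.exp((temps - tm) / slope))
        frac = _apply_noise(frac, rng, cfg.noise_sd)
        curves.append(MeltCurve(sample=sample, temps=temps, soluble=frac))
    return curves[0], curves[1]


def gen_deg_tables(
    n_genes: int,
    planted_overlap: Sequence[str],
    n_conditions: int = 5,
    cfg: SimConfig = SimConfig(),
) -> tuple[list[pd.DataFrame], set[str]]:
    """Simulate per-condition DEG tables plus a disease gene list.

    The planted genes pass the strict |log2FC| > 1, p < 0.05 filter in
    every condition and appear in the disease list; every background gene
    fails the consensus — either it is absent from the disease list, or it
    misses at least one filter criterion in at least one condition. Hence
    filtering each table and intersecting with the disease list recovers
    exactly ``planted_overlap``.

    Returns ``(tables, disease_genes)`` where each table has columns
    gene, log2fc, pvalue.
    """
    planted = list(dict.fromkeys(planted_overlap))
    if n_genes < len(planted):
        raise ValueError("n_genes must be at least the number of planted genes")
    if n_conditions < 1:
        raise ValueError("need at least one condition")
    rng = cfg.rng()
    n_background = n_genes - len(planted)
    background = [f"G{i:05d}" for i in range(n_background)]
    genes = planted + background

    disease = set(planted)
    # Background failure plan: in_disease background genes must fail the DEG
    # filter in >=1 condition; out-of-disease genes may do anything.
    in_disease = rng.random(n_background) < 0.5
    fail_condition = rng.integers(0, n_conditions, size=n_background)
    disease |= {g for g, ind in zip(background, in_disease) if ind}

    def passing_row(g):
        sign = 1 if rng.random() < 0.5 else -1
        return (g, sign * rng.uniform(1.2, 4.0), rng.uniform(1e-6, 0.04))

    def failing_row(g):
        mode = rng.random()
        if mode < 0.4:  # effect too small
            return (g, rng.uniform(-0.9, 0.9), rng.uniform(1e-6, 0.9))
        if mode < 0.8:  # not significant
            sign = 1 if rng.random() < 0.5 else -1
            return (g, sign * rng.uniform(1.2, 4.0), rng.uniform(0.06, 0.95))
        return (g, rng.uniform(-0.9, 0.9), rng.uniform(0.06, 0.95))

    tables = []
    for cond in range(n_conditions):
        rows = [passing_row(g) for g in planted]
        for j, g in enumerate(background):
            must_fail = in_disease[j] and fail_condition[j] == cond
            if must_fail or rng.random() < 0.5:
                rows.append(failing_row(g))
            else:
                rows.append(passing_row(g))
        tables.append(pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"]))
    assert all(len(t) == len(genes) for t in tables)
    return tables, disease


def gen_metric_table(
    n_chemicals: int,
    dominant: str | None = None,
    cfg: SimConfig = SimConfig(),
    class_sizes: Sequence[int] = (2, 5, 1, 3, 2),
) -> MetricTable:
    """Simulate a chemicals × metrics table for risk integration.

    Metrics are spread over classes of the given sizes (default: the
    13-metric, 5-class layout). A third of the metrics use the negate
    transform (stored as negative raw values) to exercise orientation
    handling. If ``dominant`` is given, that chemical is strictly best on
    every metric after transformation.
    """
    if n_chemicals < 2:
        raise ValueError("min–max scaling needs at least 2 chemicals")
    rng = cfg.rng()
    chems = [f"C{i:02d}" for i in range(n_chemicals)]
    if dominant is not None:
        if dominant not in chems:
            chems[-1] = dominant
    values = {}
    specs = {}
    m = 0
    for ci, size in enumerate(class_sizes):
        cls = f"class_{ci}"
        for _ in range(size):
            name = f"metric_{m:02d}"
            transform = "negate" if m % 3 == 0 else "identity"
            concern = rng.uniform(0.0, 10.0, size=n_chemicals)  # transformed scale
            col = dict(zip(chems, concern))
            if dominant is not None:
                col[dominant] = max(col.values()) + 1.0
            if transform == "negate":
                col = {k: -v for k, v in col.items()}
            values[name] = col
            specs[name] = MetricSpec(class_name=cls, transform=transform)
            m += 1
    df = pd.DataFrame(values).loc[chems]
    return MetricTable(values=df, specs=specs)


def simulate_bundle(out_dir, cfg: SimConfig = SimConfig()) -> dict:
    """Write a complete synthetic input bundle for the pipeline.

    Emits titration spectra (quenching at two temperatures plus one
    enhancement series), melt curves, DEG tables with a planted
    {PGR, AREG} consensus, a disease gene list, and a metric table —
    in the same CSV dialects the analysis stages read — plus a sidecar
    JSON recording the seed and every ground-truth parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = {
        "seed": cfg.seed,
        "noise_sd": cfg.noise_sd,
        "ksv_true_298": 3.57e4,
        "ksv_true_310": 2.94e4,
        "ka_enh_true": 4.16e4,
        "tm_control": 48.0,
        "delta_tm": 1.97,
        "planted_overlap": ["PGR", "AREG"],
    }

    cfg298 = cfg.model_copy(update={"temperature_K": 298.0})
    cfg310 = cfg.model_copy(update={"seed": cfg.seed + 1, "temperature_K": 310.0})
    cfg_enh = cfg.model_copy(update={"seed": cfg.seed + 2})
    series = [
        gen_titration_series(truth["ksv_true_298"], cfg=cfg298, ligand="SIM-QUENCH"),
        gen_titration_series(truth["ksv_true_310"], cfg=cfg310, ligand="SIM-QUENCH"),
        gen_enhancement_series(truth["ka_enh_true"], cfg=cfg_enh, ligand="SIM-ENH"),
    ]
    write_titration_csv(series, out / "titration.csv")

    control, treated = gen_melt_table(
        truth["tm_control"], truth["delta_tm"], cfg=cfg.model_copy(update={"seed": cfg.seed + 3})
    )
    write_melt_csv([control, treated], out / "melt.csv")

    tables, disease = gen_deg_tables(
        200, truth["planted_overlap"], cfg=cfg.model_copy(update={"seed": cfg.seed + 4})
    )
    for i, t in enumerate(tables):
        t.to_csv(out / f"deg_condition_{i}.csv", index=False)
    (out / "disease_genes.txt").write_text("\n".join(sorted(disease)) + "\n")

    table = gen_metric_table(6, cfg=cfg.model_copy(update={"seed": cfg.seed + 5}))
    table.values.rename_axis("chemical").to_csv(out / "metrics.csv")
    spec_json = {
        name: {
            "class": s.class_name,
            "transform": s.transform,
            **({"control_value": s.control_value} if s.control_value is not None else {}),
        }
        for name, s in table.specs.items()
    }
    (out / "metric_config.json").write_text(json.dumps(spec_json, indent=2))

    (out / "simulation.json").write_text(json.dumps(truth, indent=2))
    return truth
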