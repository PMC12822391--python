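"""Pipeline configuration and stage orchestration.

`run_pipeline` executes whichever analysis stages have inputs present,
collects per-stage outputs and failures, and writes per-stage CSVs plus a
combined JSON report. Stages are independent: a failure in one does not
stop the others, but any failure makes the run exit nonzero at the CLI.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, Field

from bindrisk import cetsa, quenching, spectra, tables, thermo, toxpi

logger = logging.getLogger("bindrisk")

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    """Constants, thresholds and weights for a pipeline run.

    Serialized verbatim into every report for provenance.
    """

    tau0_s: float = Field(default=1e-8, gt=0)
    R_J_mol_K: float = Field(default=8.314, gt=0)
    kq_limit: float = Field(default=2e10, gt=0)
    ka_lo: float = Field(default=1e4, gt=0)
    ka_hi: float = Field(default=1e6, gt=0)
    fc_thresh: float = Field(default=1.0, ge=0)
    p_thresh: float = Field(default=0.05, gt=0, le=1)
    shift_nm: float = Field(default=2.0, ge=0)
    ss_tol: float = Field(default=0.5, gt=0)
    energy_tol: float = Field(default=0.01, gt=0)
    toxpi_weights: dict[str, float] | None = None
    control_sample: str = "control"
    seed: int = 0


def _stage_screen(config: RunConfig, inputs: Mapping[str, object], out_dir: Path) -> dict:
    deg_paths = inputs["deg_tables"]
    sets = [
        tables.filter_degs(tables.read_deg_csv(p), config.fc_thresh, config.p_thresh)
        for p in deg_paths
    ]
    all_sets = list(sets)
    if "disease_genes" in inputs:
        all_sets.append(tables.read_gene_list(inputs["disease_genes"]))
    consensus = tables.intersect_gene_sets(all_sets)
    pd.DataFrame({"gene": sorted(consensus)}).to_csv(out_dir / "consensus_genes.csv", index=False)
    return {"n_deg_sets": len(sets), "consensus_genes": sorted(consensus)}


def _stage_fluor(config: RunConfig, inputs: Mapping[str, object], out_dir: Path) -> dict:
    """Per-series spectral characterization and quench/binding fits."""
    all_series = spectra.read_titration_csv(inputs["titration"])
    rows, report = [], {}
    for ts in all_series:
        key = f"{ts.protein}|{ts.ligand}|{ts.temperature:g}K"
        lam0, f0 = spectra.characterize_spectrum(ts.control)
        # Stern–Volmer convention: fixed observation wavelength = control λmax
        series = spectra.extract_intensity_series(ts, lambda_ref=lam0)
        treated_peaks = [spectra.characterize_spectrum(s)[0] for s in ts.spectra[1:]]
        shift = spectra.classify_shift(lam0, treated_peaks[-1], config.shift_nm) if treated_peaks else "none"
        trend = spectra.monotonic_trend(series)
        entry: dict = {"lambda_max_nm": lam0, "f0": f0, "shift": shift, "trend": trend}
        row = {"protein": ts.protein, "ligand": ts.ligand, "T_K": ts.temperature,
               "lambda_max_nm": lam0, "shift": shift, "trend": trend}
        try:
            if trend == "decreasing":
                qf = quenching.stern_volmer_fit(series, ts.temperature, config.tau0_s)
                bf = quenching.double_log_fit(series, ts.temperature)
                entry["quench"] = {"ksv": qf.ksv, "kq": qf.kq, "r2": qf.r2}
                entry["binding"] = {"ka": bf.ka, "n_sites": bf.n_sites, "model": bf.model}
                row.update(Ksv_1e4=qf.ksv_1e4, Kq_1e12=qf.kq_1e12, Ka_1e4=bf.ka_1e4,
                           n_sites=bf.n_sites)
            elif trend == "increasing":
                bf = quenching.enhancement_fit(series, ts.temperature)
                entry["binding"] = {"ka": bf.ka, "f_inf": bf.f_inf, "model": bf.model}
                row.update(Ka_1e4=bf.ka_1e4)
            else:
                entry["binding"] = None
            if "binding" in entry and entry["binding"]:
                entry["ka_in_optimal_range"] = quenching.ka_in_optimal_range(
                    entry["binding"]["ka"], config.ka_lo, config.ka_hi
                )
        except ValueError as err:
            entry["error"] = str(err)
        report[key] = entry
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "fluor_fits.csv", index=False, float_format="%.6g")
    return report


def _stage_thermo(config: RunConfig, inputs: Mapping[str, object], out_dir: Path) -> dict:
    df = pd.read_csv(inputs["binding_constants"])
    ka_by_T: dict[str, dict[float, float]] = {}
    for r in df.itertuples():
        ka_by_T.setdefault(str(r.system), {})[float(r.T_K)] = float(r.ka)
    params = thermo.thermo_table(ka_by_T, R=config.R_J_mol_K)
    frame = thermo.thermo_frame(params, ka_by_T=ka_by_T)
    frame.to_csv(out_dir / "thermo.csv", index=False, float_format="%.6g")
    return {
        system: {
            "dG_by_T": p.dG_by_T,
            "dH": p.dH,
            "dS": p.dS,
            "force_class": p.force_class,
            "spontaneous": p.spontaneous,
        }
        for system, p in params.items()
    }


def _stage_cetsa(config: RunConfig, inputs: Mapping[str, object], out_dir: Path) -> dict:
    curves = cetsa.read_melt_csv(inputs["melt"])
    fits = [cetsa.fit_melt_curve(c) for c in curves]
    frame = cetsa.melt_fits_frame(fits, control=config.control_sample)
    frame.to_csv(out_dir / "melt_fits.csv", index=False, float_format="%.6g")
    ctrl = next((f for f in fits if f.sample == config.control_sample), None)
    return {
        f.sample: {
            "tm50_C": f.tm50,
            "r2": f.r2,
            "delta_tm50_C": cetsa.delta_tm50(f, ctrl) if ctrl else None,
        }
        for f in fits
    }


def _stage_tables(config: RunConfig, inputs: Mapping[str, object], out_dir: Path) -> dict:
    report: dict = {}
    if "mmgbsa" in inputs:
        recs = tables.read_energy_csv(inputs["mmgbsa"])
        report["mmgbsa"] = {
            r.chemical: dict(
                tables.validate_energy_decomposition(r, config.energy_tol)._asdict()
            )
            for r in recs
        }
        ranking = tables.rank_chemicals_by_value([(r.chemical, r.g_binding) for r in recs])
        report["affinity_order"] = [c for c, _ in ranking]
    if "docking" in inputs:
        df = pd.read_csv(inputs["docking"])
        ranking = tables.rank_chemicals_by_value(
            [(str(r.chemical), float(r.score)) for r in df.itertuples()]
        )
        report["docking_order"] = [c for c, _ in ranking]
    if "secondary_structure" in inputs:
        sss = tables.read_secondary_structure_csv(inputs["secondary_structure"])
        by_name = {s.sample: s for s in sss}
        report["ss_valid"] = {
            s.sample: dict(tables.validate_secondary_structure(s, config.ss_tol)._asdict())
            for s in sss
        }
        ctrl = by_name.get(config.control_sample)
        if ctrl is not None:
            report["ss_delta"] = {
                s.sample: {
                    k: {"signed": d[0], "abs": d[1]}
                    for k, d in tables.secondary_structure_delta(s, ctrl).items()
                }
                for s in sss
                if s.sample != ctrl.sample
            }
    return report


def _stage_toxpi(config: RunConfig, inputs: Mapping[str, object], out_dir: Path) -> dict:
    df = pd.read_csv(inputs["metrics"], index_col=0)
    spec_cfg = json.loads(Path(inputs["metric_config"]).read_text())
    specs = {
        name: toxpi.MetricSpec(
            class_name=c["class"],
            transform=c.get("transform", "identity"),
            control_value=c.get("control_value"),
        )
        for name, c in spec_cfg.items()
    }
    table = toxpi.MetricTable(values=df[list(specs)], specs=specs)
    scorer = toxpi.ToxPiScorer(weights=config.toxpi_weights).fit(table)
    out = scorer.transform(table)
    out.rename_axis("chemical").to_csv(out_dir / "toxpi_scores.csv", float_format="%.6g")
    return {
        r.chemical: {"overall": r.overall, "rank": r.rank, "slices": r.slice_scores}
        for r in scorer.results_
    }


_STAGES = {
    "screen": (_stage_screen, ("deg_tables",)),
    "fluor": (_stage_fluor, ("titration",)),
    "thermo": (_stage_thermo, ("binding_constants",)),
    "cetsa": (_stage_cetsa, ("melt",)),
    "tables": (_stage_tables, ()),  # runs if any table input present
    "toxpi": (_stage_toxpi, ("metrics", "metric_config")),
}
_TABLE_INPUTS = ("mmgbsa", "docking", "secondary_structure")


def run_pipeline(config: RunConfig, inputs: Mapping[str, object], out_dir) -> dict:
    """Run every stage whose inputs are present; return the combined report.

    The report echoes the configuration, carries one entry per executed
    stage, and records failures under ``errors``. It is also written to
    ``out_dir/report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.model_dump(), "stages": {}, "errors": {}}
    for name, (fn, required) in _STAGES.items():
        if name == "tables":
            if not any(k in inputs for k in _TABLE_INPUTS):
                continue
        elif not all(k in inputs for k in required):
            continue
        logger.info("running stage %s", name)
        try:
            report["stages"][name] = fn(config, inputs, out)
        except Exception as err:  # stage isolation is the contract here
            logger.error("stage %s failed: %s", name, err)
            report["errors"][name] = str(err)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
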