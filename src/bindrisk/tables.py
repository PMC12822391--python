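"""Validation and summarization of tabular screening inputs.

This module handles the bookkeeping stages of the pipeline that consume
tables produced elsewhere (docking scores, MM/GBSA energy decompositions,
CD secondary-structure fractions, differential-expression tables) plus a
couple of small assay-derived quantities:

- MM/GBSA additivity: the binding free energy must equal the sum of its
  van der Waals, electrostatic, polar- and nonpolar-solvation components.
- Secondary-structure closure: the four CD fractions must sum to 100%.
- Affinity ranking: chemicals ordered by docking score or ΔG (more
  negative = stronger binding).
- DEG biomarker screen: strict |log2FC| > 1 and p < 0.05 filtering followed
  by multi-set intersection with a disease gene list.
- Tumor volume V = L·W²/2 and treated/control fold changes.

Energy units in this module are kcal/mol (the docking/MM/GBSA convention);
the thermodynamics module stays in kJ/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "DEGRecord",
    "DockingRecord",
    "EnergyDecomposition",
    "SecondaryStructure",
    "ValidationResult",
    "filter_degs",
    "fold_change_vs_control",
    "intersect_gene_sets",
    "rank_chemicals_by_value",
    "read_deg_csv",
    "read_energy_csv",
    "read_gene_list",
    "read_secondary_structure_csv",
    "secondary_structure_delta",
    "tumor_volume",
    "validate_energy_decomposition",
    "validate_secondary_structure",
]

_SS_ELEMENTS = ("alpha_helix", "beta_sheet", "beta_turn", "random_coil")


class ValidationResult(NamedTuple):
    """Outcome of an additivity/closure check: ``ok`` plus the deviation."""

    ok: bool
    delta: float


@dataclass(frozen=True)
class EnergyDecomposition:
    """One MM/GBSA row: energy components and total, kcal/mol.

    ``sems`` optionally carries the standard errors of the mean for each
    component in the same order (vdw, ele, sol_polar, sol_nonpolar, total).
    """

    chemical: str
    e_vdw: float
    e_ele: float
    g_sol_polar: float
    g_sol_nonpolar: float
    g_binding: float
    sems: tuple[float, ...] | None = None

    @property
    def component_sum(self) -> float:
        return self.e_vdw + self.e_ele + self.g_sol_polar + self.g_sol_nonpolar


@dataclass(frozen=True)
class SecondaryStructure:
    """CD-derived secondary-structure fractions (%) for one sample."""

    sample: str
    alpha_helix: float
    beta_sheet: float
    beta_turn: float
    random_coil: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _SS_ELEMENTS}


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result."""

    gene: str
    log2fc: float
    p: float


@dataclass(frozen=True)
class DockingRecord:
    """One chemical's docking score (kcal/mol scale, more negative = stronger)."""

    chemical: str
    score: float


def validate_energy_decomposition(
    rec: EnergyDecomposition, tol: float = 0.01
) -> ValidationResult:
    """Check that the MM/GBSA total equals the sum of its four components.

    ``ok`` iff |ΔE_vdW + ΔE_ele + ΔG_sol-polar + ΔG_sol-nonpolar −
    ΔG_binding| ≤ tol (kcal/mol). The signed deviation is returned either way.
    The boundary is inclusive up to float representation error, so a row off
    by exactly one printing ulp (e.g. 0.01 at tol 0.01) validates.
    """
    delta = rec.component_sum - rec.g_binding
    return ValidationResult(ok=abs(delta) <= tol * (1 + 1e-9), delta=delta)


def validate_secondary_structure(ss: SecondaryStructure, tol: float = 0.5) -> ValidationResult:
    """Check that the four secondary-structure fractions sum to 100 ± tol %."""
    total = sum(ss.as_dict().values())
    return ValidationResult(ok=abs(total - 100.0) <= tol, delta=total)


def secondary_structure_delta(
    treated: SecondaryStructure, control: SecondaryStructure
) -> dict[str, tuple[float, float]]:
    """Per-element (signed Δ, |Δ|) of treated vs control fractions."""
    t, c = treated.as_dict(), control.as_dict()
    return {k: (t[k] - c[k], abs(t[k] - c[k])) for k in _SS_ELEMENTS}


def rank_chemicals_by_value(
    records: Iterable[tuple[str, float]], ascending: bool = True
) -> list[tuple[str, float]]:
    """Order chemicals by value; rank 1 is first in the returned list.

    ``ascending=True`` puts the most negative value first (the convention
    for binding energies, where more negative = stronger). Ties are broken
    by chemical name, lexicographically. Duplicate chemicals raise.
    """
    records = list(records)
    names = [c for c, _ in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chemical names")
    return sorted(records, key=lambda cv: (cv[1] if ascending else -cv[1], cv[0]))


def filter_degs(
    records: Iterable[DEGRecord], fc_thresh: float = 1.0, p_thresh: float = 0.05
) -> set[str]:
    """Differentially expressed genes under strict thresholds.

    Keeps genes with |log2FC| > fc_thresh AND p < p_thresh (both strict).
    Records with p outside (0, 1] are malformed and rejected with a single
    warning carrying the count.
    """
    kept: set[str] = set()
    n_bad = 0
    for rec in records:
        if not 0 < rec.p <= 1:
            n_bad += 1
            continue
        if abs(rec.log2fc) > fc_thresh and rec.p < p_thresh:
            kept.add(rec.gene)
    if n_bad:
        warnings.warn(f"rejected {n_bad} DEG record(s) with p outside (0, 1]", stacklevel=2)
    return kept


def intersect_gene_sets(sets: Sequence[set[str]]) -> set[str]:
    """Genes present in every input set (case-sensitive exact symbols)."""
    if len(sets) < 2:
        raise ValueError("intersection requires at least 2 gene sets")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-approximation tumor volume V = L·W²/2, mm³."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("length and width must be positive")
    if width_mm > length_mm:
        warnings.warn(
            "width exceeds length; computing V = L*W^2/2 with the given values", stacklevel=2
        )
    return length_mm * width_mm**2 / 2.0


def fold_change_vs_control(treated: float, control: float) -> float:
    """Treated/control ratio (relative migration rate, band fold, ...)."""
    if control <= 0:
        raise ValueError("control value must be positive")
    return treated / control


# ---------------------------------------------------------------------------
# CSV readers


def read_deg_csv(path) -> list[DEGRecord]:
    """Read a 3-column DEG table (gene, log2fc, pvalue)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        gene_c, fc_c = cols["gene"], cols["log2fc"]
        p_c = cols.get("pvalue") or cols["p"]
    except KeyError as err:
        raise ValueError(f"DEG CSV missing column: {err}") from err
    return [
        DEGRecord(gene=str(r[gene_c]), log2fc=float(r[fc_c]), p=float(r[p_c]))
        for _, r in df.iterrows()
    ]


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_energy_csv(path) -> list[EnergyDecomposition]:
    """Read an MM/GBSA component table.

    Expected columns: chemical, e_vdw, e_ele, g_sol_polar, g_sol_nonpolar,
    g_binding.
    """
    df = pd.read_csv(path)
    required = ["chemical", "e_vdw", "e_ele", "g_sol_polar", "g_sol_nonpolar", "g_binding"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"energy CSV missing columns: {missing}")
    return [
        EnergyDecomposition(
            chemical=str(r.chemical),
            e_vdw=float(r.e_vdw),
            e_ele=float(r.e_ele),
            g_sol_polar=float(r.g_sol_polar),
            g_sol_nonpolar=float(r.g_sol_nonpolar),
            g_binding=float(r.g_binding),
        )
        for r in df.itertuples()
    ]


def read_secondary_structure_csv(path) -> list[SecondaryStructure]:
    """Read a CD fraction table (sample, alpha_helix, beta_sheet, beta_turn, random_coil)."""
    df = pd.read_csv(path)
    required = ["sample", *_SS_ELEMENTS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"secondary-structure CSV missing columns: {missing}")
    return [
        SecondaryStructure(
            sample=str(r.sample),
            alpha_helix=float(r.alpha_helix),
            beta_sheet=float(r.beta_sheet),
            beta_turn=float(r.beta_turn),
            random_coil=float(r.random_coil),
        )
        for r in df.itertuples()
    ]
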