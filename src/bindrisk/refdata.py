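"""Bundled reference measurements for six bisphenol analogs and PR-LBD.

Literature-reported endpoints for BPA and five of its substitutes (BPS,
BPE, BPF, BPB, BPAF) interacting with the ligand-binding domain of the
progesterone receptor. These values power the worked examples, the
consistency checks, and the packaged risk-ranking fixture:

- AutoDock Vina docking scores (kcal/mol-scale; more negative = stronger);
- MM/GBSA binding free-energy decompositions (kcal/mol);
- Stern–Volmer quenching constants Ksv and association constants Ka at
  298 K and 310 K (reported in the conventional ×10⁴ L/mol scale);
- CD secondary-structure fractions (%) of the free protein (control, 0:1
  ligand:protein) and of each 10:1 complex;
- assorted assay endpoints (ΔTm50, migration/invasion/expression folds)
  used by the integrated risk fixture. Slots whose source values were
  reported only graphically are synthetic placeholders and are marked
  ``verified=False`` in the fixture.
"""

from __future__ import annotations

import pandas as pd

from bindrisk.tables import EnergyDecomposition, SecondaryStructure
from bindrisk.toxpi import MetricSpec, MetricTable

__all__ = [
    "BISPHENOLS",
    "DOCKING_SCORES",
    "ENERGY_DECOMPOSITIONS",
    "KA_BY_CHEMICAL",
    "KSV_BY_CHEMICAL",
    "SECONDARY_STRUCTURE",
    "SS_CONTROL",
    "reference_metric_table",
]

#: The six analogs, in the customary listing order.
BISPHENOLS = ("BPA", "BPS", "BPE", "BPF", "BPB", "BPAF")

#: AutoDock Vina docking scores against PR-LBD.
DOCKING_SCORES: dict[str, float] = {
    "BPA": -7.8,
    "BPS": -7.6,
    "BPE": -7.6,
    "BPF": -7.6,
    "BPB": -7.9,
    "BPAF": -8.6,
}

#: MM/GBSA decompositions (kcal/mol): vdW, electrostatic, polar solvation,
#: nonpolar solvation, total. SEMs in the same order.
ENERGY_DECOMPOSITIONS: tuple[EnergyDecomposition, ...] = (
    EnergyDecomposition("BPA", -33.24, -15.18, 23.50, -3.40, -28.32,
                        sems=(0.25, 0.32, 0.20, 0.01, 0.27)),
    EnergyDecomposition("BPAF", -36.91, -14.92, 26.61, -4.16, -29.38,
                        sems=(0.27, 0.26, 0.18, 0.01, 0.24)),
    EnergyDecomposition("BPE", -29.80, -18.47, 26.43, -3.28, -25.11,
                        sems=(0.22, 0.40, 0.28, 0.01, 0.25)),
    EnergyDecomposition("BPB", -35.50, -13.42, 23.29, -3.64, -29.27,
                        sems=(0.29, 0.38, 0.29, 0.01, 0.27)),
    EnergyDecomposition("BPS", -34.37, -24.10, 40.04, -3.33, -21.76,
                        sems=(0.23, 0.56, 0.47, 0.01, 0.27)),
    EnergyDecomposition("BPF", -32.40, -17.49, 26.29, -3.39, -26.98,
                        sems=(0.27, 0.25, 0.17, 0.01, 0.28)),
)

#: Stern–Volmer constants Ksv (L/mol) per chemical and temperature (K).
#: Chemical/temperature combinations with no quenching response are absent.
KSV_BY_CHEMICAL: dict[str, dict[float, float]] = {
    "BPA": {298.0: 0.76e4, 310.0: 0.66e4},
    "BPS": {298.0: 3.57e4, 310.0: 2.94e4},
    "BPE": {310.0: 1.06e4},
    "BPF": {298.0: 0.51e4},
    "BPB": {298.0: 1.01e4, 310.0: 0.38e4},
    "BPAF": {310.0: 0.58e4},
}

#: Association constants Ka (L/mol) per chemical and temperature (K).
#: BPAF at 298 K derives from the fluorescence-enhancement model (no Ksv).
KA_BY_CHEMICAL: dict[str, dict[float, float]] = {
    "BPA": {298.0: 0.98e4, 310.0: 3.67e4},
    "BPS": {298.0: 0.54e4, 310.0: 3.30e4},
    "BPE": {310.0: 2.30e4},
    "BPF": {298.0: 1.41e4},
    "BPB": {298.0: 10.51e4, 310.0: 2.90e4},
    "BPAF": {298.0: 4.16e4, 310.0: 2.79e4},
}

#: CD fractions of the ligand-free protein (the 0:1 control scan).
SS_CONTROL = SecondaryStructure("control", 9.39, 44.64, 14.48, 31.55)

#: CD fractions of each 10:1 ligand:protein complex.
SECONDARY_STRUCTURE: tuple[SecondaryStructure, ...] = (
    SecondaryStructure("BPA", 9.15, 44.24, 14.22, 32.39),
    SecondaryStructure("BPS", 8.91, 46.03, 14.37, 30.69),
    SecondaryStructure("BPE", 7.88, 48.59, 14.13, 29.39),
    SecondaryStructure("BPF", 8.38, 52.89, 15.11, 23.62),
    SecondaryStructure("BPB", 10.60, 55.50, 16.75, 17.15),
    SecondaryStructure("BPAF", 2.40, 65.47, 20.93, 11.20),
)

# Risk-fixture endpoints. Text-reported values are verified; slots whose
# sources were graphical-only (or, for BPE's 298 K ΔG, imputed from the
# 310 K measurement) are synthetic placeholders flagged verified=False.
_DG_298 = {  # −RT ln Ka at 298 K, kJ/mol; BPE imputed from its 310 K value
    "BPA": -22.769, "BPS": -21.293, "BPE": -25.885, "BPF": -23.671,
    "BPB": -28.647, "BPAF": -26.351,
}
_DTM50 = {  # °C; BPA and BPAF text-reported, BPS/BPF "moderate", rest placeholder
    "BPA": 1.97, "BPS": 1.2, "BPE": 0.8, "BPF": 1.0, "BPB": 1.4, "BPAF": 1.89,
}
_CCK8 = {  # proliferation fold vs control at 1e-10 M (graphical only)
    "BPA": 1.2, "BPS": 1.15, "BPE": 1.2, "BPF": 1.25, "BPB": 1.2, "BPAF": 1.3,
}
_MIGRATION = {  # wound-healing relative migration rate vs control
    "BPA": 1.8, "BPS": 2.00, "BPE": 2.54, "BPF": 1.9, "BPB": 1.7, "BPAF": 2.50,
}
_INVASION = {  # transwell invasion fold vs control
    "BPA": 1.4, "BPS": 1.3, "BPE": 1.35, "BPF": 1.5, "BPB": 1.45, "BPAF": 2.06,
}
_MRNA = {  # PGR mRNA fold vs control (BPF/BPAF text-reported, rest ~null)
    "BPA": 1.3, "BPS": 1.1, "BPE": 1.2, "BPF": 4.12, "BPB": 1.4, "BPAF": 3.55,
}
_PROTEIN = {  # PR protein fold vs control (BPAF text-reported, rest ~null)
    "BPA": 1.1, "BPS": 1.0, "BPE": 1.05, "BPF": 1.2, "BPB": 1.15, "BPAF": 1.88,
}


def reference_metric_table() -> MetricTable:
    """The packaged 13-metric / 5-class risk-integration fixture.

    Classes and membership: in-silico binding (docking score, MM/GBSA ΔG),
    chemical analysis (ΔG at 298 K and the four CD fractions as absolute
    differences from the control), in-vitro binding (ΔTm50), cytotoxicity
    (CCK-8 proliferation, migration, invasion folds), and receptor
    expression (mRNA and protein folds). Binding energies are negated so
    that stronger binding means higher concern; each class carries a 20%
    weight by default (uniform over five classes).

    Only the claim that BPAF ranks first is supported by verified slots
    alone; several other slots are unverified placeholders (see module
    docstring), so full six-way orderings from this fixture are indicative
    only.
    """
    ss = {s.sample: s for s in SECONDARY_STRUCTURE}
    ctrl = SS_CONTROL
    values = pd.DataFrame(
        {
            "docking_score": DOCKING_SCORES,
            "mmgbsa_dG": {e.chemical: e.g_binding for e in ENERGY_DECOMPOSITIONS},
            "dG_298": _DG_298,
            "alpha_helix": {c: ss[c].alpha_helix for c in BISPHENOLS},
            "beta_sheet": {c: ss[c].beta_sheet for c in BISPHENOLS},
            "beta_turn": {c: ss[c].beta_turn for c in BISPHENOLS},
            "random_coil": {c: ss[c].random_coil for c in BISPHENOLS},
            "delta_tm50": _DTM50,
            "cck8_fold": _CCK8,
            "migration_fold": _MIGRATION,
            "invasion_fold": _INVASION,
            "mrna_fold": _MRNA,
            "protein_fold": _PROTEIN,
        }
    ).loc[list(BISPHENOLS)]
    specs = {
        "docking_score": MetricSpec("in_silico_binding", "negate"),
        "mmgbsa_dG": MetricSpec("in_silico_binding", "negate"),
        "dG_298": MetricSpec("chemical_analysis", "negate", verified=False),
        "alpha_helix": MetricSpec(
            "chemical_analysis", "absdiff_vs_control", control_value=ctrl.alpha_helix
        ),
        "beta_sheet": MetricSpec(
            "chemical_analysis", "absdiff_vs_control", control_value=ctrl.beta_sheet
        ),
        "beta_turn": MetricSpec(
            "chemical_analysis", "absdiff_vs_control", control_value=ctrl.beta_turn
        ),
        "random_coil": MetricSpec(
            "chemical_analysis", "absdiff_vs_control", control_value=ctrl.random_coil
        ),
        "delta_tm50": MetricSpec("in_vitro_binding", verified=False),
        "cck8_fold": MetricSpec("cytotoxicity", verified=False),
        "migration_fold": MetricSpec("cytotoxicity", verified=False),
        "invasion_fold": MetricSpec("cytotoxicity", verified=False),
        "mrna_fold": MetricSpec("pr_expression", verified=False),
        "protein_fold": MetricSpec("pr_expression", verified=False),
    }
    return MetricTable(values=values, specs=specs)
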