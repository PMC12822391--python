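"""Binding thermodynamics from association constants at two temperatures.

Given association constants Ka measured at two temperatures, the van't Hoff
relation gives the binding enthalpy (assumed temperature-independent over
the narrow interval):

    ln(k2/k1) = ΔH · (1/T1 − 1/T2) / R

the Gibbs free energy of binding at each temperature is

    ΔG(T) = −R·T·ln(Ka)

and the entropy change follows from ΔG = ΔH − T·ΔS:

    ΔS = (ΔH − ΔG)/T

All energies are in kJ/mol (ΔS in kJ/(mol·K)); R defaults to 8.314
J/(mol·K). The sign pattern of (ΔH, ΔS) classifies the dominant
noncovalent binding force under the Ross–Subramanian convention:
ΔH>0, ΔS>0 hydrophobic; ΔH<0, ΔS<0 van der Waals + hydrogen bonding;
ΔH<0, ΔS>0 electrostatic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

__all__ = [
    "GAS_CONSTANT",
    "ThermoParams",
    "classify_binding_forces",
    "entropy_change",
    "gibbs_free_energy",
    "thermo_table",
    "thermo_frame",
    "vant_hoff_enthalpy",
]

#: Molar gas constant, J/(mol·K).
GAS_CONSTANT = 8.314

ForceClass = Literal["hydrophobic", "vdw_hbond", "electrostatic", "mixed"]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic summary of one protein–ligand system.

    ``dH`` (kJ/mol) and ``dS`` (kJ/(mol·K)) are present only when Ka was
    available at two temperatures; ``dG_by_T`` maps each temperature (K) to
    ΔG (kJ/mol). ``spontaneous`` is True when every available ΔG < 0.
    """

    system: str
    dG_by_T: dict[float, float] = field(default_factory=dict)
    dH: float | None = None
    dS: float | None = None
    force_class: ForceClass | None = None
    spontaneous: bool = False
    dS_reference_T: float | None = None


def vant_hoff_enthalpy(
    k1: float, T1: float, k2: float, T2: float, R: float = GAS_CONSTANT
) -> float:
    """Two-point van't Hoff binding enthalpy, kJ/mol.

    Exact closed-form solution (no regression):
    ``ΔH = R·ln(k2/k1)/(1/T1 − 1/T2)``.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("binding constants must be positive")
    if T1 <= 0 or T2 <= 0:
        raise ValueError("temperatures must be positive (K)")
    if T1 == T2:
        raise ValueError("van't Hoff enthalpy requires two distinct temperatures")
    return R * math.log(k2 / k1) / (1.0 / T1 - 1.0 / T2) / 1000.0


def gibbs_free_energy(ka: float, T: float, R: float = GAS_CONSTANT) -> float:
    """Gibbs free energy of binding ΔG = −R·T·ln(Ka), kJ/mol."""
    if ka <= 0:
        raise ValueError("ka must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return -R * T * math.log(ka) / 1000.0


def entropy_change(dH: float, dG: float, T: float) -> float:
    """Entropy change ΔS = (ΔH − ΔG)/T, kJ/(mol·K)."""
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return (dH - dG) / T


def classify_binding_forces(dH: float, dS: float, tol: float = 1e-6) -> ForceClass:
    """Dominant noncovalent force from the signs of ΔH and ΔS.

    Ross–Subramanian sign rules; a ΔH or ΔS within ``tol`` of zero is
    ambiguous and maps to "mixed".
    """
    if abs(dH) <= tol or abs(dS) <= tol:
        return "mixed"
    if dH > 0 and dS > 0:
        return "hydrophobic"
    if dH < 0 and dS < 0:
        return "vdw_hbond"
    if dH < 0 and dS > 0:
        return "electrostatic"
    return "mixed"  # dH > 0, dS < 0: never spontaneous at any T


def thermo_table(
    ka_by_T: Mapping[str, Mapping[float, float]], R: float = GAS_CONSTANT
) -> dict[str, ThermoParams]:
    """Compute ΔG/ΔH/ΔS per system from Ka values at one or two temperatures.

    ΔG is computed at every temperature with a Ka. ΔH and ΔS require exactly
    two temperatures; with only one they are left absent (None), matching
    the usual incomplete-table situation. ΔS is reported at the lower
    temperature (both temperatures agree to well within printing precision
    for a temperature-independent ΔH).
    """
    out: dict[str, ThermoParams] = {}
    for system, by_T in ka_by_T.items():
        temps = sorted(by_T)
        if not temps:
            out[system] = ThermoParams(system=system)
            continue
        dG = {float(T): gibbs_free_energy(by_T[T], T, R=R) for T in temps}
        dH = dS = force = ref_T = None
        if len(temps) == 2:
            T1, T2 = temps
            dH = vant_hoff_enthalpy(by_T[T1], T1, by_T[T2], T2, R=R)
            dS = entropy_change(dH, dG[T1], T1)
            force = classify_binding_forces(dH, dS)
            ref_T = float(T1)
        out[system] = ThermoParams(
            system=system,
            dG_by_T=dG,
            dH=dH,
            dS=dS,
            force_class=force,
            spontaneous=all(v < 0 for v in dG.values()),
            dS_reference_T=ref_T,
        )
    return out


def thermo_frame(
    params: Mapping[str, ThermoParams],
    quench_fits: Mapping[str, Mapping[float, "object"]] | None = None,
    ka_by_T: Mapping[str, Mapping[float, float]] | None = None,
) -> pd.DataFrame:
    """Flatten ThermoParams into a report table (one row per system × T).

    Columns follow the conventional layout: system, T_K, Ksv_1e4, Kq_1e12,
    Ka_1e4, dH_kJ_mol, dG_kJ_mol, dS_kJ_mol_K. ΔH/ΔS appear on the
    lower-temperature row only; absent cells are NaN (written as empty
    strings in CSV output).
    """
    rows = []
    for system, p in params.items():
        temps = sorted(p.dG_by_T)
        for i, T in enumerate(temps):
            qf = (quench_fits or {}).get(system, {}).get(T)
            ka = (ka_by_T or {}).get(system, {}).get(T)
            rows.append(
                {
                    "system": system,
                    "T_K": T,
                    "Ksv_1e4": getattr(qf, "ksv_1e4", float("nan")),
                    "Kq_1e12": getattr(qf, "kq_1e12", float("nan")),
                    "Ka_1e4": ka / 1e4 if ka is not None else float("nan"),
                    "dH_kJ_mol": p.dH if (i == 0 and p.dH is not None) else float("nan"),
                    "dG_kJ_mol": p.dG_by_T[T],
                    "dS_kJ_mol_K": p.dS if (i == 0 and p.dS is not None) else float("nan"),
                }
            )
    return pd.DataFrame(rows)
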