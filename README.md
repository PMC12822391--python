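# bindrisk

Receptor-binding analysis and integrated risk ranking for bisphenol analogs.

Bisphenol A (BPA) is being replaced by structural analogs — BPAF, BPB, BPE,
BPF and BPS — whose endocrine-disrupting potential is largely
uncharacterized. One route to breast-cancer risk runs through the
progesterone receptor (PR): an analog that binds the PR ligand-binding
domain (PR-LBD) can perturb its conformation, stabilize it in cells, and
upregulate PR-driven proliferation. `bindrisk` implements the quantitative
chain that turns the underlying bench measurements into a single
per-chemical risk ranking:

1. **Fluorescence titration** (`bindrisk.spectra`, `bindrisk.quenching`) —
   from emission spectra at increasing ligand concentration: the
   Stern–Volmer quenching constant
   `F0/F = 1 + Ksv[Q] = 1 + kq·τ0·[Q]` (τ0 = 10⁻⁸ s), mechanism
   classification (static vs dynamic from the temperature dependence of Ksv
   and the diffusion limit kq ≈ 2×10¹⁰ L mol⁻¹ s⁻¹), and association
   constants from either the double-log plot
   `log10((F0−F)/F) = log10(Ka) + n·log10[Q]` (quenching) or the
   double-reciprocal enhancement model
   `(F∞−F0)/(Fx−F0) = 1 + 1/(Ka[Q])` (enhancement).
2. **Binding thermodynamics** (`bindrisk.thermo`) — two-point van't Hoff
   enthalpy `ln(k2/k1) = ΔH(1/T1 − 1/T2)/R`, `ΔG = −RT ln Ka`,
   `ΔS = (ΔH − ΔG)/T`, and Ross–Subramanian force classification from the
   signs of ΔH and ΔS.
3. **CETSA melt curves** (`bindrisk.cetsa`) — descending Boltzmann sigmoid
   fits of soluble protein vs temperature, the melting midpoint Tm50, and
   ligand-induced shifts ΔTm50.
4. **Table validation and the biomarker screen** (`bindrisk.tables`) —
   MM/GBSA component additivity, CD secondary-structure closure, affinity
   ranking, the strict |log2FC| > 1 & p < 0.05 DEG filter and multi-set
   intersection, and small assay helpers (tumor volume `V = L·W²/2`, fold
   changes).
5. **ToxPi risk integration** (`bindrisk.toxpi`) — 13 metrics in 5
   equally-weighted classes, oriented so larger = higher concern, min–max
   scaled across chemicals, averaged within classes and weighted into one
   score per chemical.

Curve fits are scikit-learn-style estimators (`SternVolmerRegressor`,
`MeltCurveRegressor`, `ToxPiScorer`, ...) that compose with sklearn
tooling; plain functions returning result dataclasses wrap them.
`bindrisk.synthetic` generates every pipeline input with known ground
truth, and `bindrisk.refdata` bundles reference measurements for the six
analogs. A `bindrisk` CLI exposes each stage (`simulate`, `screen`,
`fluor`, `thermo`, `cetsa`, `tables`, `toxpi`, `run`).

## Worked example

```python
from bindrisk.thermo import thermo_table
from bindrisk.refdata import KA_BY_CHEMICAL, reference_metric_table
from bindrisk.toxpi import ToxPiScorer

params = thermo_table(KA_BY_CHEMICAL)
bpa = params["BPA"]
print(f"BPA: dH = {bpa.dH:.3f} kJ/mol, dG(298) = {bpa.dG_by_T[298.0]:.3f} kJ/mol, "
      f"dS = {bpa.dS:.3f} kJ/(mol K), force = {bpa.force_class}")

scorer = ToxPiScorer().fit(reference_metric_table())
print(scorer.transform(reference_metric_table())[["overall", "rank"]]
      .sort_values("rank").round(3))
```

prints

```
BPA: dH = 84.510 kJ/mol, dG(298) = -22.769 kJ/mol, dS = 0.360 kJ/(mol K), force = hydrophobic
      overall  rank
BPAF    0.952     1
BPB     0.401     2
BPA     0.372     3
BPF     0.354     4
BPE     0.190     5
BPS     0.096     6
```

BPA binding is endothermic and entropy-driven (ΔH > 0, ΔS > 0 —
hydrophobic), yet spontaneous (ΔG < 0) at both temperatures. In the
integrated ranking the fluorinated analog BPAF carries the highest risk
score by a wide margin: it leads in silico binding (docking −8.6,
MM/GBSA −29.38 kcal/mol), causes the largest conformational change
(β-sheet +20.83%, random coil −20.35% vs the free protein), and dominates
the cytotoxicity and receptor-expression endpoints. Positions 2–6 lean on
fixture slots reconstructed from graphical data (marked unverified in
`refdata`) and are indicative only.

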