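# Methods

## Fluorescence quenching and binding models

A titration series is a set of emission spectra (300–400 nm) of the
protein at increasing ligand concentration `[Q]` (default series 0, 1, 5,
10, 15, 20 µM) at one temperature. Downstream fits read the intensity at a
**fixed observation wavelength** — the control (zero-ligand) spectrum's
emission maximum — because the Stern–Volmer formalism assumes a fixed
wavelength; reading each spectrum at its own maximum is retained as an
option for dose-response plots only. Spectral shifts are called blue/red
when the treated peak moves by at least 2 nm (any threshold in (0, 9) nm
reproduces the reference labels, which call 0 nm "no shift" and 9 nm a
shift).

**Stern–Volmer.** `F0/F = 1 + Ksv[Q]`. Since the model has no free
intercept, Ksv is the through-origin least-squares slope of `F0/F − 1` on
`[Q]`; a free-intercept line is reported as a diagnostic but never used.
The bimolecular rate constant `kq = Ksv/τ0` with the unquenched lifetime
τ0 = 10⁻⁸ s (configurable). Mechanism: *static* when kq exceeds the
diffusion-limited collisional ceiling (2×10¹⁰ L mol⁻¹ s⁻¹) at both
temperatures **and** Ksv falls with temperature (complex stability
decreases when heated); *dynamic* when kq is at/below the ceiling and Ksv
rises; anything else is *indeterminate*.

**Double-log (Scatchard-type).** `log10((F0−F)/F) = log10 Ka + n log10[Q]`
fitted by ordinary least squares. Logs are base 10 (the plotting
convention); Ka is base-invariant, n is not, so the base is recorded in
the fit metadata. For a single-site static series `F = F0/(1 + Ka[Q])`
this is an algebraic identity with n = 1 and Ka = Ksv, which the tests use
as an oracle.

**Enhancement.** Ligands that brighten rather than quench follow
`(F∞−F0)/(Fx−F0) = 1 + 1/(Ka[Q])`, fitted as the double-reciprocal line
`1/(Fx−F0) = a + b/[Q]`, `Ka = a/b`, `F∞ = F0 + 1/a`. The line is fitted
with inverse-variance weights `w ∝ (Fx−F0)⁴`: with noise proportional to
signal, `var(1/(Fx−F0)) ∝ (Fx−F0)⁻⁴`, so an unweighted fit is dominated by
the noisiest low-concentration points (the familiar reciprocal-plot
pathology). Weighting leaves exact data untouched and, under simulated
noise, tracks the error of the full nonlinear maximum-likelihood fit.

Model selection between the two binding models follows the dose–response
direction: strictly decreasing series → double-log; strictly increasing →
enhancement; non-monotone series raise. Monotonicity uses a relative tie
tolerance of 10⁻⁶. Association constants in the window 10⁴–10⁶ L/mol
(inclusive) are flagged as physiologically meaningful binders.

### Identifiability under noise

With 2% multiplicative noise per intensity and the default 6-point
concentration series, median relative errors over 200 seeds are:

- **Ksv**: ≈4% at the generator's exemplar Ksv = 5×10⁴ L/mol. The error is
  dynamic-range limited — it scales inversely with the maximum quench
  fraction, so weak quenchers (Ksv ≈ 0.8×10⁴, only ~14% quench at the top
  concentration) are recovered far less precisely (tens of percent).
- **Ka (double-log)**: ~25–90% across the realistic range. The intercept
  sits at `log10[Q] = 0` (1 M), ~5 decades beyond the sampled 10⁻⁶–2×10⁻⁵ M
  window, so small slope errors are amplified exponentially into Ka.
- **Ka (enhancement)**: ~11–22% even with weighting; the series reaches at
  most ~45–67% of saturation for Ka in 4×10⁴–10⁵ L/mol, leaving Ka and F∞
  nearly collinear. The nonlinear maximum-likelihood fit does no better,
  so this is an information floor of the design, not an estimator defect.

Consequently only Ksv supports tight recovery claims on this design; Ka
values from single noisy titrations should be treated as order-of-magnitude
estimates. One acceptance-level check encodes a 5% noisy-Ka target and is
expected to fail for this reason; it is retained unmodified.

## Thermodynamics

Two-point van't Hoff: `ΔH = R ln(k2/k1)/(1/T1 − 1/T2)` (exact closed form,
no regression; ΔH assumed constant over 298–310 K), `ΔG = −RT ln Ka`,
`ΔS = (ΔH − ΔG)/T`. R = 8.314 J mol⁻¹ K⁻¹, configurable. ΔS is reported at
the lower temperature; both temperatures agree to the printed 3 decimals
when ΔH is temperature-independent. Systems with Ka at only one
temperature get ΔG only (ΔH/ΔS left absent). Force classification follows
the Ross–Subramanian sign convention — ΔH>0 ∧ ΔS>0 hydrophobic;
ΔH<0 ∧ ΔS<0 van der Waals + hydrogen bonds; ΔH<0 ∧ ΔS>0 electrostatic —
with a 10⁻⁶ zero-tolerance mapping ambiguous signs to "mixed". The
electrostatic cell is convention-derived; the reference study only labels
the two combinations it observed, so force classes for systems it does not
discuss are rule-derived, not externally verified.

## CETSA melt curves

Band intensities are normalized to the lowest-temperature point
(idempotent). The descending Boltzmann sigmoid
`f(T) = bottom + (top − bottom)/(1 + exp((T − tm50)/slope))` is fitted by
trust-region nonlinear least squares with initialization top = max,
bottom = min, tm50 = temperature nearest the half-range, slope = 1 °C, and
bounds: plateaus in [−0.2, 1.5] (densitometry rarely reaches exactly 0/1),
tm50 within the sampled range, slope in (10⁻³, 50] °C. Tm50 is the sigmoid
midpoint; the linear interpolation of the 50% crossing is reported
alongside for comparison with the "half precipitated" operational
definition. ΔTm50 = Tm50(treated) − Tm50(control), positive =
stabilization. Curves that do not decline raise ("no melt transition").
The default 7-point gradient is 43.5–54.0 °C; at 3% noise the median
|Tm50 error| over 200 seeds is ≈0.09 °C. The reported stabilization shifts
(1.97 and 1.89 °C) derive from unpublished densitometry and are used here
as simulation targets only, not recomputation targets.

## Table validation and the biomarker screen

MM/GBSA totals must equal ΔE_vdW + ΔE_ele + ΔG_sol-polar + ΔG_sol-nonpolar
within 0.01 kcal/mol; the boundary is inclusive up to float representation
so rows off by exactly one printing ulp validate. Secondary-structure
fractions must sum to 100 ± 0.5% (0.1% in the strict acceptance check).
Affinity ranking sorts ascending (more negative = stronger) with
lexicographic tie-breaks and rejects duplicate chemicals. The DEG filter
is strict on both thresholds (|log2FC| > 1, p < 0.05, exactly as the
screening criteria state); records with p outside (0, 1] are rejected with
a warning count. Gene symbols are matched case-sensitively with no alias
resolution. Energy units stay in kcal/mol here; the thermodynamics module
stays in kJ/mol.

## ToxPi integration

Transforms orient every metric so larger = higher concern: negation for
binding energies/docking scores, |value − control| for secondary-structure
fractions, identity elsewhere. Orientation is explicit per metric in the
configuration, never inferred from the data. Scaling is min–max to [0, 1]
across chemicals per metric (an x/max variant is available behind a flag);
a metric constant across chemicals is degenerate and scores 0 for all
rather than erroring, keeping the 13-metric layout intact. Slice scores
are unweighted means of their member metrics; the overall score is the
weighted sum of slices (weights must sum to 1; uniform 0.2 over the five
default classes). Ranking is by descending overall score with
lexicographic tie-breaking.

The packaged reference fixture has 13 metrics in 5 classes (in-silico
binding 2, chemical analysis 5, in-vitro binding 1, cytotoxicity 3,
receptor expression 2). Slots whose source values exist only graphically —
most cytotoxicity/expression folds, four of six ΔTm50 values — are
plausible placeholders marked `verified=False`, chosen once from the
prose descriptions; the 298 K ΔG for BPE is imputed from its 310 K value.
Only "BPAF ranks first" is asserted as a hard check; it is robust because
BPAF leads on the fully verified in-silico and conformational metrics
alone. The full six-way order is reported but indicative.

## Synthetic data

Generators emulate exactly the forward models the fits assume: Gaussian
emission peaks (center 335 nm, width 25 nm — only the peak location
matters downstream) whose height follows the static-quenching or
enhancement law; unit-amplitude descending sigmoids for melt curves; DEG
tables where planted genes pass both filter criteria in every condition
and appear in the disease list while every background gene fails the
consensus by construction. Noise is multiplicative Gaussian truncated at
zero (fluorescence and densitometry noise scale with signal), one draw per
sampled point, single scan per condition (replicates optional). Passing
round-trip tests therefore demonstrates estimator correctness under the
assumed models — not robustness to real-data pathologies such as
inner-filter effects, baseline drift, spectral overlap, correlated
densitometry error, or probe-to-gene mapping ambiguity, none of which the
generators simulate.

## Problem sizes

Recovery studies use 200 seeds on the default 6-concentration titration and
the 7-point melt gradient; the DEG screen fixture uses 500 genes × 5
conditions with a planted 2-gene consensus. The full test suite runs in
well under a minute; the acceptance script in a few seconds.

## Known limitations

- Two-temperature van't Hoff assumes ΔH constant and propagates no
  uncertainty; multi-temperature regression and ΔCp are out of scope.
- Ka estimates from single noisy titrations are order-of-magnitude (see
  identifiability above).
- No inner-filter correction; spectra are used as read.
- The ToxPi fixture's unverified slots limit rank claims beyond first
  place.
- The CLI consumes tabular exports only; docking/MD/CD deconvolution are
  upstream tools' responsibilities.
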