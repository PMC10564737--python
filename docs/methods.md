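# Methods

This note records the models implemented in `covalkit`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not demonstrate.

## Equilibrium probe binding

A fluorescent probe L binds protein E 1:1. Anisotropy A mixes the free and
bound endpoint values linearly in the bound probe fraction
F_b = (A_f − A)/(A_f − A_b). Because the probe (10 nM by default) and its
dissociation constant K_L (77.56 nM reference value) are within an order
of magnitude, probe depletion is never negligible; the forward model is
therefore the exact quadratic solution of the 1:1 mass balance everywhere,
not the hyperbola (the two agree within 1% only when the probe is below
K_L/100). `fit_probe_KL` estimates (K_L, A_f, A_b) jointly by least
squares unless a calibration is supplied.

Noise can push measured F_b outside [0, 1]; values are clamped for
downstream use, with the raw value and a per-point flag retained.

### Competition and the IC50 → K_i conversion

Competition titrations are fitted with a 4-parameter logistic in
concentration (hill slope free, initialized from data quartiles; a zero
point is allowed and maps exactly to the top asymptote). The IC50 is
converted to the inhibitor dissociation constant K_i with the exact
three-species equilibrium accounting standard for FP competition assays
(the Nikolovska-Coleska convention): at 50% inhibition the bound probe is
half its no-inhibitor value; free probe, free protein and bound inhibitor
follow from the equilibrium relations, and K_i = [P]·[I]/[PI] at that
point. The conversion is exact given an exact IC50 — the test suite
verifies that the converted K_i makes the independently solved equilibrium
reproduce half-maximal probe binding to 1e-6 — and it reduces to
K_i ≈ IC50 when both probe and protein are far below K_L. K_i never
exceeds the IC50.

The three-species equilibrium itself is solved as a single monotone
scalar equation in free protein (Brent's method, machine-precision
tolerances); a log-parametrized multi-dimensional root solve serves as the
independent oracle in tests.

## Covalent kinetics

The competition mechanism is

    E + P <=> EP          (probe, kon_P/koff_P, K_L = koff_P/kon_P)
    E + I <=> EI -> E–I   (inhibitor, K_i = koff_I/kon_I; k_inact)

`simulate_mechanism` integrates the mass-action ODEs (LSODA, rtol 1e-8,
configurable) with free species eliminated by conservation, so the mass
balances hold to rounding at every step. With k_inact = 0 the long-time
state matches the closed-form competitive equilibrium to 1e-6 (tested).
An optional pre-equilibrated start places the system at the reversible
equilibrium at t = 0, emulating a time course that begins after mixing
and equilibration — the same assumption the intercept-based analysis
makes.

### From time courses to k_obs and k_inact/K_I

The published analysis takes an early, approximately linear window of
F_b(t): intercept F_b0, slope, and k_obs = −slope/F_b0. Two numerical
facts shape the defaults:

* The window keeps points with F_b ≥ 0.7·F_b0 (≤ 30% decay), at least 4.
* The raw −slope/intercept ratio **underestimates** a first-order rate by
  roughly half the fractional decay spanned (−15% at a 30% window, −9%
  even at 20%). The default therefore applies a curvature correction:
  k_obs is the root of "OLS ratio of exp(−kt) on the same grid = measured
  ratio", which is exact for first-order decay and costs one scalar root
  solve. The raw ratio is always reported alongside. A log-linear fit
  (`method="log"`) is also available; it is exact on clean exponentials
  but undefined once noise drives F_b ≤ 0, so the corrected linear fit is
  the default.

k_obs values are fitted to k_obs = k_inact·[I]/(K_I + [I]) by weighted
least squares, weights from the per-concentration linearization errors.
Concentrations whose F_b0 falls below 5× the linear-fit residual noise
are excluded from the rate fit (the probe is already fully displaced at
t = 0, so the curve carries no rate information — including such points
only injects noise); their F_b0 still informs the IC50. The efficiency
k_inact/K_I carries a delta-method standard error. In the low-
concentration regime ([I] ≪ K_I) `fit_efficiency_linear` gives the
zero-intercept slope (the model has no intercept; a free-intercept refit
is reported as a diagnostic only). Note the concentration-weighted slope
approaches k_inact/(K_I + I_max), so the linear regime should satisfy
I_max ≲ K_I/10 for percent-level accuracy; a warning fires above
0.2·K_I when K_I is known.

All fits nondimensionalize concentrations and rates before optimization:
molar-scale parameters (~1e-6) sit far from unit scale and stall
trust-region steps otherwise.

K_i at t = 0 chains the F_b0 dose-response through the 4PL fit and the
equilibrium conversion above. Modification time courses (intact MS) are
fitted to f(t) = 1 − e^(−kt), pseudo-first-order with unit plateau, with
t95 = ln(20)/k.

## Thermal shift

DSF melting curves (1 °C grid, 25–95 °C) are lightly smoothed
(Savitzky-Golay, 5-point window, order 2 — a 1 °C grid with instrument
noise cannot be differentiated raw), differentiated on the grid, and T_m
taken at the steepest fluorescence rise with quadratic interpolation
around the grid extremum. A derivative peak that sits at the boundary or
does not stand out from the baseline slope is flagged unreliable rather
than reported.

CETSA luminescence curves (16-point 40–72 °C grid) are normalized to the
lowest measured temperature (percent stabilized; a warning fires if that
is not the nominal 40 °C start), then fitted with a Boltzmann sigmoid
f(T) = bottom + (top − bottom)/(1 + exp((T_agg − T)/s)); the sign of s is
auto-detected from the curve direction (luminescence decays, fluorescence
rises) and recorded. Replicates are fitted per curve and summarized as
mean T_agg per condition; ΔT_agg against the vehicle control is fitted to
a log-logistic dose-response (hill fixed at 1 by default, free
optionally) for the cellular EC50. Boltzmann and derivative midpoints
agree within one grid step on clean sigmoids (tested).

## Chemistry arithmetic

ΔG = RT ln(K_D/1 M) with R = 1.98720425×10⁻³ kcal/(mol·K), natural log,
standard state 1 M; T defaults to 298 K (the calorimetry temperature),
which reproduces the published ΔG columns to two decimals. −TΔS = ΔG − ΔH.
LE = −ΔG/NHA with NHA a user-supplied heavy-atom count (no structure
parsing is in scope).

GSH reactivity: C(t) = C₀e^(−k_e·t), T½ = ln2/k_e, with k_e > 0 denoting
decay (instrument software sometimes prints the same rate negative — the
identity T½·k_e = ln 2 holds by construction here). An increasing series
is flagged non-reactive with T½ = ∞.

Composition strings use the signed-count dialect of proteomics search
engines: `C(26)H(25)N(3)O(7)FPSe(-1)S` — element symbol, optional signed
parenthesized count, bare symbol = 1. Negative counts encode placeholder
bookkeeping (a cysteine modelled as selenocysteine during the search:
the Se(−1)S pair converts it back). Atomic masses come from the NIST
table shipped with pyteomics (provenance recorded in reports);
monoisotopic uses principal-isotope masses, average uses
abundance-weighted weights. The reference covalent adduct —
a chloroacetamide ligand C26H26ClFN3O7P minus HCl after thiol attack —
computes to 541.14 Da monoisotopic / 541.47 Da average; the published
rounded figure (542 Da) does not state its convention, so both are
reported.

## Synthetic data: what it emulates and what it does not

Generators draw from the forward model each analysis assumes and add
Gaussian noise **on the instrument observable** (anisotropy,
luminescence, fluorescence, peak-area ratio) — noise arises at the
detector, not on derived quantities. Same spec + seed ⇒ byte-identical
CSV. Every stochastic routine takes an explicit seed; there is no global
random state.

Default designs are the study conditions: 10 nM probe; 3-fold protein
dilutions from 50 µM (saturation); 2-fold inhibitor dilutions from 50 µM
plus a vehicle control against 50 nM protein, sampled every 2 min for
1 h in technical triplicate (covalent FP); 16-point 40–72 °C CETSA grid
in triplicate; 1 °C 25–95 °C DSF ramp; GSH sampling over 2 h. The
protein and inhibitor concentrations printed in the source protocol
(300 µM protein, 100 mM inhibitor top dose) are mutually inconsistent
with the nanomolar probe and micromolar affinities and were evidently
unit typos; the defaults above are internally consistent and recorded in
every truth file. Anisotropy noise (0.3 mA on a 100 mA window) is a
typical plate-reader figure.

The covalent FP generator uses the analysis model itself as the forward
model: F_b0(I) from the reversible three-species equilibrium at K_i, and
exponential decay at k_obs(I) from the saturation equation at K_I. This
is deliberate: the reference parameter set (K_I = 3.6 µM vs
K_i = 1.1 µM) implies, under mass action, koff_I ≈ k_inact — a
slow-binding regime in which no intercept-based analysis is unbiased, and
in which the "reversible equilibrium at t = 0" premise of the published
procedure cannot hold exactly. The phenomenological generator makes the
estimator chain testable against exact ground truth; the mass-action
simulator is exercised separately, in a rapid-equilibrium regime with the
protein well below K_L, where the full pipeline recovers the mechanistic
parameters within 15% (the residual bias being genuine assay physics:
probe competition inflates the apparent K_I by ≈(1 + [L]/K_L), and a
probe readout saturating in protein compresses the apparent rate).
Passing these tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to slow-binding kinetics,
instrument drift, or non-Gaussian outliers, none of which are emulated.

## Known limitations

* No tight-binding (Morrison) correction: E_total ≈ K_I regimes are
  flagged by the pseudo-first-order guard (I < 10·E), not modelled.
* The IC50 → K_i conversion assumes the reversible equilibrium is
  established at t = 0 and that the 4PL IC50 equals the true
  half-displacement concentration; the equilibrium competition curve is
  not exactly 4PL, contributing ~1–2% error at the defaults.
* DSF curves are modelled as clean sigmoids; real dye curves show
  post-transition decay, which the derivative method tolerates but the
  generator does not emulate.
* NHA counts are user inputs; no SMILES/structure handling.
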