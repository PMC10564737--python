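# covalkit

Quantitative characterization of covalent ligands for phosphotyrosine-
recognition (SH2) domains — built around the assay panel used to profile a
covalent SOCS2 inhibitor, and usable for any target with the same readouts.

A covalent inhibitor binds its target reversibly and then reacts
irreversibly:

```
E + I  <=>[K_i]  E·I  --k_inact-->  E–I
```

Its potency is not a single affinity but the pair (k_inact, K_I) — the
maximal inactivation rate and the concentration of half-maximal rate — and
the headline efficiency **k_inact/K_I** (M⁻¹ s⁻¹). `covalkit` implements
the full inference chain from plate-reader data:

* **Equilibrium probe binding** (`covalkit.binding`) — anisotropy to bound
  fraction, F_b = (A_f − A)/(A_f − A_b); exact 1:1 binding with ligand
  depletion (the binding quadratic) for probe K_L; 4-parameter-logistic
  IC50; IC50 → K_i by exact competitive-equilibrium accounting
  (Nikolovska-Coleska convention).
* **Covalent kinetics** (`covalkit.covalent`) — mass-action simulation of
  the probe/inhibitor competition mechanism; early-window linearization of
  F_b(t) to (F_b0, k_obs) with first-order curvature correction; the
  saturation fit k_obs = k_inact·[I]/(K_I + [I]); the low-concentration
  linear-regime slope; reversible K_i at t = 0; pseudo-first-order
  modification kinetics from intact MS.
* **Thermal shift** (`covalkit.thermal`) — DSF T_m by first-derivative
  extremum; CETSA percent-stabilized normalization, Boltzmann T_agg and
  ΔT_agg dose-response EC50.
* **Chemistry arithmetic** (`covalkit.chem`) — ΔG = RT ln K_D, −TΔS =
  ΔG − ΔH, ligand efficiency LE = −RT ln(K_D)/NHA; glutathione-reactivity
  half-life (C(t) = C₀e^(−k·t), T½ = ln2/k); elemental-composition parsing
  (MaxQuant signed-count dialect) and monoisotopic/average mass.
* **Synthetic data** (`covalkit.synthesize`) — seeded generators for every
  assay layout, with ground-truth records for estimator validation, plus
  fixture tables of published reference values.
* **CLI** (`covalkit.cli`) — `covalkit simulate | fit-probe | fit-covalent |
  fit-ic50 | fit-gsh | fit-melt | fit-cetsa | fit-modification | masscalc |
  thermo | demo`, all emitting self-describing JSON reports.

## Worked example

Generate a noisy covalent competition FP dataset at the reference ground
truth (k_inact = 2.1×10⁻⁴ s⁻¹, K_I = 3.6 µM, K_i = 1.1 µM, probe
K_L = 77.56 nM) and recover the parameters:

```sh
covalkit simulate --assay covalent_fp --seed 1 --out cov.csv
covalkit fit-covalent --input cov.csv --probe 1e-8 --protein 5e-8 \
    --kl 7.756e-8 --af 20 --ab 120 --out fit.json
```

`fit.json` then contains (seed 1):

```
"k_inact":    1.903e-4      # s^-1, true value 2.1e-4
"K_I":        3.197e-6      # M, true value 3.6e-6
"efficiency": 59.5          # k_inact/K_I in M^-1 s^-1, true 58.3
"Ki_t0":      1.107e-6      # M, reversible K_i at t = 0, true 1.1e-6
```

i.e. the rate parameters come back within ~10% under triplicate
plate-reader noise and the efficiency within a few percent. Desk
arithmetic is one call each:

```pycon
>>> from covalkit import ligand_efficiency, delta_g, composition_mass, parse_composition
>>> ligand_efficiency(190e-6, 17)       # free phosphotyrosine, kcal/mol/NHA
0.2985
>>> delta_g(0.38e-6)                    # kcal/mol at 298 K
-8.754
>>> composition_mass(parse_composition("C(26)H(25)N(3)O(7)FP"), "average")
541.47
```

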