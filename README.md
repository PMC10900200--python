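# glycobalance

Quantifying weak aromatic interactions — CH/π, cation/π, anion/π — from
dynamic covalent **molecular balances**. A carbohydrate-derived amine and a
2-arylpropionaldehyde condense in situ into a *Z*/*E* enamine pair in which
only the *Z* isomer can fold into an intramolecular aromatic contact. The
*Z*/*E* population ratio, read out over time from HSQC cross-peak
integrals, therefore reports the free energy of that contact. This package
implements the complete analysis chain behind such experiments, exercised
end-to-end on synthetic data.

## The model

The chemistry is a network of three reversible reactions with six
effective rate constants (units M and min; acid catalyst and water are not
explicit species):

```
A + L  <=(k1)=(k-1)=>   I          bimolecular adduct formation
I      <=(k1Z)=(k-1Z)=> Z          Z-enamine branch
I      <=(k1E)=(k-1E)=> E          E-enamine branch
```

Two closed forms anchor the analysis: by detailed balance the equilibrium
ratio is `Keq = (k1Z·k−1E)/(k1E·k−1Z)`, and the t → 0⁺ ratio is `k1Z/k1E`
(both products drain the same intermediate). The observed ratio curve is
fitted with

```
[Z]/[E](t) = Keq + A·exp(−t/c)          (or a two-exponential sum)
```

whose asymptote estimates `Keq` and whose t = 0 value `Keq + ΣAᵢ`
estimates `k1Z/k1E`. Free energies follow as `ΔG_Z/E = −RT ln Keq`
(kcal/mol, 293 K), and differences isolate the physics:

* `ΔG_int   = ΔG_Z/E(model) − ΔG_Z/E(R0)` — interaction free energy of the
  aromatic complex (R0 carries no interacting fragment);
* `ΔG_charge`, `ΔG_pol` — a charged or CH-polarized model minus its
  neutral isostere.

Keq uncertainties follow a tiered scheme (5% / 7.5% / 10% / 15% relative
for Keq in 1–5 / 5–10 / 10–15 / >15, reciprocals by symmetry), converted
to free energy half-widths via `RT ln(1 + f)` and combined in quadrature
for differences. Solvent dependence is analyzed by ordinary least squares
of `ΔG_charge` / `ΔG_pol` against the Hunter hydrogen-bond α/β parameters
(supplied as a user CSV), and complex classes are ranked per solvent.

## Worked example

Simulate a balance, dress it as a noisy HSQC integral series, and fit it:

```python
import numpy as np
import glycobalance as gb

rates = gb.RateConstants(k1=10.0, k_m1=0.002, k1Z=0.02, k_m1Z=0.002,
                         k1E=0.01, k_m1E=0.004)
gb.closed_form_ratios(rates)        # (4.0, 2.0): Keq and k1Z/k1E

design = gb.ExperimentDesign(duration=3000.0,
                             sampling=np.arange(0.0, 3001.0, 30.0),
                             noise_rel_sd=0.03, seed=42)
series, truth = gb.generate_experiment(rates, design)
result = gb.select_fit(gb.build_ratio_series(series))
print(result.summary())
```

```
Z/E ratio exponential fit
=========================================
model:            Keq + sum_i A_i exp(-t/c_i), 1 exp
observations:     100
converged:        True
residual SSE:     2.43444
AICc:             -365.3
-----------------------------------------
Keq               4.00744 +/- 0.0257
A1               -2.32595 +/- 0.0847
c1 (min)          477.462 +/- 31.9
Z/E at t=0        1.68149
```

With 3% multiplicative noise on each integral, the fitted asymptote
recovers the true `Keq = 4.0` to 0.2%; the extrapolated t = 0 ratio
(truth 2.0) is a rougher, qualitative estimate of the kinetic preference.
Thermodynamics of the dichloromethane showcase (measured Keq values 0.45
for R0, 1.3 for the neutral isostere R6, 8.0 for the trimethylammonium
model M6):

```python
m6 = gb.free_energy_record(8.0, 293.0, balance_id="M6", solvent="DCM")
r6 = gb.free_energy_record(1.3, 293.0, balance_id="R6", solvent="DCM")
r0 = gb.free_energy_record(0.45, 293.0, balance_id="R0", solvent="DCM")
dg_int = gb.interaction_free_energy(m6, r0)
dg_charge = gb.isostere_contribution(m6, r6, "charge")
```

```
dG_ZE(M6)     = -1.211 +/- 0.042 kcal/mol
dG_int(M6)    = -1.676 +/- 0.051 kcal/mol
dG_charge(M6) = -1.058 +/- 0.051 kcal/mol
charge share  = 63.1 %
```

The cation/π complex is worth −1.68 kcal/mol, and the charge supplies
about two thirds of that stability.

A `glycobalance` CLI exposes the stages (`simulate`, `synth`, `fit`,
`thermo`, `trends`, `run`); `glycobalance run --config study.yaml --outdir
out/` executes the whole pipeline from a balance registry (YAML) plus
kinetic CSVs and writes fit, free-energy, class-mean, hierarchy and trend
tables as TSV.

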