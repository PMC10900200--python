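# Methods

## The reaction network and its observables

The balance chemistry is modelled as mass action over five species — free
amine `A`, free aldehyde `L`, a lumped hemiaminal/imine intermediate `I`,
and the two enamines `Z` and `E` — connected by a reversible bimolecular
condensation and two reversible unimolecular branch reactions. Lumping the
hemiaminal and imine into one intermediate and omitting water release and
the acid catalyst are deliberate: the catalyst load does not shift the
observed Z/E ratios, so the six rate constants are effective constants at
fixed catalyst concentration. Units are M and minutes; concentrations
default to the assay loads of 1 mM amine and 0.5 mM aldehyde.

Integration uses `scipy.integrate.solve_ivp` (LSODA, analytic Jacobian)
with `rtol = 1e-10`, `atol = 1e-13` M. These tight defaults are what keep
both mass balances below 1e-9 relative error when rate constants span four
orders of magnitude; probing the t → 0⁺ limit (where concentrations are
of order 1e-14 M) requires passing a smaller `atol`, which the tests do.
Integrator failure raises with the offending parameters; sub-tolerance
negative concentrations are clipped to zero, anything worse raises.

Two closed forms are used as oracles against the integrator and as ground
truth for synthetic data: the detailed-balance equilibrium ratio
`Keq = (k1Z·k−1E)/(k1E·k−1Z)` and the initial ratio `k1Z/k1E`. The
equilibrium composition itself has a closed form (a quadratic in the
converted amount), which also supplies the Jacobian eigenvalues used to
size integration horizons.

Kinetic regimes are labelled from `ρ = k1·a0/(k1Z + k1E)`: fast
pre-equilibrium for ρ ≥ 10, slow bimolecular for ρ ≤ 0.1, intermediate
between. The order-of-magnitude thresholds separate the two limiting
behaviours cleanly; nothing downstream is sensitive to their exact values.

## Ratio-curve fitting

The observable is the ratio of the Z and E cross-peak integrals, which
share one proportionality constant to concentration. Points where the E
integral falls below a configurable fraction (default 2%) of its maximum
are discarded before division — early points sit at the noise floor and
their ratio is meaningless. The curve is fitted by unweighted nonlinear
least squares (Levenberg–Marquardt via lmfit) to
`Keq + Σ Aᵢ exp(−t/cᵢ)` with one or two terms; no weighting scheme is
applied because the noise on the ratio is approximately homoscedastic in
relative terms and the curves span at most a factor of a few. Initial
guesses assume a monotone-ish curve (asymptote from the last point,
amplitude from first-minus-last, timescale a third of the span); on
non-convergence the fit restarts up to five times from deterministic
perturbations and keeps the best solution, returning an honestly flagged
result rather than fabricated parameters.

Two identifiability constraints bound the timescales: `cᵢ` may not exceed
the observation span (a slower component is indistinguishable from a
constant and lets a second exponential absorb the asymptote, collapsing
Keq toward zero — a degeneracy we observed directly), and may not fall
below half of the first positive sample time (a faster component is
constrained by no data point and explodes the extrapolated t = 0 value).
Model order is selected by corrected AIC: the two-exponential fit is kept
only if it improves AICc by more than 2, is converged, and did not
collapse its asymptote below 5% of the late observations. A
single-exponential fit whose residual is already at numerical noise
short-circuits the comparison (the AICc of a perfect fit is undefined).

The fitted t = 0 value `Keq + ΣAᵢ` estimates the kinetic preference
`k1Z/k1E`. It is an extrapolation below the first sample and should be
read as semi-quantitative; the tests hold it to 15% only in the fast
pre-equilibrium regime, where the ratio curve is well resolved.

## Free energies and the error model

`ΔG_Z/E = −RT ln Keq` with `R = 1.98720e-3 kcal·mol⁻¹·K⁻¹` and a default
`T = 293 K` (20 °C). Differential quantities are plain subtractions —
`ΔG_int` against the bare reference R0, `ΔG_charge`/`ΔG_pol` against the
declared neutral isostere — validated for matching solvent and
temperature, with isostere pairings checked against the balance registry.

Keq uncertainty follows the tiered scheme established from duplicate
experiments: 5% relative for Keq in [1, 5), 7.5% in [5, 10), 10% in
[10, 15), 15% above. Tiers are implemented as lower-inclusive half-open
intervals (the prose ranges overlap at their endpoints); Keq below 1 takes
the tier of its reciprocal, since −RT ln Keq is antisymmetric in ln Keq
and a ratio and its inverse are measured with the same relative precision.
A relative error `f` maps to the free-energy half-width `RT ln(1 + f)` —
at 293 K the four tiers give at most 0.028, 0.042, 0.056 and 0.081
kcal/mol, inside the stated ±0.03/0.05/0.08/0.10 bounds. Errors of all
differential quantities combine in quadrature.

Class summaries report mean ± sample standard deviation per complex class
(singletons without a deviation), ordered most stabilizing first. Solvent
trends are ordinary least squares of a contribution against the Hunter α
or β parameter, via statsmodels; the regression is unweighted, and a
degenerate flat response is reported as slope 0 with R² = 0. Hunter
parameters are user-supplied configuration — they are literature values
and are never hard-coded.

## The synthetic-data generator

The generator emulates the study's experiments, not generic kinetics. A
draw proceeds in three steps. (1) Shape: bimolecular equilibrium constant
log-uniform in [1000, 10000] M⁻¹, both branch equilibrium constants
log-uniform in [1, 20], regime ratio ρ log-uniform in [10, 300] (fast) or
below 0.1 (slow), and kinetic preference `k1Z/k1E = u·Keq` with `u`
log-uniform in [1, 4] — the stabler isomer also forms faster, with initial
ratios exceeding equilibrium ratios by the modest factors seen in the
measured series. (2) Realism rejection: the closed-form equilibrium must
show near-complete aldehyde consumption (≥ 80%) and only marginal
intermediate accumulation (≤ 5% of the aldehyde load), mirroring what the
NMR assays observe. Note that in the fast pre-equilibrium regime the
*transient* intermediate level is necessarily large (tens of % of the
aldehyde) whenever the bimolecular constant sits in the thousands of M⁻¹
at millimolar loads — that is arithmetic, not a modelling choice — so the
marginal-accumulation constraint is applied to the settled composition.
(3) Timescale: all six constants are rescaled (an exact time-axis
rescaling that changes nothing dimensionless) so the simulated
equilibration time falls uniformly in 300–600 min. Equilibration is
defined strictly — Z, E *and* the Z/E ratio within 2% of their
asymptotes — because "apparent equilibrium" in the assays means the
monitored ratio visibly flattens; in the fast regime the ratio
equilibrates more slowly than the concentrations and a looser definition
truncates the very curve being measured. For slow-regime draws the feed
rate is additionally kept an order of magnitude below the *reverse*
branch rates: the slow scenario is "slow bimolecular step followed by
faster intramolecular processes", and the ratio can only pre-equilibrate
ahead of the conversion if the reverse interconversion is fast too.

Observables are built as `signal = scale·concentration·(1 + ε)` with ε
i.i.d. Gaussian, truncated at −0.9, default 3% relative — multiplicative
because HSQC volumes scale with concentration and relative error is the
natural NMR noise model. The 3% default is a calibration choice (raw
integral noise is not reported anywhere); it lands fitted-Keq errors
within the first error tier. Default sampling is every 15 min for
600 min (sequential HSQC cadence); a discontinuous preset (dense first
two hours, then daily) mirrors slow polar-solvent monitoring. Ground
truth travels in a separate structure/sidecar so recovery tests stay
blind. Every draw is reproducible from its integer seed; per-experiment
seeds are spawned from the dataset seed.

What the generator does *not* emulate: spectral effects (peak overlap,
baseline, relaxation weighting), chemical side reactions (the aldol
pathway suppressed experimentally by the α-methyl aldehydes), catalyst
depletion, or solvent-dependent kinetics beyond the user choosing
different designs per solvent. Passing recovery tests therefore show the
*analysis chain* is unbiased and correctly calibrated under the stated
noise model, not that real spectra of arbitrary quality will fit equally
well.

## Numerical choices and problem sizes

The exponential model is an approximation to the network's true ratio
curve (a ratio of three-mode exponential mixtures); the residual model
error of the noiseless chain is at the 0.1–0.3% level in Keq, which is why
noiseless round-trip tests assert 1% on Keq while exact-model
self-consistency is held to 1e-6. Recovery statistics in the tests use
200 synthetic experiments (about ten seconds of compute), the
simulator-vs-closed-form oracle 100 rate sets, and the regime property 8
slow-regime sets with 1500-point trajectories; these sizes give stable
pass/fail margins while keeping the suite quick. The recovery thresholds
(≥ 90% of fitted Keq within the truth's error tier; ≥ 80% of fast-regime
initial ratios within 15%) pass with margin across seeds — typical
measured rates are 96–98% and 87–93%.

## Known limitations

* Rate constants are effective at fixed catalyst load; no temperature
  dependence, no stochastic (Gillespie) simulation.
* The initial-ratio estimator degrades when the first sample lands after
  most of the fast relaxation; the generator's default cadence avoids
  this, real discontinuous monitoring may not.
* Per-balance experimental free energies of the original study (and hence
  its class means such as −1.64 ± 0.28 kcal/mol for tetra-alkyl-ammonium
  complexes) live in supplementary tables not shipped here; the class
  summary and trend machinery is therefore validated on synthetic studies
  with designed effects, not against those numbers.
* Solvent trend fits are unweighted; with three to five solvents per
  regression the R² values are sensitive to single points, exactly as in
  the original analysis.
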