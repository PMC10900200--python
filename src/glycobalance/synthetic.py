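"""Seeded synthetic HSQC-integral time series for the balance network.

The generator emulates the structure of the real experiments: a 1 mM amine
and 0.5 mM aldehyde reacting through the three-reaction network, monitored
as Z and E cross-peak integrals on a regular (or deliberately irregular)
time grid, with multiplicative noise on each integral.  Rate constants are
drawn from the documented simulation ranges — bimolecular equilibrium
constants log-uniform in [1000, 10000] M^-1, branch equilibrium constants
log-uniform in [1, 20] — and their absolute magnitudes are rescaled so that
equilibration lands in the 300–600 min window typical of the
dichloromethane assays.  Sampled sets are additionally screened so the
equilibrium composition matches the empirical picture: near-complete
aldehyde consumption and only marginal accumulation of the
hemiaminal/imine intermediate.

Every draw is reproducible from its integer seed, and each generated series
carries its ground truth (rates, equilibrium and initial Z/E ratios) in a
separate structure so recovery tests can stay blind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import (
    RateConstants,
    Trajectory,
    classify_regime,
    closed_form_ratios,
    equilibrium_state,
    relaxation_rates,
    simulate_network,
    time_to_asymptote,
)
from .ratiofit import KineticSeries

__all__ = [
    "ExperimentDesign",
    "GroundTruth",
    "regular_sampling",
    "discontinuous_sampling",
    "sample_rate_constants",
    "generate_experiment",
    "generate_dataset",
]

#: documented sampling ranges for the network's equilibrium constants
BIMOLECULAR_K_RANGE = (1000.0, 10000.0)  # M^-1
BRANCH_K_RANGE = (1.0, 20.0)  # dimensionless
#: target window for the equilibration time of the default design, min
EQUILIBRATION_RANGE = (300.0, 600.0)


def regular_sampling(duration: float = 600.0, interval: float = 15.0) -> np.ndarray:
    """Regular grid mirroring sequential HSQC acquisition (every 15 min)."""
    return np.arange(0.0, duration + 1e-9, interval)


def discontinuous_sampling(duration: float = 7200.0) -> np.ndarray:
    """Irregular grid mirroring discontinuous monitoring over days.

    Dense coverage of the first two hours (every 10 min) followed by one
    point per day, as used for slowly equilibrating polar media.
    """
    dense = np.arange(0.0, 120.0 + 1e-9, 10.0)
    sparse = np.arange(1440.0, duration + 1e-9, 1440.0)
    return np.concatenate([dense, sparse])


@dataclass(frozen=True)
class ExperimentDesign:
    """Conditions of one synthetic kinetic experiment.

    Defaults are the study conditions: 1 mM amine, 0.5 mM aldehyde,
    600 min monitored every 15 min, 3% multiplicative noise on each
    integral.  ``signal_scale`` converts concentration to the arbitrary
    integral unit shared by both cross-peaks.
    """

    a0: float = 1e-3
    l0: float = 5e-4
    duration: float = 600.0
    sampling: np.ndarray | None = None
    noise_rel_sd: float = 0.03
    signal_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_rel_sd < 0:
            raise ValueError("noise_rel_sd must be >= 0")
        if self.sampling is not None:
            grid = np.asarray(self.sampling, dtype=float)
            if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
                raise ValueError("sampling must be a strictly increasing 1-D grid")
            if grid[0] < 0 or grid[-1] > self.duration + 1e-9:
                raise ValueError("sampling must lie within [0, duration]")
            object.__setattr__(self, "sampling", grid)

    @property
    def grid(self) -> np.ndarray:
        if self.sampling is not None:
            return self.sampling
        return regular_sampling(self.duration)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden truth behind one synthetic series, for recovery tests."""

    rates: RateConstants
    keq_ze: float
    initial_ratio: float
    regime: str
    seed: int


class UnattainableDesignError(RuntimeError):
    """No rate set satisfying the requested regime/timescale was found."""


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _equilibration_time(rates: RateConstants, a0: float, l0: float) -> float:
    """Time for the enamine concentrations *and* their ratio to settle.

    "Apparent equilibrium" is read strictly: Z, E and the Z/E ratio must
    all settle within 2% of their asymptotes, so that a monitoring window
    of this length observes the ratio curve actually flattening out (as the
    real assays do) rather than truncating it mid-relaxation.  Including
    the ratio matters in the fast pre-equilibrium regime, where the
    concentrations settle quickly but the ratio keeps drifting toward Keq
    on the slower product-interconversion timescale.
    """
    band = 0.02
    eq = equilibrium_state(rates, a0, l0)
    keq = eq.Z / eq.E
    slow = relaxation_rates(rates, a0, l0)[0]
    horizon = 30.0 / slow
    for _ in range(3):
        grid = np.linspace(0.0, horizon, 600)
        traj = simulate_network(rates, a0, l0, grid, rtol=1e-8, atol=1e-12)
        tz = time_to_asymptote(traj.t, traj.Z, final=eq.Z, band=band)
        te = time_to_asymptote(traj.t, traj.E, final=eq.E, band=band)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(traj.E > 0, traj.Z / np.where(traj.E > 0, traj.E, 1.0), np.nan)
        ratio[0] = keq  # Z = E = 0 at t = 0; treat the 0/0 point as settled
        tr = time_to_asymptote(traj.t, ratio, final=keq, band=band)
        t_eq = max(tz, te, tr)
        if math.isfinite(t_eq):
            return t_eq
        horizon *= 5.0
    raise UnattainableDesignError(
        f"equilibration time not reached within {horizon:g} min for rates "
        f"{rates.as_dict()}"
    )


def sample_rate_constants(
    regime: str,
    n: int,
    seed: int,
    *,
    a0: float = 1e-3,
    l0: float = 5e-4,
    max_intermediate_fraction: float = 0.05,
    min_aldehyde_consumption: float = 0.8,
    max_attempts_per_set: int = 200,
) -> list[RateConstants]:
    """Draw ``n`` rate sets realising the requested kinetic regime.

    ``regime`` is ``"fast_preequilibrium"``, ``"slow_bimolecular"`` or
    ``"mixed"`` (each draw picks one of the two limits at random).  Each
    set is constructed in three steps:

    1. draw the dimensionless shape — bimolecular K log-uniform in
       [1000, 10000] M^-1, both branch K log-uniform in [1, 20], a kinetic
       Z/E preference ``k1Z/k1E = u * keq_ze`` with ``u`` log-uniform in
       [1, 4] (the more stable stereoisomer also forms faster, with initial
       ratios exceeding equilibrium ratios by the modest factors seen
       experimentally), and the regime ratio ``rho = k1*a0/(k1Z + k1E)``
       log-uniform in [10, 300] (fast) or [1/300, 0.1] (slow);
    2. reject shapes whose *equilibrium* composition is unphysical for the
       assays: intermediate above ``max_intermediate_fraction`` of the
       aldehyde load, or aldehyde consumption below
       ``min_aldehyde_consumption``;
    3. rescale all six constants (an exact time-axis rescaling) so the
       simulated equilibration time lands uniformly in 300–600 min at the
       default 1 mM / 0.5 mM loads.

    Reproducible per ``seed``; raises :class:`UnattainableDesignError` when
    the rejection step exhausts ``max_attempts_per_set``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regime not in ("fast_preequilibrium", "slow_bimolecular", "mixed"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    out: list[RateConstants] = []
    while len(out) < n:
        for _attempt in range(max_attempts_per_set):
            kbi = _loguniform(rng, *BIMOLECULAR_K_RANGE)
            kz = _loguniform(rng, *BRANCH_K_RANGE)
            ke = _loguniform(rng, *BRANCH_K_RANGE)
            # kinetic preference tracks the thermodynamic one: initial Z/E
            # ratios sit a modest factor above the equilibrium ratio
            pref = (kz / ke) * _loguniform(rng, 1.0, 4.0)  # k1Z/k1E
            this_regime = regime
            if regime == "mixed":
                this_regime = ("fast_preequilibrium", "slow_bimolecular")[rng.integers(2)]
            if this_regime == "fast_preequilibrium":
                rho = _loguniform(rng, 10.0, 300.0)
            else:
                # "slow bimolecular followed by faster intramolecular steps"
                # must hold for the *reverse* unimolecular rates too, or the
                # Z/E ratio cannot pre-equilibrate ahead of the conversion;
                # the reverse rates are the forward ones over the branch K,
                # so the feed is kept an order of magnitude below
                # (k_m1Z + k_m1E), not just below (k1Z + k1E)
                rev_fraction = (pref / kz + 1.0 / ke) / (1.0 + pref)
                upper = 0.1 * rev_fraction
                rho = _loguniform(rng, min(1.0 / 300.0, 0.01 * rev_fraction), upper)
            branch_sum = 0.01  # min^-1 at unit scale; rescaled below
            k1z = branch_sum * pref / (1.0 + pref)
            k1e = branch_sum / (1.0 + pref)
            rates = RateConstants(
                k1=rho * branch_sum / a0,
                k_m1=rho * branch_sum / a0 / kbi,
                k1Z=k1z,
                k_m1Z=k1z / kz,
                k1E=k1e,
                k_m1E=k1e / ke,
            )
            eq = equilibrium_state(rates, a0, l0)
            if eq.I > max_intermediate_fraction * l0:
                continue
            if (l0 - eq.L) / l0 < min_aldehyde_consumption:
                continue
            t_eq = _equilibration_time(rates, a0, l0)
            target = rng.uniform(*EQUILIBRATION_RANGE)
            out.append(rates.scaled(t_eq / target))
            break
        else:
            raise UnattainableDesignError(
                f"no admissible {regime} rate set after "
                f"{max_attempts_per_set} attempts"
            )
    return out


def generate_experiment(
    rates: RateConstants, design: ExperimentDesign
) -> tuple[KineticSeries, GroundTruth]:
    """Simulate one experiment and dress it as noisy integral signals.

    The trajectory is sampled on ``design.grid``; each Z and E concentration
    is scaled to integral units and perturbed by independent multiplicative
    Gaussian noise ``(1 + eps)`` with ``sd = design.noise_rel_sd``, truncated
    at ``eps = -0.9`` so signals stay positive.  Returns the observable
    series plus the hidden ground truth.
    """
    grid = design.grid
    sim_grid = grid if grid[0] == 0.0 else np.concatenate([[0.0], grid])
    traj = simulate_network(rates, design.a0, design.l0, sim_grid)
    take = slice(None) if grid[0] == 0.0 else slice(1, None)
    z = traj.Z[take] * design.signal_scale
    e = traj.E[take] * design.signal_scale
    rng = np.random.default_rng(design.seed)
    if design.noise_rel_sd > 0:
        eps_z = np.clip(rng.normal(0.0, design.noise_rel_sd, z.size), -0.9, None)
        eps_e = np.clip(rng.normal(0.0, design.noise_rel_sd, e.size), -0.9, None)
        z = z * (1.0 + eps_z)
        e = e * (1.0 + eps_e)
    keq, initial = closed_form_ratios(rates)
    series = KineticSeries(
        t=grid.copy(), z_signal=z, e_signal=e,
        meta={"seed": design.seed, "a0": design.a0, "l0": design.l0},
    )
    truth = GroundTruth(
        rates=rates,
        keq_ze=keq,
        initial_ratio=initial,
        regime=classify_regime(rates, design.a0),
        seed=design.seed,
    )
    return series, truth


def generate_dataset(
    regime: str,
    n: int,
    seed: int,
    design: ExperimentDesign | None = None,
) -> tuple[list[KineticSeries], list[GroundTruth]]:
    """Generate ``n`` independent experiments of one regime.

    Per-experiment seeds are spawned deterministically from ``seed``; the
    i-th experiment of a dataset is identical across calls with the same
    arguments.
    """
    base = design or ExperimentDesign()
    rate_sets = sample_rate_constants(regime, n, seed, a0=base.a0, l0=base.l0)
    # independent, reproducible noise streams per experiment
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    series_list, truths = [], []
    for rates, child in zip(rate_sets, child_seeds):
        series, truth = generate_experiment(rates, replace(base, seed=int(child)))
        series_list.append(series)
        truths.append(truth)
    return series_list, truths


def ground_truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    """Tabulate ground truths for the sidecar CSV."""
    rows = []
    for i, gt in enumerate(truths):
        row = {"experiment": i, **gt.rates.as_dict(),
               "keq_ze": gt.keq_ze, "initial_ratio": gt.initial_ratio,
               "regime": gt.regime, "seed": gt.seed}
        rows.append(row)
    return pd.DataFrame(rows)
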