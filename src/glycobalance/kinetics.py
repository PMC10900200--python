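"""Mass-action kinetics of the Z/E enamine balance network.

The network couples a reversible bimolecular condensation of a free amine
(``A``) and a free aldehyde (``L``) into a lumped hemiaminal/imine
intermediate (``I``) with two competing reversible unimolecular
rearrangements of that intermediate into the *Z*- and *E*-enamine products::

    A + L  <=[k1]=[k_m1]=>  I
    I      <=[k1Z]=[k_m1Z]=>  Z
    I      <=[k1E]=[k_m1E]=>  E

Six effective rate constants fully define the system.  The acid catalyst and
released water are not explicit species: the observed Z/E ratios are
insensitive to the catalytic acid load, so the constants are effective
constants at fixed catalyst concentration.  Units are molar and minutes
throughout.

Two closed-form observables of the network anchor everything downstream:

* the equilibrium Z/E ratio, by detailed balance
  ``Keq = (k1Z * k_m1E) / (k1E * k_m1Z)``, and
* the initial Z/E ratio (the t -> 0+ limit starting from Z = E = 0),
  ``k1Z / k1E``, because both products are fed by the same intermediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "MixtureState",
    "Trajectory",
    "KineticsError",
    "SimulationError",
    "simulate_network",
    "closed_form_ratios",
    "classify_regime",
    "equilibrium_state",
    "relaxation_rates",
    "time_to_asymptote",
]

#: column layout of the trajectory CSV interchange format
TRAJECTORY_COLUMNS = ["t_min", "A_M", "L_M", "I_M", "Z_M", "E_M"]


class KineticsError(ValueError):
    """Invalid rate constants, concentrations or time grids."""


class SimulationError(RuntimeError):
    """The ODE integrator failed to produce a valid trajectory."""


@dataclass(frozen=True)
class RateConstants:
    """The six mass-action rate constants of the balance network.

    Parameters
    ----------
    k1 : float
        Bimolecular adduct formation rate, M^-1 min^-1.
    k_m1 : float
        Adduct dissociation rate, min^-1.
    k1Z, k_m1Z : float
        Forward/reverse rates of the Z-enamine branch, min^-1.
    k1E, k_m1E : float
        Forward/reverse rates of the E-enamine branch, min^-1.
    """

    k1: float
    k_m1: float
    k1Z: float
    k_m1Z: float
    k1E: float
    k_m1E: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (math.isfinite(value) and value > 0.0):
                raise KineticsError(
                    f"rate constant {name} must be strictly positive and "
                    f"finite, got {value!r}"
                )

    def as_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1,
            "k_m1": self.k_m1,
            "k1Z": self.k1Z,
            "k_m1Z": self.k_m1Z,
            "k1E": self.k1E,
            "k_m1E": self.k_m1E,
        }

    def scaled(self, factor: float) -> "RateConstants":
        """Multiply all six constants by ``factor``.

        Mass-action homogeneity makes this an exact rescaling of the time
        axis by ``1 / factor``; equilibrium composition, Z/E ratios and the
        regime classification are unchanged.
        """
        if not (math.isfinite(factor) and factor > 0):
            raise KineticsError(f"scale factor must be positive, got {factor!r}")
        return RateConstants(
            *(factor * v for v in self.as_dict().values())
        )

    def swapped_branches(self) -> "RateConstants":
        """Exchange the Z and E branches (swaps the two product roles)."""
        return replace(
            self, k1Z=self.k1E, k_m1Z=self.k_m1E, k1E=self.k1Z, k_m1E=self.k_m1Z
        )


@dataclass(frozen=True)
class MixtureState:
    """Concentrations of all species at one time point (M, time in min)."""

    t: float
    A: float
    L: float
    I: float
    Z: float
    E: float


@dataclass
class Trajectory:
    """Time-resolved species concentrations on a strictly increasing grid."""

    t: np.ndarray
    A: np.ndarray
    L: np.ndarray
    I: np.ndarray
    Z: np.ndarray
    E: np.ndarray
    rates: RateConstants
    a0: float
    l0: float

    def __len__(self) -> int:
        return self.t.size

    def state(self, i: int) -> MixtureState:
        return MixtureState(
            float(self.t[i]), float(self.A[i]), float(self.L[i]),
            float(self.I[i]), float(self.Z[i]), float(self.E[i]),
        )

    def ratio(self) -> np.ndarray:
        """Z/E concentration ratio; inf where E is exactly zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.E > 0, self.Z / np.where(self.E > 0, self.E, 1.0), np.inf)

    def conservation_error(self) -> tuple[float, float]:
        """Max relative violation of the amine and aldehyde mass balances."""
        amine = np.abs(self.A + self.I + self.Z + self.E - self.a0) / self.a0
        aldehyde = np.abs(self.L + self.I + self.Z + self.E - self.l0) / self.l0
        return float(amine.max()), float(aldehyde.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(zip(TRAJECTORY_COLUMNS, [self.t, self.A, self.L, self.I, self.Z, self.E]))
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, rates: RateConstants, a0: float, l0: float) -> "Trajectory":
        frame = pd.read_csv(path, float_precision="round_trip")
        if list(frame.columns) != TRAJECTORY_COLUMNS:
            raise KineticsError(
                f"trajectory CSV must have columns {TRAJECTORY_COLUMNS}, "
                f"got {list(frame.columns)}"
            )
        cols = [frame[c].to_numpy(dtype=float) for c in TRAJECTORY_COLUMNS]
        return cls(*cols, rates=rates, a0=a0, l0=l0)


def _validate_concentration(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise KineticsError(f"{name} must be a positive finite concentration, got {value!r}")


def _rhs(rates: RateConstants):
    k1, km1 = rates.k1, rates.k_m1
    k1z, km1z = rates.k1Z, rates.k_m1Z
    k1e, km1e = rates.k1E, rates.k_m1E

    def f(_t, y):
        a, l, i, z, e = y
        bi = k1 * a * l - km1 * i
        fz = k1z * i - km1z * z
        fe = k1e * i - km1e * e
        return [-bi, -bi, bi - fz - fe, fz, fe]

    def jac(_t, y):
        a, l, _i, _z, _e = y
        return np.array([
            [-k1 * l, -k1 * a, km1, 0.0, 0.0],
            [-k1 * l, -k1 * a, km1, 0.0, 0.0],
            [k1 * l, k1 * a, -(km1 + k1z + k1e), km1z, km1e],
            [0.0, 0.0, k1z, -km1z, 0.0],
            [0.0, 0.0, k1e, 0.0, -km1e],
        ])

    return f, jac


def simulate_network(
    rates: RateConstants,
    a0: float,
    l0: float,
    time_grid,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-13,
    method: str = "LSODA",
    initial_state: MixtureState | None = None,
) -> Trajectory:
    """Integrate the balance network deterministically.

    Parameters
    ----------
    rates : RateConstants
    a0, l0 : float
        Total amine and aldehyde concentrations (M).  The default initial
        condition is all-free material: ``A = a0``, ``L = l0``,
        ``I = Z = E = 0``.
    time_grid : array_like
        Strictly increasing output times in minutes, starting at 0.
    rtol, atol : float
        Integrator tolerances.  The defaults (1e-10 relative, 1e-13 M
        absolute) keep mass conservation below 1e-9 relative even when the
        rate constants span several orders of magnitude; tighten ``atol``
        when probing the t -> 0+ limit where concentrations are minute.
    method : str
        Any stiff-capable :func:`scipy.integrate.solve_ivp` method.
    initial_state : MixtureState, optional
        Explicit starting composition overriding the all-free default.

    Raises
    ------
    KineticsError
        On invalid rates, concentrations or grid.
    SimulationError
        If the integrator does not converge or reports negative
        concentrations beyond tolerance; never returns silent NaNs.
    """
    _validate_concentration("a0", a0)
    _validate_concentration("l0", l0)
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise KineticsError("time grid must be a non-empty 1-D array")
    if t[0] != 0.0:
        raise KineticsError(f"time grid must start at 0, got {t[0]!r}")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise KineticsError("time grid must be strictly increasing")

    if initial_state is None:
        y0 = [a0, l0, 0.0, 0.0, 0.0]
    else:
        y0 = [initial_state.A, initial_state.L, initial_state.I,
              initial_state.Z, initial_state.E]

    f, jac = _rhs(rates)
    if t.size == 1:  # degenerate grid: nothing to integrate
        y = np.array(y0, dtype=float)[:, None]
    else:
        sol = solve_ivp(
            f, (t[0], t[-1]), y0, t_eval=t, method=method,
            rtol=rtol, atol=atol, jac=jac,
        )
        if not sol.success:
            raise SimulationError(
                f"ODE integration failed: {sol.message} "
                f"(rates={rates.as_dict()}, a0={a0}, l0={l0})"
            )
        y = sol.y
        if np.any(~np.isfinite(y)):
            raise SimulationError("integrator produced non-finite concentrations")

    floor = -1e3 * atol - 1e-9 * max(a0, l0)
    if y.min() < floor:
        raise SimulationError(
            f"integrator produced negative concentration {y.min():.3e} M"
        )
    y = np.clip(y, 0.0, None)
    return Trajectory(t, y[0], y[1], y[2], y[3], y[4], rates=rates, a0=a0, l0=l0)


def closed_form_ratios(rates: RateConstants) -> tuple[float, float]:
    """Equilibrium and initial Z/E ratios from the rate constants alone.

    Returns ``(keq_ze, initial_ratio)`` where ``keq_ze`` is the detailed
    balance equilibrium ratio ``(k1Z * k_m1E) / (k1E * k_m1Z)`` (the
    t -> infinity limit of Z/E) and ``initial_ratio`` is ``k1Z / k1E``
    (the t -> 0+ limit starting from Z = E = 0, since both branches drain
    the same intermediate).
    """
    keq = (rates.k1Z * rates.k_m1E) / (rates.k1E * rates.k_m1Z)
    return keq, rates.k1Z / rates.k1E


def classify_regime(
    rates: RateConstants,
    a0: float,
    *,
    fast_threshold: float = 10.0,
    slow_threshold: float = 0.1,
) -> str:
    """Label the kinetic regime of the network at amine load ``a0``.

    The deciding ratio is ``rho = k1 * a0 / (k1Z + k1E)``: the pseudo
    first-order adduct formation rate against the combined branch rates.
    ``rho >= 10`` -> ``"fast_preequilibrium"`` (the intermediate equilibrates
    with the free reagents before the enamines form), ``rho <= 0.1`` ->
    ``"slow_bimolecular"`` (adduct formation is rate limiting and the Z/E
    ratio curve equilibrates before the individual concentrations), anything
    between -> ``"intermediate"``.  The one-order-of-magnitude thresholds
    separate the two limiting behaviours cleanly.
    """
    _validate_concentration("a0", a0)
    rho = rates.k1 * a0 / (rates.k1Z + rates.k1E)
    if rho >= fast_threshold:
        return "fast_preequilibrium"
    if rho <= slow_threshold:
        return "slow_bimolecular"
    return "intermediate"


def equilibrium_state(rates: RateConstants, a0: float, l0: float) -> MixtureState:
    """Closed-form equilibrium composition of the network.

    At equilibrium every reaction satisfies detailed balance, so with
    ``K_bi = k1/k_m1``, ``K_Z = k1Z/k_m1Z``, ``K_E = k1E/k_m1E`` and
    ``S = 1 + K_Z + K_E`` the converted amount ``C = I + Z + E`` solves the
    quadratic ``S*K_bi*C^2 - (S*K_bi*(a0 + l0) + 1)*C + S*K_bi*a0*l0 = 0``
    (the physically admissible root lies below ``min(a0, l0)``).
    """
    _validate_concentration("a0", a0)
    _validate_concentration("l0", l0)
    kbi = rates.k1 / rates.k_m1
    kz = rates.k1Z / rates.k_m1Z
    ke = rates.k1E / rates.k_m1E
    s = 1.0 + kz + ke
    a = s * kbi
    b = -(s * kbi * (a0 + l0) + 1.0)
    c = s * kbi * a0 * l0
    disc = b * b - 4.0 * a * c
    root = (-b - math.sqrt(disc)) / (2.0 * a)  # smaller root < min(a0, l0)
    inter = root / s
    return MixtureState(
        t=math.inf, A=a0 - root, L=l0 - root, I=inter, Z=kz * inter, E=ke * inter
    )


def relaxation_rates(rates: RateConstants, a0: float, l0: float) -> np.ndarray:
    """Relaxation rates (min^-1) of the network linearised at equilibrium.

    Returns the magnitudes of the three non-zero eigenvalues of the
    equilibrium Jacobian, sorted ascending; the slowest sets the
    equilibration timescale, the fastest the t -> 0+ probe scale.  Two zero
    eigenvalues (the two mass balances) are discarded.
    """
    eq = equilibrium_state(rates, a0, l0)
    _f, jac = _rhs(rates)
    eig = np.linalg.eigvals(jac(0.0, [eq.A, eq.L, eq.I, eq.Z, eq.E]))
    mags = np.sort(np.abs(eig.real))
    return mags[2:]  # drop the two conservation-law zeros


def time_to_asymptote(t, y, final: float | None = None, band: float = 0.1) -> float:
    """First time after which ``y`` stays within ``band`` of its asymptote.

    ``final`` defaults to the last sample.  Returns ``inf`` when even the
    final sample is outside the band (only possible with an explicit
    ``final``).  The "stays within" convention makes the metric meaningful
    for non-monotone curves such as fast-regime enamine concentrations that
    overshoot through a maximum.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if final is None:
        final = float(y[-1])
    within = np.abs(y - final) <= band * abs(final)
    if not within[-1]:
        return math.inf
    # index of the last point outside the band
    outside = np.nonzero(~within)[0]
    first = 0 if outside.size == 0 else outside[-1] + 1
    return float(t[first])
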