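"""Solvent trends: linear free energy relationships and stability rankings.

Charge and polarization contributions respond to the hydrogen-bonding
character of the medium.  Following the usual linear free energy treatment,
each contribution is regressed against an empirical solvent hydrogen-bond
parameter — the donor strength alpha or the acceptor strength beta — by
ordinary least squares, and classes of aromatic complexes are ranked per
solvent by their mean interaction free energy.  Hunter alpha/beta values are
user-supplied inputs (a CSV table), never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .thermo import FreeEnergyRecord
from .ratiofit import InsufficientDataError

__all__ = [
    "SolventDescriptor",
    "TrendFit",
    "RankResult",
    "regress_vs_parameter",
    "rank_hierarchy",
]


@dataclass(frozen=True)
class SolventDescriptor:
    """A solvent with its Hunter hydrogen-bond donor/acceptor parameters."""

    name: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError(f"alpha/beta must be finite for solvent {self.name!r}")


@dataclass(frozen=True)
class TrendFit:
    """OLS line of a free energy quantity against a solvent parameter."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_stderr: float
    parameter: str
    quantity: str | None = None

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        return (
            f"{self.quantity or 'dG'} ~ {self.parameter}: "
            f"slope = {self.slope:.4g} +/- {self.slope_stderr:.2g} kcal/mol "
            f"per unit, intercept = {self.intercept:.4g} kcal/mol, "
            f"R^2 = {self.r_squared:.3f} (n = {self.n_points})"
        )


def _solvent_table(
    solvents: Iterable[SolventDescriptor],
) -> dict[str, SolventDescriptor]:
    table: dict[str, SolventDescriptor] = {}
    for d in solvents:
        if d.name in table:
            raise ValueError(f"duplicated solvent {d.name!r} in descriptor table")
        table[d.name] = d
    return table


def regress_vs_parameter(
    values: Sequence[FreeEnergyRecord],
    solvents: Iterable[SolventDescriptor],
    parameter: str,
) -> TrendFit:
    """OLS regression of free energy records on a solvent parameter.

    Records are matched to descriptors by solvent name; each record must
    come from a distinct solvent.  ``parameter`` selects ``"alpha"`` or
    ``"beta"``.  The regression is unweighted.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 records pair up with a descriptor.
    ValueError
        Unknown parameter, duplicated solvent names, or a record whose
        solvent has no descriptor.
    """
    if parameter not in ("alpha", "beta"):
        raise ValueError(f"parameter must be 'alpha' or 'beta', got {parameter!r}")
    table = _solvent_table(solvents)
    xs, ys, seen = [], [], set()
    for rec in values:
        if rec.solvent is None:
            continue
        if rec.solvent in seen:
            raise ValueError(f"duplicated solvent {rec.solvent!r} among the records")
        if rec.solvent not in table:
            raise ValueError(f"no descriptor for solvent {rec.solvent!r}")
        seen.add(rec.solvent)
        xs.append(getattr(table[rec.solvent], parameter))
        ys.append(rec.value)
    if len(xs) < 3:
        raise InsufficientDataError(
            f"regression needs >= 3 solvent points, got {len(xs)}"
        )
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(y) == 0.0:
        # degenerate flat response: OLS r^2 is 0/0; report a zero trend
        return TrendFit(0.0, float(y[0]), 0.0, len(y), 0.0, parameter)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(res.rsquared)
    if not math.isfinite(r2):
        r2 = 0.0
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=len(y),
        slope_stderr=float(res.bse[1]),
        parameter=parameter,
    )


@dataclass(frozen=True)
class RankResult:
    """Stability ordering of complex classes within one solvent."""

    classes: tuple[str, ...]
    has_ties: bool
    solvent: str | None = None


def rank_hierarchy(
    per_class_means: Mapping[str, float], solvent: str | None = None
) -> RankResult:
    """Order complex classes from most to least stabilizing.

    Sorts ascending by mean free energy (most negative first); exact ties
    are broken alphabetically and flagged on the result.  The ordering is
    invariant to adding any constant to all means.
    """
    if len(per_class_means) < 2:
        raise ValueError("ranking needs at least 2 classes")
    items = sorted(per_class_means.items(), key=lambda kv: (kv[1], kv[0]))
    vals = [v for _, v in items]
    has_ties = any(a == b for a, b in zip(vals, vals[1:]))
    return RankResult(tuple(k for k, _ in items), has_ties, solvent)
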