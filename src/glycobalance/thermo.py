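"""Free energies from Z/E equilibrium constants, with the tiered error model.

Conversions and differences
---------------------------
``dG_ZE = -R T ln(Keq)`` converts a Z/E equilibrium constant to the free
energy difference between the two enamine stereoisomers (kcal/mol, negative
values favour Z).  Three differential quantities isolate specific physics:

* ``dG_int``    — interaction free energy of the aromatic complex: a model's
  ``dG_ZE`` minus that of the bare reference balance R0 (which carries no
  interacting fragment).
* ``dG_charge`` — net contribution of a charge: a charged model minus its
  neutral isostere (e.g. the trimethylammonium model against its isosteric
  tert-butyl analogue).
* ``dG_pol``    — net contribution of CH polarization: a CH-polarized model
  minus its nonpolarized isostere.

Error model
-----------
Keq uncertainties follow a conservative tier scheme established from
duplicate experiments: relative errors of 5% (Keq 1-5), 7.5% (5-10),
10% (10-15) and 15% (Keq > 15).  A relative Keq error ``f`` bounds the free
energy error by ``R T ln(1 + f)``; at 293 K the four tiers give at most
0.028, 0.042, 0.056 and 0.081 kcal/mol.  Errors of differential quantities
combine in quadrature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "FreeEnergyRecord",
    "EquilibriumMeasurement",
    "delta_g_from_keq",
    "assign_keq_error_tier",
    "dg_error_from_keq_error",
    "free_energy_record",
    "interaction_free_energy",
    "isostere_contribution",
    "propagate_dg_error",
    "summarize_complex_class",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL_PER_MOL_K = 1.98720e-3
#: assay temperature (20 degC)
DEFAULT_TEMPERATURE_K = 293.0

#: (upper Keq bound of tier, relative error fraction); last tier is open
KEQ_ERROR_TIERS = ((5.0, 0.05), (10.0, 0.075), (15.0, 0.10), (math.inf, 0.15))


@dataclass(frozen=True)
class EquilibriumMeasurement:
    """One balance's measured Keq with its experimental context."""

    balance_id: str
    keq: float
    role: str = "model"  # model | reference
    reference_id: str | None = None
    solvent: str | None = None
    aldehyde: str | None = None
    counterion: str | None = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not (math.isfinite(self.keq) and self.keq > 0):
            raise ValueError(f"keq must be positive, got {self.keq!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.role not in ("model", "reference"):
            raise ValueError(f"role must be 'model' or 'reference', got {self.role!r}")


@dataclass(frozen=True)
class FreeEnergyRecord:
    """A free energy value in kcal/mol with its propagated error.

    ``quantity`` is one of ``dG_ZE``, ``dG_int``, ``dG_charge``, ``dG_pol``.
    Negative values are Z-stabilizing (attractive interactions).
    ``provenance`` lists the balance ids that entered the value.
    """

    quantity: str
    value: float
    error: float
    temperature: float = DEFAULT_TEMPERATURE_K
    solvent: str | None = None
    balance_id: str | None = None
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.quantity not in ("dG_ZE", "dG_int", "dG_charge", "dG_pol"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if not math.isfinite(self.value):
            raise ValueError("value must be finite")
        if not (self.error >= 0 and math.isfinite(self.error)):
            raise ValueError("error must be finite and >= 0")


def delta_g_from_keq(keq: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """-R T ln(Keq) in kcal/mol; zero at Keq = 1, decreasing in Keq."""
    if not (math.isfinite(keq) and keq > 0):
        raise ValueError(f"keq must be strictly positive, got {keq!r}")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return -R_KCAL_PER_MOL_K * temperature * math.log(keq)


def assign_keq_error_tier(keq: float) -> float:
    """Relative Keq error fraction from the tier scheme.

    Tiers are lower-inclusive half-open intervals over Keq: [1, 5) -> 5%,
    [5, 10) -> 7.5%, [10, 15) -> 10%, [15, inf) -> 15%.  Keq below 1 is
    assigned the tier of its reciprocal: -RT ln Keq is antisymmetric in
    ln Keq, so a ratio and its inverse carry the same relative precision.
    """
    if not (math.isfinite(keq) and keq > 0):
        raise ValueError(f"keq must be strictly positive, got {keq!r}")
    k = keq if keq >= 1.0 else 1.0 / keq
    for upper, fraction in KEQ_ERROR_TIERS:
        if k < upper:
            return fraction
    raise AssertionError("unreachable")  # pragma: no cover


def dg_error_from_keq_error(
    fraction: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Free energy half-width R T ln(1 + f) from a relative Keq error f.

    A (1 + f)-fold over- or under-estimate of Keq shifts -RT ln Keq by at
    most RT ln(1 + f); this is the maximum |ddG| the tier fraction allows.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"fraction must lie in [0, 1), got {fraction!r}")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return R_KCAL_PER_MOL_K * temperature * math.log1p(fraction)


def free_energy_record(
    keq: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    *,
    balance_id: str | None = None,
    solvent: str | None = None,
) -> FreeEnergyRecord:
    """Build a ``dG_ZE`` record from a Keq, with its tier error attached."""
    return FreeEnergyRecord(
        quantity="dG_ZE",
        value=delta_g_from_keq(keq, temperature),
        error=dg_error_from_keq_error(assign_keq_error_tier(keq), temperature),
        temperature=temperature,
        solvent=solvent,
        balance_id=balance_id,
        provenance=(balance_id,) if balance_id else (),
    )


def propagate_dg_error(e_model: float, e_reference: float) -> float:
    """Quadrature combination ``sqrt(e_model^2 + e_reference^2)``."""
    if e_model < 0 or e_reference < 0:
        raise ValueError("errors must be non-negative")
    return math.hypot(e_model, e_reference)


def _check_comparable(a: FreeEnergyRecord, b: FreeEnergyRecord) -> None:
    if a.quantity != "dG_ZE" or b.quantity != "dG_ZE":
        raise ValueError(
            f"differential quantities require two dG_ZE records, got "
            f"{a.quantity!r} and {b.quantity!r}"
        )
    if a.temperature != b.temperature:
        raise ValueError(
            f"temperature mismatch: {a.temperature} K vs {b.temperature} K"
        )
    if a.solvent != b.solvent:
        raise ValueError(f"solvent mismatch: {a.solvent!r} vs {b.solvent!r}")


def _difference(
    model: FreeEnergyRecord, reference: FreeEnergyRecord, quantity: str
) -> FreeEnergyRecord:
    _check_comparable(model, reference)
    return FreeEnergyRecord(
        quantity=quantity,
        value=model.value - reference.value,
        error=propagate_dg_error(model.error, reference.error),
        temperature=model.temperature,
        solvent=model.solvent,
        balance_id=model.balance_id,
        provenance=model.provenance + reference.provenance,
    )


def interaction_free_energy(
    model: FreeEnergyRecord, r0: FreeEnergyRecord
) -> FreeEnergyRecord:
    """``dG_int = dG_ZE(model) - dG_ZE(R0)``, error in quadrature."""
    return _difference(model, r0, "dG_int")


def isostere_contribution(
    model: FreeEnergyRecord,
    isostere: FreeEnergyRecord,
    kind: str,
    registry: Mapping[str, str] | None = None,
) -> FreeEnergyRecord:
    """Charge or polarization contribution from an isostere subtraction.

    ``kind`` is ``"charge"`` or ``"polarization"``.  When a ``registry``
    mapping of model balance id -> declared isostere id is given, the
    pairing is validated against it and an undeclared pairing is rejected.
    """
    if kind not in ("charge", "polarization"):
        raise ValueError(f"kind must be 'charge' or 'polarization', got {kind!r}")
    if registry is not None:
        declared = registry.get(model.balance_id)
        if declared != isostere.balance_id:
            raise ValueError(
                f"pairing {model.balance_id!r} vs {isostere.balance_id!r} is not "
                f"declared in the balance registry (declared: {declared!r})"
            )
    quantity = "dG_charge" if kind == "charge" else "dG_pol"
    return _difference(model, isostere, quantity)


def summarize_complex_class(
    records: Sequence[FreeEnergyRecord],
    class_labels: Sequence[str],
) -> pd.DataFrame:
    """Per-class mean and sample standard deviation of free energies.

    ``class_labels`` is parallel to ``records``.  Returns a frame with
    columns ``complex_class``, ``mean``, ``sd``, ``n`` ordered by
    descending stability (most negative mean first).  Singleton classes get
    ``sd = NaN``; labels with no records are dropped with a warning.
    """
    if len(records) != len(class_labels):
        raise ValueError("records and class_labels must be parallel sequences")
    values: dict[str, list[float]] = {}
    for rec, label in zip(records, class_labels):
        if label is None:
            continue
        values.setdefault(label, []).append(rec.value)
    rows = []
    for label, vals in values.items():
        if not vals:
            warnings.warn(f"class {label!r} has no records; omitted", stacklevel=2)
            continue
        arr = np.asarray(vals)
        rows.append({
            "complex_class": label,
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
            "n": int(arr.size),
        })
    frame = pd.DataFrame(rows, columns=["complex_class", "mean", "sd", "n"])
    return frame.sort_values("mean", kind="stable", ignore_index=True)
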