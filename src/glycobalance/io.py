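"""File formats, balance registry and the end-to-end pipeline.

Formats
-------
* kinetic CSV — header exactly ``t_min,z_integral,e_integral``; one row per
  HSQC time point.
* solvent CSV — header ``name,alpha,beta`` (Hunter hydrogen-bond
  parameters, user-supplied).
* registry config — a versioned YAML document declaring every balance
  entry (id, role, reference/isostere pairing, complex class, solvent,
  aldehyde, counterion) plus study-level settings; see
  :func:`load_registry`.

The pipeline (:func:`run_pipeline`) strings the stages together: read each
series, build the guarded ratio curve, select and fit the exponential
model, convert the fitted Keq to free energies with tier errors, form the
differential quantities against the declared references, summarize complex
classes per solvent and regress charge/polarization contributions against
the solvent parameters.  All outputs are deterministic functions of the
config and input files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import thermo
from .ratiofit import KineticSeries, build_ratio_series, select_fit
from .thermo import (
    DEFAULT_TEMPERATURE_K,
    FreeEnergyRecord,
    assign_keq_error_tier,
    free_energy_record,
    interaction_free_energy,
    isostere_contribution,
    summarize_complex_class,
)
from .trends import SolventDescriptor, rank_hierarchy, regress_vs_parameter
from .ratiofit import InsufficientDataError

__all__ = [
    "KINETIC_HEADER",
    "ParseError",
    "RegistryError",
    "BalanceEntry",
    "BalanceRegistry",
    "read_kinetic_csv",
    "write_kinetic_csv",
    "read_solvent_table",
    "load_registry",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger("glycobalance")

KINETIC_HEADER = ("t_min", "z_integral", "e_integral")

COMPLEX_CLASSES = frozenset({
    "nonpolarized_CHpi",
    "polarized_CHpi",
    "cationic_CHpi_poor_donor",
    "cationic_CHpi_good_donor",
    "anionic_CHpi",
})

REGISTRY_VERSION = 1


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


class RegistryError(ValueError):
    """An inconsistent balance registry."""


# -- kinetic CSV -----------------------------------------------------------

def read_kinetic_csv(path, meta: Mapping | None = None) -> KineticSeries:
    """Read a kinetic CSV into a validated :class:`KineticSeries`.

    Rows are sorted by time on read; exact duplicate times are rejected.
    Parse failures name the 1-based line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: line 1: empty file")
    header = tuple(col.strip() for col in lines[0].split(","))
    if header != KINETIC_HEADER:
        raise ParseError(
            f"{path}: line 1: header must be "
            f"{','.join(KINETIC_HEADER)!r}, got {lines[0]!r}"
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
        try:
            rows.append(tuple(float(p) for p in parts))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if len(rows) < 1:
        raise ParseError(f"{path}: no data rows")
    data = np.array(sorted(rows), dtype=float)
    t = data[:, 0]
    if np.any(np.diff(t) == 0):
        dup = t[np.nonzero(np.diff(t) == 0)[0][0]]
        raise ParseError(f"{path}: duplicate time {dup!r} min")
    return KineticSeries(t=t, z_signal=data[:, 1], e_signal=data[:, 2],
                         meta=dict(meta or {}))


def write_kinetic_csv(series: KineticSeries, path) -> None:
    """Write a kinetic CSV at full float precision (round-trip safe)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(KINETIC_HEADER) + "\n")
        for t, z, e in zip(series.t, series.z_signal, series.e_signal):
            fh.write(f"{t:.17g},{z:.17g},{e:.17g}\n")


# -- solvent table ---------------------------------------------------------

def read_solvent_table(path) -> list[SolventDescriptor]:
    """Read the ``name,alpha,beta`` solvent CSV."""
    frame = pd.read_csv(path)
    if list(frame.columns) != ["name", "alpha", "beta"]:
        raise ParseError(
            f"{path}: line 1: header must be 'name,alpha,beta', "
            f"got {list(frame.columns)}"
        )
    descriptors = [
        SolventDescriptor(str(r["name"]), float(r["alpha"]), float(r["beta"]))
        for _, r in frame.iterrows()
    ]
    names = [d.name for d in descriptors]
    if len(set(names)) != len(names):
        raise ParseError(f"{path}: duplicated solvent names")
    return descriptors


# -- registry --------------------------------------------------------------

@dataclass(frozen=True)
class BalanceEntry:
    """One balance measured in one solvent, with its declared references."""

    balance_id: str
    role: str  # model | reference
    solvent: str
    series: str  # path to the kinetic CSV, relative to the config
    reference_id: str | None = None  # isostere or None
    isostere_kind: str = "none"  # charge | polarization | none
    complex_class: str | None = None
    aldehyde: str = "a1"
    counterion: str | None = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.role not in ("model", "reference"):
            raise RegistryError(f"{self.balance_id}: role must be model|reference")
        if self.isostere_kind not in ("charge", "polarization", "none"):
            raise RegistryError(
                f"{self.balance_id}: isostere_kind must be charge|polarization|none"
            )
        if self.complex_class is not None and self.complex_class not in COMPLEX_CLASSES:
            raise RegistryError(
                f"{self.balance_id}: unknown complex_class {self.complex_class!r} "
                f"(allowed: {sorted(COMPLEX_CLASSES)})"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.balance_id, self.solvent)


@dataclass
class BalanceRegistry:
    """The study layout: entries plus study-level settings."""

    entries: list[BalanceEntry]
    primary_reference: str = "R0"
    temperature: float = DEFAULT_TEMPERATURE_K
    min_signal_fraction: float = 0.02
    solvent_table: list[SolventDescriptor] = field(default_factory=list)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise RegistryError("duplicate (balance_id, solvent) entries")
        self._by_key = {e.key: e for e in self.entries}
        for e in self.entries:
            if e.reference_id is not None and (e.reference_id, e.solvent) not in self._by_key:
                raise RegistryError(
                    f"{e.balance_id} ({e.solvent}): reference_id "
                    f"{e.reference_id!r} does not resolve in that solvent"
                )
            if e.reference_id is not None and e.isostere_kind == "none":
                raise RegistryError(
                    f"{e.balance_id}: reference_id given but isostere_kind is 'none'"
                )

    def lookup(self, balance_id: str, solvent: str) -> BalanceEntry | None:
        return self._by_key.get((balance_id, solvent))

    def isostere_pairs(self) -> dict[str, str]:
        return {
            e.balance_id: e.reference_id
            for e in self.entries
            if e.reference_id is not None
        }


def load_registry(path) -> BalanceRegistry:
    """Load and validate the YAML registry config."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return registry_from_dict(doc, base_dir=path.parent)


def registry_from_dict(doc: Mapping, base_dir=Path(".")) -> BalanceRegistry:
    if not isinstance(doc, Mapping):
        raise RegistryError("registry config must be a mapping")
    version = doc.get("version")
    if version != REGISTRY_VERSION:
        raise RegistryError(
            f"unsupported registry version {version!r} (expected {REGISTRY_VERSION})"
        )
    temperature = float(doc.get("temperature_K", DEFAULT_TEMPERATURE_K))
    entries = []
    for raw in doc.get("balances", []):
        raw = dict(raw)
        raw.setdefault("temperature", temperature)
        entries.append(BalanceEntry(**raw))
    if not entries:
        raise RegistryError("registry declares no balances")
    solvent_table: list[SolventDescriptor] = []
    st = doc.get("solvent_table")
    if isinstance(st, str):
        solvent_table = read_solvent_table(Path(base_dir) / st)
    elif isinstance(st, Sequence):
        solvent_table = [
            SolventDescriptor(str(s["name"]), float(s["alpha"]), float(s["beta"]))
            for s in st
        ]
    return BalanceRegistry(
        entries=entries,
        primary_reference=str(doc.get("primary_reference", "R0")),
        temperature=temperature,
        min_signal_fraction=float(doc.get("min_signal_fraction", 0.02)),
        solvent_table=solvent_table,
        base_dir=Path(base_dir),
    )


# -- pipeline --------------------------------------------------------------

@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    fits: pd.DataFrame
    free_energies: pd.DataFrame
    class_means: pd.DataFrame
    hierarchies: pd.DataFrame
    trends: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("fits", "free_energies", "class_means", "hierarchies", "trends"):
            frame = getattr(self, name)
            frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.10g", lineterminator="\n")


def run_pipeline(config, outdir=None) -> PipelineResult:
    """Run fit -> free energies -> class summaries -> solvent trends.

    ``config`` is a registry mapping (see :func:`registry_from_dict`), a
    path to a YAML file, or an already-built :class:`BalanceRegistry`.
    Writes the result TSVs under ``outdir`` when given.  Identical inputs
    produce byte-identical outputs.
    """
    if isinstance(config, BalanceRegistry):
        registry = config
    elif isinstance(config, Mapping):
        registry = registry_from_dict(config)
    else:
        registry = load_registry(config)

    fit_rows = []
    dg_ze: dict[tuple[str, str], FreeEnergyRecord] = {}
    for entry in registry.entries:
        series = read_kinetic_csv(
            registry.base_dir / entry.series,
            meta={"balance_id": entry.balance_id, "solvent": entry.solvent},
        )
        curve = build_ratio_series(series, registry.min_signal_fraction)
        fit = select_fit(curve)
        tier = assign_keq_error_tier(fit.keq)
        logger.info(
            "balance %s [%s]: keq=%.4g tier=%.3g n_exp=%d converged=%s",
            entry.balance_id, entry.solvent, fit.keq, tier,
            fit.n_exponentials, fit.converged,
        )
        logger.debug("residuals %s: %s", entry.balance_id, fit.residuals())
        fit_rows.append({
            "balance_id": entry.balance_id,
            "solvent": entry.solvent,
            "keq": fit.keq,
            "keq_err_tier": tier,
            "initial_ratio": fit.initial_ratio,
            "n_exp": fit.n_exponentials,
            "sse": fit.residual_sse,
            "converged": fit.converged,
        })
        dg_ze[entry.key] = free_energy_record(
            fit.keq, entry.temperature,
            balance_id=entry.balance_id, solvent=entry.solvent,
        )

    # differential free energies
    energy_rows = []
    int_records: list[FreeEnergyRecord] = []
    int_classes: list[str | None] = []
    contribution_records: list[tuple[str, FreeEnergyRecord]] = []
    pairs = registry.isostere_pairs()
    for entry in registry.entries:
        rec = dg_ze[entry.key]
        row = {
            "balance_id": entry.balance_id,
            "solvent": entry.solvent,
            "aldehyde": entry.aldehyde,
            "counterion": entry.counterion,
            "complex_class": entry.complex_class,
            "keq": None,
            "keq_tier": None,
            "dG_ZE": rec.value,
            "dG_ZE_err": rec.error,
            "dG_int": None, "dG_int_err": None,
            "dG_contribution": None, "dG_contribution_err": None,
            "contribution_kind": entry.isostere_kind,
        }
        row["keq"] = next(r["keq"] for r in fit_rows
                          if (r["balance_id"], r["solvent"]) == entry.key)
        row["keq_tier"] = assign_keq_error_tier(row["keq"])
        if entry.balance_id != registry.primary_reference:
            ref_key = (registry.primary_reference, entry.solvent)
            if ref_key not in dg_ze:
                raise RegistryError(
                    f"dG_int for {entry.balance_id} ({entry.solvent}) needs "
                    f"{registry.primary_reference} measured in the same solvent"
                )
            rec_int = interaction_free_energy(rec, dg_ze[ref_key])
            row["dG_int"], row["dG_int_err"] = rec_int.value, rec_int.error
            int_records.append(rec_int)
            int_classes.append(entry.complex_class)
        if entry.reference_id is not None:
            iso = dg_ze[(entry.reference_id, entry.solvent)]
            contrib = isostere_contribution(rec, iso, entry.isostere_kind, pairs)
            row["dG_contribution"], row["dG_contribution_err"] = (
                contrib.value, contrib.error,
            )
            contribution_records.append((entry.isostere_kind, contrib))
        energy_rows.append(row)

    # per-solvent class summaries and rankings
    mean_frames, hierarchy_rows = [], []
    solvents = sorted({e.solvent for e in registry.entries})
    for solvent in solvents:
        recs = [r for r, c in zip(int_records, int_classes)
                if r.solvent == solvent and c is not None]
        labels = [c for r, c in zip(int_records, int_classes)
                  if r.solvent == solvent and c is not None]
        if not recs:
            continue
        summary = summarize_complex_class(recs, labels)
        summary.insert(0, "solvent", solvent)
        mean_frames.append(summary)
        if len(summary) >= 2:
            rank = rank_hierarchy(
                dict(zip(summary["complex_class"], summary["mean"])), solvent
            )
            hierarchy_rows.append({
                "solvent": solvent,
                "ranking": " > ".join(rank.classes),
                "has_ties": rank.has_ties,
            })

    # solvent trends per (model, kind), across solvents
    trend_rows = []
    if registry.solvent_table:
        by_model: dict[tuple[str, str], list[FreeEnergyRecord]] = {}
        for kind, rec in contribution_records:
            by_model.setdefault((rec.balance_id, kind), []).append(rec)
        for (balance_id, kind), recs in sorted(by_model.items()):
            for parameter in ("alpha", "beta"):
                try:
                    fitres = regress_vs_parameter(recs, registry.solvent_table, parameter)
                except InsufficientDataError:
                    continue
                trend_rows.append({
                    "balance_id": balance_id,
                    "quantity": "dG_charge" if kind == "charge" else "dG_pol",
                    "parameter": parameter,
                    "slope": fitres.slope,
                    "intercept": fitres.intercept,
                    "r_squared": fitres.r_squared,
                    "n": fitres.n_points,
                })

    result = PipelineResult(
        fits=pd.DataFrame(fit_rows),
        free_energies=pd.DataFrame(energy_rows),
        class_means=(pd.concat(mean_frames, ignore_index=True) if mean_frames
                     else pd.DataFrame(columns=["solvent", "complex_class", "mean", "sd", "n"])),
        hierarchies=pd.DataFrame(hierarchy_rows,
                                 columns=["solvent", "ranking", "has_ties"]),
        trends=pd.DataFrame(trend_rows,
                            columns=["balance_id", "quantity", "parameter",
                                     "slope", "intercept", "r_squared", "n"]),
    )
    if outdir is not None:
        result.write(outdir)
    return result
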