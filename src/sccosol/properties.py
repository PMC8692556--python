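"""Corresponding-states and group-contribution property estimation.

The EoS and cluster routes need the solute's critical constants, acentric
factor, solid molar volume and sublimation pressure -- quantities rarely
measured for drugs.  This module provides the estimation chain: a normal
boiling point back-solved from the Klincewicz Tc relation, Lee-Kesler
vapor-pressure and acentric-factor correlations, and a pluggable
group-contribution evaluator driven by editable JSON coefficient tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data import load_gc_table

__all__ = [
    "klincewicz_tb",
    "lee_kesler_f",
    "lee_kesler_psub",
    "lee_kesler_omega",
    "GroupCount",
    "GCTable",
    "gc_estimate",
    "load_table",
]

P_ATM = 101325.0  # Pa


def klincewicz_tb(Tc: float, M: float) -> float:
    """Normal boiling point (K) from Tc = 50.2 - 0.16 M + 1.41 Tb.

    The relation is inverted: Tb = (Tc - 50.2 + 0.16 M) / 1.41.
    """
    Tb = (Tc - 50.2 + 0.16 * M) / 1.41
    if Tb <= 0:
        raise ValueError("nonphysical boiling point from Klincewicz inversion")
    return Tb


def lee_kesler_f(Tr):
    """The Lee-Kesler vapor-pressure functions (f0, f1) at reduced T."""
    Tr = np.asarray(Tr, dtype=float)
    f0 = 5.92714 - 6.09648 / Tr - 1.28862 * np.log(Tr) + 0.169347 * Tr**6
    f1 = 15.2518 - 15.6875 / Tr - 13.4721 * np.log(Tr) + 0.43577 * Tr**6
    return f0, f1


def lee_kesler_psub(T, Tc: float, Pc: float, omega: float):
    """Vapor/sublimation pressure (Pa) via ln(P/Pc) = f0 + omega*f1.

    Pc in Pa.  Valid for 0 < T <= Tc; anchored so P(Tc) = Pc.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or np.any(T > Tc):
        raise ValueError("require 0 < T <= Tc")
    f0, f1 = lee_kesler_f(T / Tc)
    p = Pc * np.exp(f0 + omega * f1)
    return float(p) if p.ndim == 0 else p


def lee_kesler_omega(Tb: float, Tc: float, Pc: float) -> float:
    """Acentric factor from the boiling-point anchor P(Tb) = 1 atm:
    omega = (-ln(Pc/1 atm) - f0(Tbr)) / f1(Tbr), Pc in Pa."""
    if not (0 < Tb < Tc):
        raise ValueError("require 0 < Tb < Tc")
    f0, f1 = lee_kesler_f(Tb / Tc)
    if abs(f1) < 1e-3:  # f1 vanishes at Tbr -> 1: the anchor carries no slope
        raise ValueError("degenerate anchor: f1(Tbr) ~ 0")
    return float((-np.log(Pc / P_ATM) - f0) / f1)


@dataclass(frozen=True)
class GroupCount:
    """Molecular decomposition: integer occurrence counts per group label."""

    method_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("group counts must be non-negative")


@dataclass(frozen=True)
class GCTable:
    """Coefficient table: per-group increments plus the assembling formula.

    formula_id selects how the increment sum S becomes a property:
      - "sum": value = S
      - "sum_A3_to_cm3": molar volume = 0.6022 * S (angstrom^3 -> cm3/mol)
      - "fedors_log_tc": Tc = 535 * log10(S)
      - "joback_tc": Tc = Tb / (0.584 + 0.965 S - S^2), needs tb=
      - "joback_pc": Pc (MPa) = 0.1 * (0.113 + 0.0032 n_atoms - S)^-2,
        needs n_atoms=
      - "joback_tb": Tb = 198.2 + S
      - "lydersen_pc": Pc (MPa) = 0.101325 * M / (0.34 + S)^2, needs M
    """

    method_id: str
    contributions: Mapping[str, float]
    formula_id: str

    def __post_init__(self) -> None:
        if not self.contributions:
            raise ValueError("empty contribution table")


def load_table(name: str) -> GCTable:
    """Load a packaged coefficient table by file stem."""
    raw = load_gc_table(name)
    return GCTable(
        method_id=raw["method_id"],
        contributions=raw["contributions"],
        formula_id=raw["formula_id"],
    )


def gc_estimate(
    gc: GroupCount,
    table: GCTable,
    M: float | None = None,
    tb: float | None = None,
    n_atoms: int | None = None,
) -> float:
    """Assemble a property estimate from group counts and a table.

    Raises on labels absent from the table.  ``M``, ``tb`` and ``n_atoms``
    feed formulas that need them (see :class:`GCTable`).
    """
    if gc.method_id != table.method_id:
        raise ValueError(
            f"method mismatch: counts are {gc.method_id!r}, table {table.method_id!r}"
        )
    unknown = [g for g in gc.counts if g not in table.contributions]
    if unknown:
        raise KeyError(f"groups not in {table.method_id} table: {unknown}")
    S = float(sum(n * table.contributions[g] for g, n in gc.counts.items()))
    f = table.formula_id
    if f == "sum":
        return S
    if f == "sum_A3_to_cm3":
        return 0.6022 * S
    if f == "fedors_log_tc":
        if S <= 1.0:
            raise ValueError("increment sum must exceed 1 for the log form")
        return 535.0 * np.log10(S)
    if f == "joback_tc":
        if tb is None:
            raise ValueError("joback_tc needs tb=")
        return tb / (0.584 + 0.965 * S - S**2)
    if f == "joback_pc":
        if n_atoms is None:
            raise ValueError("joback_pc needs n_atoms=")
        return 0.1 * (0.113 + 0.0032 * n_atoms - S) ** -2
    if f == "joback_tb":
        return 198.2 + S
    if f == "lydersen_pc":
        if M is None:
            raise ValueError("lydersen_pc needs M=")
        return 0.101325 * M / (0.34 + S) ** 2
    raise ValueError(f"unknown formula_id {f!r}")
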