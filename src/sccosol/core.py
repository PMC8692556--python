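"""Domain types, measurement conversions and data-consistency diagnostics.

Solubility of a solid solute (index 2) in supercritical CO2 (index 1) is
expressed as a mole fraction ``y2`` on a total-moles basis.  Measurements are
isothermal tables of (T, P, rho1, y2) where ``rho1`` is the pure-CO2 density
at the state point (an input, typically from the NIST reference EoS).

The vial-sampling conversion chain assumes a fixed volume of saturated
ScCO2 (the sampling loop) is depressurised into a solvent-preloaded vial;
the solute concentration measured in the vial is converted back to a fluid
phase mole fraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

R = 8.314  # J mol-1 K-1

__all__ = [
    "R",
    "ComponentSpec",
    "IsothermPoint",
    "SolubilityDataset",
    "SamplingGeometry",
    "MTConsistency",
    "y2_from_vial_concentration",
    "s_from_y2",
    "y2_from_s",
    "sample_std",
    "mt_selfconsistency",
]


@dataclass(frozen=True)
class ComponentSpec:
    """Constant properties of one chemical species.

    Parameters
    ----------
    M : float
        Molar mass, g/mol.
    Tc : float
        Critical temperature, K.
    Pc : float
        Critical pressure, MPa.
    omega : float
        Acentric factor (dimensionless).
    Vsolid : float, optional
        Solid molar volume in m3/mol (solutes only).
    psub_table : dict, optional
        Map of temperature (K) to sublimation pressure (Pa).
    """

    M: float
    Tc: float
    Pc: float
    omega: float = 0.0
    Vsolid: float | None = None
    psub_table: Mapping[float, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.M <= 0 or self.Tc <= 0 or self.Pc <= 0:
            raise ValueError("M, Tc and Pc must be positive")
        if self.Vsolid is not None and self.Vsolid <= 0:
            raise ValueError("Vsolid must be positive when given")

    def psub(self, T: float) -> float:
        """Tabulated sublimation pressure at T (Pa); exact-key lookup with
        log-linear interpolation in 1/T between tabulated temperatures."""
        if not self.psub_table:
            raise ValueError(f"no sublimation-pressure table for {self.name!r}")
        tab = {float(k): float(v) for k, v in self.psub_table.items()}
        if T in tab:
            return tab[T]
        Ts = np.array(sorted(tab))
        ps = np.array([tab[t] for t in Ts])
        if not (Ts[0] <= T <= Ts[-1]):
            raise ValueError(f"T={T} outside tabulated range [{Ts[0]}, {Ts[-1]}]")
        # Clausius-Clapeyron-like interpolation: ln p linear in 1/T
        return float(np.exp(np.interp(1.0 / T, 1.0 / Ts[::-1], np.log(ps[::-1]))))

    @classmethod
    def from_json(cls, path: str | Path) -> "ComponentSpec":
        raw = json.loads(Path(path).read_text())
        return cls(
            M=raw["M_g_mol"],
            Tc=raw["Tc_K"],
            Pc=raw["Pc_MPa"],
            omega=raw.get("omega", 0.0),
            Vsolid=raw.get("Vsolid_m3_mol"),
            psub_table=(
                {float(k): v for k, v in raw["psub_Pa"].items()}
                if raw.get("psub_Pa")
                else None
            ),
            name=raw.get("name", ""),
        )

    def to_json(self, path: str | Path) -> None:
        raw = {
            "name": self.name,
            "M_g_mol": self.M,
            "Tc_K": self.Tc,
            "Pc_MPa": self.Pc,
            "omega": self.omega,
        }
        if self.Vsolid is not None:
            raw["Vsolid_m3_mol"] = self.Vsolid
        if self.psub_table:
            raw["psub_Pa"] = {str(k): v for k, v in self.psub_table.items()}
        Path(path).write_text(json.dumps(raw, indent=1))


@dataclass(frozen=True)
class IsothermPoint:
    """One solubility measurement: state (T, P, rho1) and mole fraction y2."""

    T: float  # K
    P: float  # MPa
    rho1: float  # kg/m3 (== g/L numerically)
    y2: float  # mol/mol total
    S: float | None = None  # g/L, optional
    sd: float | None = None  # sample std of y2, optional

    def __post_init__(self) -> None:
        if self.T <= 0 or self.P <= 0 or self.rho1 <= 0:
            raise ValueError("T, P and rho1 must be positive")
        if not (0.0 < self.y2 < 1.0):
            raise ValueError("y2 must lie strictly in (0, 1)")


class SolubilityDataset:
    """Ordered collection of isothermal solubility measurements.

    The canonical regression input for every model in the package.  Column
    accessors return numpy arrays in row order; ``isotherms()`` groups rows
    by temperature with pressure ascending within each group.
    """

    def __init__(self, points: Iterable[IsothermPoint], label: str = ""):
        self.points: list[IsothermPoint] = list(points)
        if not self.points:
            raise ValueError("dataset needs at least one point")
        self.label = label

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def T(self) -> np.ndarray:
        return np.array([p.T for p in self.points])

    @property
    def P(self) -> np.ndarray:
        return np.array([p.P for p in self.points])

    @property
    def rho1(self) -> np.ndarray:
        return np.array([p.rho1 for p in self.points])

    @property
    def y2(self) -> np.ndarray:
        return np.array([p.y2 for p in self.points])

    @property
    def S(self) -> np.ndarray:
        return np.array([np.nan if p.S is None else p.S for p in self.points])

    def isotherms(self) -> dict[float, "SolubilityDataset"]:
        out: dict[float, SolubilityDataset] = {}
        for T in sorted(set(p.T for p in self.points)):
            pts = sorted((p for p in self.points if p.T == T), key=lambda p: p.P)
            out[T] = SolubilityDataset(pts, label=f"{self.label} @ {T} K")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_K": self.T,
                "P_MPa": self.P,
                "rho_kg_m3": self.rho1,
                "y2": self.y2,
                "S_g_L": self.S,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "SolubilityDataset":
        pts = []
        has_S = "S_g_L" in df.columns
        has_sd = "sd_y2" in df.columns
        for row in df.itertuples(index=False):
            d = row._asdict()
            S = d.get("S_g_L") if has_S else None
            sd = d.get("sd_y2") if has_sd else None
            pts.append(
                IsothermPoint(
                    T=float(d["T_K"]),
                    P=float(d["P_MPa"]),
                    rho1=float(d["rho_kg_m3"]),
                    y2=float(d["y2"]),
                    S=None if S is None or pd.isna(S) else float(S),
                    sd=None if sd is None or pd.isna(sd) else float(sd),
                )
            )
        return cls(pts, label=label)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "SolubilityDataset":
        df = pd.read_csv(path)
        required = {"T_K", "P_MPa", "rho_kg_m3", "y2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
        return cls.from_frame(df, label=label if label is not None else str(path))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SamplingGeometry:
    """Volumes of the saturation sampling train.

    loop_volume: volume of saturated ScCO2 sampled (m3); vial_volume: total
    collected (solvent-diluted) solution volume (m3).
    """

    loop_volume: float
    vial_volume: float

    def __post_init__(self) -> None:
        if self.loop_volume <= 0 or self.vial_volume <= 0:
            raise ValueError("sampling volumes must be positive")
        if self.loop_volume > self.vial_volume:
            warnings.warn(
                "sampling loop larger than collection vial; check volume units",
                stacklevel=3,
            )


def y2_from_vial_concentration(
    Cs: float,
    geom: SamplingGeometry,
    rho1: float,
    solute: ComponentSpec,
    solvent: ComponentSpec,
) -> float:
    """Mole fraction from the vial concentration of the collected sample.

    n_drug = Cs * V_vial / M_s (Cs in g/L, volume converted to L) and
    n_CO2 = V_loop * rho1 / M_CO2; returns n_drug / (n_drug + n_CO2).
    """
    if Cs < 0 or rho1 <= 0:
        raise ValueError("Cs must be >= 0 and rho1 > 0")
    if Cs == 0.0:
        return 0.0
    n_drug = Cs * (geom.vial_volume * 1e3) / solute.M  # g/L * L / (g/mol)
    n_co2 = geom.loop_volume * rho1 * 1e3 / solvent.M  # m3 * kg/m3 -> g / (g/mol)
    return n_drug / (n_drug + n_co2)


def s_from_y2(
    y2: float, rho1: float, solute: ComponentSpec, solvent: ComponentSpec
) -> float:
    """Equilibrium solubility in g per litre of CO2:
    S = rho1 * (M_s / M_CO2) * y2 / (1 - y2), rho1 read as g/L."""
    y2 = np.asarray(y2, dtype=float)
    if np.any(y2 >= 1.0) or np.any(y2 < 0.0):
        raise ValueError("y2 must lie in [0, 1)")
    out = rho1 * (solute.M / solvent.M) * y2 / (1.0 - y2)
    return float(out) if out.ndim == 0 else out


def y2_from_s(
    S: float, rho1: float, solute: ComponentSpec, solvent: ComponentSpec
) -> float:
    """Exact algebraic inverse of :func:`s_from_y2`."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be >= 0")
    r = S * solvent.M / (solute.M * rho1)
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def sample_std(values: Sequence[float]) -> float:
    """Unbiased (n-1) sample standard deviation of replicate measurements."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("sample_std needs at least two values")
    return float(np.std(v, ddof=1))


@dataclass(frozen=True)
class MTConsistency:
    """Straight-line diagnostic of the Mendez-Santiago/Teja transformation.

    Data generated by T ln(y2 P) = H1 + H2 rho1 + H3 T collapse onto a single
    line when T ln(y2 P) - H3 T is plotted against rho1, regardless of
    isotherm; departure from the line flags internally inconsistent data.
    """

    rho1: np.ndarray
    transformed: np.ndarray  # T ln(y2 P) - H3 T, P in MPa
    slope: float
    intercept: float
    r2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho_kg_m3": self.rho1, "T_ln_y2P_minus_H3T": self.transformed}
        )


def mt_selfconsistency(
    data: SolubilityDataset, H: Sequence[float]
) -> MTConsistency:
    """Apply the MT transformation with parameter triple H = (H1, H2, H3).

    Pressure enters the y2*P product in MPa (the package-wide convention;
    fitted constants absorb the unit choice).  Returns the transformed
    points together with slope/intercept/R2 of their least-squares line.
    """
    H1, H2, H3 = (float(h) for h in H)
    y2P = data.y2 * data.P
    if np.any(y2P <= 0):
        raise ValueError("y2*P must be positive for the MT transformation")
    t = data.T * np.log(y2P) - H3 * data.T
    x = data.rho1
    slope, intercept = np.polyfit(x, t, 1)
    resid = t - (slope * x + intercept)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return MTConsistency(
        rho1=x, transformed=t, slope=float(slope), intercept=float(intercept), r2=r2
    )
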