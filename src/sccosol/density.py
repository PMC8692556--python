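"""Density-based semi-empirical solubility correlations.

Ten published correlations of the mole-fraction solubility ``y2`` of a solid
in supercritical CO2 against temperature, pressure and the pure-CO2 density
``rho1``, all behind one ``predict(params, T, P, rho1, solvent)`` interface
keyed by model id.  Unit conventions (fixed; fitted constants absorb them):
T in K, P in MPa, rho1 in kg/m3; reduced state uses the solvent criticals
with rho_c(CO2) = 467.6 kg/m3.

Every model here is linear in its parameters after a log-type
transformation, which the fitting layer exploits for exact initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import R, ComponentSpec

RHOC_CO2 = 467.6  # kg/m3, standard critical density of CO2
P_REF_MPA = 0.1  # reference pressure of the enhancement-factor form
RHO_REF = 700.0  # kg/m3, reference density of the enhancement-factor form
F_REF_PA = 1.0e5  # reference fugacity (0.1 MPa) of the reformulated Chrastil form

MODEL_IDS = (
    "alwi_garlapati",
    "bartle",
    "bian",
    "chrastil",
    "ref_chrastil",
    "garlapati_madras",
    "mt",
    "sodeifian",
    "reddy_garlapati",
    "mahesh_garlapati",
)


@dataclass(frozen=True)
class DensityModelSpec:
    """Static description of one density model."""

    model_id: str
    n_params: int
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    needs: frozenset[str]


@dataclass(frozen=True)
class ParamVector:
    """Ordered constants of one density model (units implicit per model)."""

    model_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        spec = get_spec(self.model_id)
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) != spec.n_params:
            raise ValueError(
                f"{self.model_id} expects {spec.n_params} parameters, "
                f"got {len(self.values)}"
            )


@dataclass(frozen=True)
class ReducedState:
    """State reduced by the solvent criticals: Tr = T/Tc, Pr = P/Pc,
    rho1r = rho1/rho_c."""

    Tr: float
    Pr: float
    rho1r: float

    def __post_init__(self) -> None:
        if np.any(np.asarray([self.Tr, self.Pr, self.rho1r]) <= 0):
            raise ValueError("reduced state must be positive")


def reduced_state(T, P, rho1, solvent: ComponentSpec) -> ReducedState:
    return ReducedState(
        Tr=T / solvent.Tc, Pr=P / solvent.Pc, rho1r=rho1 / RHOC_CO2
    )


_SPECS = {
    "alwi_garlapati": DensityModelSpec(
        "alwi_garlapati",
        3,
        ("A1", "A2", "A3"),
        ((-60.0, 60.0), (-200.0, 200.0), (-30.0, 30.0)),
        frozenset({"Tr", "rho1r"}),
    ),
    "bartle": DensityModelSpec(
        "bartle",
        3,
        ("B1", "B2", "B3"),
        ((-60.0, 60.0), (-30000.0, 0.0), (-0.1, 0.1)),
        frozenset({"T", "P", "rho1"}),
    ),
    "bian": DensityModelSpec(
        "bian",
        5,
        ("D1", "D2", "D3", "D4", "D5"),
        ((-60.0, 60.0), (-0.2, 0.2), (-30000.0, 30000.0), (-60.0, 60.0), (-60.0, 60.0)),
        frozenset({"T", "rho1"}),
    ),
    "chrastil": DensityModelSpec(
        "chrastil",
        3,
        ("kappa", "E1", "E2"),
        ((0.0, 20.0), (-60.0, 60.0), (-30000.0, 0.0)),
        frozenset({"T", "rho1"}),
    ),
    "ref_chrastil": DensityModelSpec(
        "ref_chrastil",
        3,
        ("kappa_p", "F1", "F2"),
        ((0.0, 20.0), (-80.0, 80.0), (-30000.0, 0.0)),
        frozenset({"T", "rho1"}),
    ),
    "garlapati_madras": DensityModelSpec(
        "garlapati_madras",
        5,
        ("G1", "G2", "G3", "G4", "G5"),
        ((-2000.0, 2000.0), (-2000.0, 2000.0), (-5.0, 5.0), (-30000.0, 30000.0), (-300.0, 300.0)),
        frozenset({"T", "rho1"}),
    ),
    "mt": DensityModelSpec(
        "mt",
        3,
        ("H1", "H2", "H3"),
        ((-30000.0, 0.0), (-10.0, 10.0), (-100.0, 100.0)),
        frozenset({"T", "P", "rho1"}),
    ),
    "sodeifian": DensityModelSpec(
        "sodeifian",
        6,
        ("I1", "I2", "I3", "I4", "I5", "I6"),
        ((-300.0, 300.0), (-1.0, 1.0), (-60.0, 60.0), (-1.0, 1.0), (-1.0, 1.0), (-3000.0, 3000.0)),
        frozenset({"T", "P", "rho1"}),
    ),
    "reddy_garlapati": DensityModelSpec(
        "reddy_garlapati",
        6,
        ("J1", "J2", "J3", "J4", "J5", "J6"),
        tuple(((-1e-4, 1e-4),) * 6),
        frozenset({"Tr", "Pr"}),
    ),
    "mahesh_garlapati": DensityModelSpec(
        "mahesh_garlapati",
        3,
        ("K1", "K2", "K3"),
        ((-60.0, 60.0), (-30.0, 30.0), (-30.0, 30.0)),
        frozenset({"Tr", "rho1r"}),
    ),
}


def registry() -> list[DensityModelSpec]:
    """All ten model descriptors, in canonical order."""
    return [_SPECS[m] for m in MODEL_IDS]


def get_spec(model_id: str) -> DensityModelSpec:
    try:
        return _SPECS[model_id]
    except KeyError:
        raise ValueError(f"unknown density model {model_id!r}") from None


def chrastil_c2(params: ParamVector, T, rho1):
    """Chrastil mass concentration c2 = rho1^kappa * exp(E1 + E2/T)."""
    if params.model_id != "chrastil":
        raise ValueError("chrastil_c2 requires chrastil parameters")
    k, E1, E2 = params.values
    rho1 = np.asarray(rho1, dtype=float)
    return rho1**k * np.exp(E1 + E2 / np.asarray(T, dtype=float))


def predict(params: ParamVector, T, P, rho1, solvent: ComponentSpec):
    """Mole-fraction solubility predicted by the given density model.

    Accepts scalars or equal-length arrays for (T, P, rho1).  The returned
    value is raw: models that can go negative for pathological parameters
    (e.g. the polynomial reduced-state form) are not clamped.
    """
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    v = params.values
    m = params.model_id
    with np.errstate(over="ignore"):
        if m == "alwi_garlapati":
            Tr = T / solvent.Tc
            rr = rho1 / RHOC_CO2
            y = np.exp(v[0] + v[1] / Tr + v[2] * rr) / (rr * Tr)
        elif m == "bartle":
            y = (P_REF_MPA / P) * np.exp(v[0] + v[1] / T + v[2] * (rho1 - RHO_REF))
        elif m == "bian":
            y = rho1 ** (v[0] + v[1] * rho1) * np.exp(
                v[2] / T + v[3] * rho1 / T + v[4]
            )
        elif m == "chrastil":
            u = rho1 ** (v[0] - 1.0) * np.exp(v[1] + v[2] / T)
            y = u / (1.0 + u)
        elif m == "ref_chrastil":
            base = R * T * rho1 / (solvent.M * 1e-3) / F_REF_PA
            y = base ** (v[0] - 1.0) * np.exp(v[1] + v[2] / T)
        elif m == "garlapati_madras":
            y = np.exp(
                v[0]
                + (v[1] + v[2] * rho1) * np.log(rho1)
                + v[3] / T
                + v[4] * np.log(rho1 * T)
            )
        elif m == "mt":
            y = np.exp((v[0] + v[1] * rho1) / T + v[2]) / P
        elif m == "sodeifian":
            y = np.exp(
                v[0]
                + v[1] * P**2 / T
                + v[2] * np.log(rho1 * T)
                + v[3] * rho1 * np.log(rho1)
                + v[4] * P * np.log(T)
                + v[5] * np.log(rho1) / T
            )
        elif m == "reddy_garlapati":
            Tr = T / solvent.Tc
            Pr = P / solvent.Pc
            y = (v[0] + v[1] * Pr + v[2] * Pr**2) * Tr**2 + (
                v[3] + v[4] * Pr + v[5] * Pr**2
            )
        elif m == "mahesh_garlapati":
            Tr = T / solvent.Tc
            rr = rho1 / RHOC_CO2
            y = np.exp(v[0] + v[1] * rr * Tr + v[2] * rr * Tr**3)
        else:  # pragma: no cover - ParamVector already validates
            raise ValueError(f"unknown density model {m!r}")
    y = np.asarray(y, dtype=float)
    return float(y) if y.ndim == 0 else y


def design_matrix(model_id: str, T, P, rho1, solvent: ComponentSpec):
    """Linearisation (X, z, back) of a model: its parameters solve
    ``X @ theta = z`` in a transformed space, and ``back(theta)`` maps the
    regression solution to the model's native parameter vector.

    Used for exact least-squares initialisation of the non-convex
    relative-deviation fits; z depends on the observed y2 and is built by
    the caller via the returned ``transform(y2)`` function.
    """
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    one = np.ones_like(T)
    ident = lambda th: th  # noqa: E731

    if model_id == "alwi_garlapati":
        Tr, rr = T / solvent.Tc, rho1 / RHOC_CO2
        X = np.column_stack([one, 1.0 / Tr, rr])
        transform = lambda y: np.log(y * rr * Tr)  # noqa: E731
        return X, transform, ident
    if model_id == "bartle":
        X = np.column_stack([one, 1.0 / T, rho1 - RHO_REF])
        transform = lambda y: np.log(y * P / P_REF_MPA)  # noqa: E731
        return X, transform, ident
    if model_id == "bian":
        X = np.column_stack([np.log(rho1), rho1 * np.log(rho1), 1.0 / T, rho1 / T, one])
        return X, np.log, ident
    if model_id == "chrastil":
        X = np.column_stack([np.log(rho1), one, 1.0 / T])
        transform = lambda y: np.log(y / (1.0 - y)) + np.log(rho1)  # noqa: E731
        # ln(y/(1-y)) = (kappa-1) ln rho + E1 + E2/T; add ln rho to fit kappa directly
        return X, transform, ident
    if model_id == "ref_chrastil":
        base = np.log(R * T * rho1 / (solvent.M * 1e-3) / F_REF_PA)
        X = np.column_stack([base, one, 1.0 / T])
        transform = lambda y: np.log(y) + base  # noqa: E731
        return X, transform, ident
    if model_id == "garlapati_madras":
        X = np.column_stack(
            [one, np.log(rho1), rho1 * np.log(rho1), 1.0 / T, np.log(rho1 * T)]
        )
        return X, np.log, ident
    if model_id == "mt":
        X = np.column_stack([one, rho1, T])
        transform = lambda y: T * np.log(y * P)  # noqa: E731
        return X, transform, ident
    if model_id == "sodeifian":
        X = np.column_stack(
            [one, P**2 / T, np.log(rho1 * T), rho1 * np.log(rho1), P * np.log(T),
             np.log(rho1) / T]
        )
        return X, np.log, ident
    if model_id == "reddy_garlapati":
        Tr, Pr = T / solvent.Tc, P / solvent.Pc
        X = np.column_stack(
            [Tr**2, Pr * Tr**2, Pr**2 * Tr**2, one, Pr, Pr**2]
        )
        return X, ident, ident
    if model_id == "mahesh_garlapati":
        Tr, rr = T / solvent.Tc, rho1 / RHOC_CO2
        X = np.column_stack([one, rr * Tr, rr * Tr**3])
        return X, np.log, ident
    raise ValueError(f"unknown density model {model_id!r}")


def linear_init(
    model_id: str, T, P, rho1, y2, solvent: ComponentSpec
) -> np.ndarray:
    """Exact least-squares parameter estimate in the model's linearised
    space; for models linear in y2 itself the rows are weighted by 1/y2 so
    the solution approximates a relative-error fit."""
    X, transform, back = design_matrix(model_id, T, P, rho1, solvent)
    z = transform(np.asarray(y2, dtype=float))
    if model_id == "reddy_garlapati":
        w = 1.0 / np.asarray(y2, dtype=float)
        X = X * w[:, None]
        z = z * w
    theta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return np.asarray(back(theta), dtype=float)
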