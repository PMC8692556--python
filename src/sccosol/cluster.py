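"""Solvate-complex (cluster) solubility models.

Dissolution is treated as the chemical equilibrium A + kappa*B <=> AB_kappa
between solute A, supercritical solvent B and a solvate complex, with a
Gibbs-energy change dF_rxn(T) referenced to the solvent's critical
pressure.  Two temperature parameterisations are supported:

* ``chen``: dF_rxn = a' - b'*T (three adjustable parameters with kappa);
* ``new``:  dF_rxn = a'' + b''*T*ln(T) + c''*T (four parameters), which
  nests the first form at b'' = 0 with a'' = a', c'' = -b'.

The apparent solubility follows y = e^X / (1 + 2*kappa*e^X) where the
exponent X collects the fugacity-ratio, Poynting and reaction terms; the
complex's PR parameters come from volume/energy combining rules in kappa.
All fugacity coefficients are evaluated with the PR EoS at the
solvent-rich composition (complex mole fraction ~ y ~ 1e-6), iterated to
self-consistency.

The complex-solvent pair carries the binary corrections (kij, lij)
calibrated by the temperature-independent EoS regression on the same data:
with the raw geometric-mean cross attraction (kij = 0) the infinite-
dilution fugacity coefficient of the heavy complex varies far too steeply
with density and no reaction term can recover the observed isothermal
pressure dependence, just as the plain EoS route fails without its fitted
corrections.  Pass ``inter=BinaryInteraction()`` to evaluate the
uncorrected theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import optimize

from .core import R, ComponentSpec, SolubilityDataset
from .eos import BinaryInteraction, PurePR, _lnphi_binary, _pure_ab_arrays, fit_eos
from .fitting import FitResult

__all__ = [
    "ChenParams",
    "NewClusterParams",
    "ClusterState",
    "cluster_ab",
    "delta_f_rxn",
    "y_from_z",
    "z_from_y",
    "y_cluster",
    "fit_cluster",
    "reaction_thermo",
]


@dataclass(frozen=True)
class ChenParams:
    """Solvation number and linear dF_rxn(T) = a' - b'*T coefficients."""

    kappa: float
    a_prime: float  # J/mol
    b_prime: float  # J/mol/K

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class NewClusterParams:
    """Solvation number and dF_rxn(T) = a'' + b''*T*ln(T) + c''*T."""

    kappa: float
    a_dp: float  # J/mol
    b_dp: float  # J/mol/K
    c_dp: float  # J/mol/K

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


ClusterParams = Union[ChenParams, NewClusterParams]


@dataclass(frozen=True)
class ClusterState:
    """Complex mole fraction z_AB and the apparent solubility y it implies."""

    z_AB: float
    y: float


def cluster_ab(kappa: float, pureA: PurePR, pureB: PurePR) -> PurePR:
    """PR parameters of the complex AB_kappa from the combining rules
    b = kappa*b_B + b_A and a = [kappa*sqrt(a_B b_B) + sqrt(a_A b_A)]^2 / b."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    prodA = pureA.a * pureA.b
    prodB = pureB.a * pureB.b
    if prodA < 0 or prodB < 0:
        raise ValueError("a*b products must be non-negative")
    b = kappa * pureB.b + pureA.b
    a = (kappa * np.sqrt(prodB) + np.sqrt(prodA)) ** 2 / b
    return PurePR(a=float(a), b=float(b))


def delta_f_rxn(T, params: ClusterParams):
    """Gibbs-energy change of complex formation at T (J/mol)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T must be positive")
    if isinstance(params, ChenParams):
        out = params.a_prime - params.b_prime * T
    else:
        out = params.a_dp + params.b_dp * T * np.log(T) + params.c_dp * T
    return float(out) if out.ndim == 0 else out


def y_from_z(z, kappa):
    """Apparent solubility from the complex mole fraction: y = z/(1+kappa*z)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z >= 1):
        raise ValueError("z must lie in [0, 1)")
    out = z / (1.0 + kappa * z)
    return float(out) if out.ndim == 0 else out


def z_from_y(y, kappa):
    """Inverse of :func:`y_from_z`."""
    y = np.asarray(y, dtype=float)
    out = y / (1.0 - kappa * y)
    return float(out) if out.ndim == 0 else out


def _exponent(T, P, kappa, dF, aC, bC, a1, b1, Vs, Pc, kij=0.0, lij=0.0,
              tol=1e-10, maxiter=60):
    """Vectorised evaluation of the cluster-model exponent X, with the
    complex mole fraction iterated to self-consistency from the pure
    solvent limit.  Species 0 is the complex, species 1 the solvent;
    (kij, lij) correct the complex-solvent pair (pure references are
    unaffected)."""
    zero = np.zeros_like(np.asarray(T, dtype=float))
    ln_p_ratio = np.log(P / Pc)
    lnphiB_ref = _lnphi_binary(1, zero, T, Pc, aC, bC, a1, b1)
    lnphiC_ref = _lnphi_binary(0, zero + 1.0, T, Pc, aC, bC, a1, b1)
    poynting = Vs * (P - Pc) / (R * T)
    z = zero.copy()
    X = np.full_like(zero, np.nan)
    for _ in range(maxiter):
        zB = 1.0 - kappa * z
        x1 = z / (z + zB)  # normalised complex fraction for phi evaluation
        lnphiB = _lnphi_binary(1, x1, T, P, aC, bC, a1, b1, kij, lij)
        lnphiC = _lnphi_binary(0, x1, T, P, aC, bC, a1, b1, kij, lij)
        X = (
            kappa * (lnphiB + ln_p_ratio - lnphiB_ref)
            + poynting
            - (lnphiC + ln_p_ratio - lnphiC_ref)
            - dF / (R * T)
        )
        with np.errstate(over="ignore"):
            z_new = 1.0 / (np.exp(-X) + kappa)  # z = e^X / (1 + kappa e^X)
        if np.all(np.abs(z_new - z) <= tol * np.maximum(z_new, 1e-300)):
            z = z_new
            break
        z = z_new
    return X, z


def _predict_cluster(T, P_pa, params: ClusterParams, solute, solvent,
                     kij=0.0, lij=0.0):
    """Vectorised apparent solubility over arrays of (T, P in Pa)."""
    T = np.asarray(T, dtype=float)
    P_pa = np.asarray(P_pa, dtype=float)
    kappa = params.kappa
    Pc = solvent.Pc * 1e6
    aA, bA = _pure_ab_arrays(T, solute)
    a1, b1 = _pure_ab_arrays(T, solvent)
    bC = kappa * b1 + bA
    aC = (kappa * np.sqrt(a1 * b1) + np.sqrt(aA * bA)) ** 2 / bC
    dF = delta_f_rxn(T, params)
    X, _ = _exponent(T, P_pa, kappa, dF, aC, bC, a1, b1, solute.Vsolid, Pc,
                     kij, lij)
    with np.errstate(over="ignore"):
        y = 1.0 / (np.exp(-X) + 2.0 * kappa)  # e^X / (1 + 2 kappa e^X)
    return y


def y_cluster(
    T: float,
    P: float,
    params: ClusterParams,
    solute: ComponentSpec,
    solvent: ComponentSpec,
    inter: BinaryInteraction | None = None,
) -> float:
    """Apparent solute mole fraction at T (K), P (Pa) for either cluster
    variant (selected by the parameter type).  ``inter`` carries the
    complex-solvent binary corrections (default: none)."""
    if P <= 0:
        raise ValueError("P must be positive")
    if solute.Vsolid is None:
        raise ValueError("solute needs a solid molar volume")
    kij, lij = inter.at(T) if inter is not None else (0.0, 0.0)
    y = float(
        _predict_cluster(np.asarray(T, float), P, params, solute, solvent, kij, lij)
    )
    if not np.isfinite(y):
        raise RuntimeError("cluster fixed point did not produce a finite y")
    return y


def _pack(variant: str, theta) -> ClusterParams:
    if variant == "chen":
        return ChenParams(*(float(t) for t in theta))
    if variant == "new":
        return NewClusterParams(*(float(t) for t in theta))
    raise ValueError("variant must be 'chen' or 'new'")


def _basis(variant: str, T: np.ndarray) -> np.ndarray:
    # columns multiply the dF coefficients after kappa
    if variant == "chen":
        return np.column_stack([np.ones_like(T), -T])
    return np.column_stack([np.ones_like(T), T * np.log(T), T])


def fit_cluster(
    data: SolubilityDataset,
    variant: str,
    solute: ComponentSpec,
    solvent: ComponentSpec,
    seed: int = 42,
    n_starts: int = 8,
    inter: BinaryInteraction | None = None,
) -> FitResult:
    """Fit a cluster model by minimising the relative-deviation objective.

    ``inter`` supplies the complex-solvent binary corrections; when None a
    temperature-independent EoS regression on the same dataset is run first
    and its (kij, lij) are inherited.

    Strategy: because y ~ 1e-6 implies X ~ ln(y), for a fixed solvation
    number the optimal reaction term decomposes per isotherm; a seeded
    kappa grid with per-isotherm one-dimensional solves and a least-squares
    projection of dF(T) onto the variant's basis provides the start for a
    full Nelder-Mead polish of all parameters (plus seeded restarts).
    """
    if solute.Vsolid is None:
        raise ValueError("solute needs a solid molar volume")
    if inter is None:
        inter = fit_eos(
            data, solute, solvent, mode="t_independent", seed=seed
        ).interaction
    kij, lij = inter.kij, inter.lij
    T, P_pa, y_exp = data.T, data.P * 1e6, data.y2
    iso_T = np.array(sorted(set(T)))
    Pc = solvent.Pc * 1e6

    def of(theta):
        if theta[0] < 0:
            return 1e12
        y_cal = _predict_cluster(
            T, P_pa, _pack(variant, theta), solute, solvent, kij, lij
        )
        bad = ~np.isfinite(y_cal) | (y_cal <= 0)
        rel = np.where(bad, 1e6, np.abs(y_exp - np.where(bad, y_exp, y_cal)) / y_exp)
        return float(np.sum(rel))

    # stage 1: kappa grid with per-isotherm decomposition
    def stage1(kappa):
        # exponent with dF = 0 gives the state-dependent part G_i
        aA, bA = _pure_ab_arrays(T, solute)
        a1, b1 = _pure_ab_arrays(T, solvent)
        bC = kappa * b1 + bA
        aC = (kappa * np.sqrt(a1 * b1) + np.sqrt(aA * bA)) ** 2 / bC
        G, _ = _exponent(T, P_pa, kappa, np.zeros_like(T), aC, bC, a1, b1,
                         solute.Vsolid, Pc, kij, lij)
        if not np.all(np.isfinite(G)):
            return None
        X_req = np.log(y_exp / (1.0 - 2.0 * kappa * y_exp))
        d_pt = G - X_req  # per-point dF/(R T)
        dF_iso = []
        for T_i in iso_T:
            m = T == T_i
            gi, yi = G[m], y_exp[m]

            def of_d(d):
                y_cal = 1.0 / (np.exp(-(gi - d)) + 2.0 * kappa)
                return float(np.sum(np.abs(yi - y_cal) / yi))

            lo, hi = d_pt[m].min() - 1.0, d_pt[m].max() + 1.0
            res = optimize.minimize_scalar(of_d, bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-10})
            dF_iso.append(res.x * R * T_i)
        dF_iso = np.asarray(dF_iso)
        coef, *_ = np.linalg.lstsq(_basis(variant, iso_T), dF_iso, rcond=None)
        return np.concatenate([[kappa], coef])

    grid = np.geomspace(1e-3, 3.0, 25)
    candidates = [c for c in (stage1(k) for k in grid) if c is not None]
    candidates.sort(key=of)
    starts = candidates[:3]

    # stage 2: Nelder-Mead polish with seeded restarts around the incumbents
    rng = np.random.default_rng(seed)
    best_x, best_f = None, np.inf
    for s in starts:
        trials = [np.asarray(s, dtype=float)]
        for _ in range(max(0, n_starts - 1) // max(1, len(starts))):
            trials.append(s * (1.0 + 0.05 * rng.standard_normal(len(s))))
        for t0 in trials:
            res = optimize.minimize(
                of, t0, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
            )
            if res.fun < best_f:
                best_f, best_x = res.fun, res.x
    if best_x is None:
        raise RuntimeError("cluster fit failed from every start")
    res = optimize.minimize(
        of, best_x, method="Nelder-Mead",
        options={"maxiter": 6000, "xatol": 1e-12, "fatol": 1e-14},
    )
    if res.fun < best_f:
        best_f, best_x = res.fun, res.x

    y_cal = _predict_cluster(
        T, P_pa, _pack(variant, best_x), solute, solvent, kij, lij
    )
    return FitResult.from_prediction(
        f"cluster_{variant}", best_x, y_exp, y_cal, seed=seed,
        extra={"kij": kij, "lij": lij},
    )


def fit_cluster_both(
    data: SolubilityDataset,
    solute: ComponentSpec,
    solvent: ComponentSpec,
    seed: int = 42,
    n_starts: int = 8,
    inter: BinaryInteraction | None = None,
) -> dict[str, FitResult]:
    """Fit both variants; the Chen solution is re-embedded (b''=0) as an
    extra polish start for the four-parameter variant, so the richer model
    never fits worse than the nested one."""
    if inter is None:
        inter = fit_eos(
            data, solute, solvent, mode="t_independent", seed=seed
        ).interaction
    chen = fit_cluster(data, "chen", solute, solvent, seed=seed,
                       n_starts=n_starts, inter=inter)
    new = fit_cluster(data, "new", solute, solvent, seed=seed,
                      n_starts=n_starts, inter=inter)
    if new.aard_percent > chen.aard_percent:
        kij, lij = inter.kij, inter.lij
        T, P_pa, y_exp = data.T, data.P * 1e6, data.y2
        k, a_p, b_p = chen.params

        def of(theta):
            if theta[0] < 0:
                return 1e12
            y_cal = _predict_cluster(
                T, P_pa, _pack("new", theta), solute, solvent, kij, lij
            )
            bad = ~np.isfinite(y_cal) | (y_cal <= 0)
            rel = np.where(bad, 1e6,
                           np.abs(y_exp - np.where(bad, y_exp, y_cal)) / y_exp)
            return float(np.sum(rel))

        embed = np.array([k, a_p, 0.0, -b_p])
        res = optimize.minimize(
            of, embed, method="Nelder-Mead",
            options={"maxiter": 6000, "xatol": 1e-12, "fatol": 1e-14},
        )
        x = res.x if res.fun < of(embed) else embed
        y_cal = _predict_cluster(T, P_pa, _pack("new", x), solute, solvent, kij, lij)
        alt = FitResult.from_prediction(
            "cluster_new", x, y_exp, y_cal, seed=seed,
            extra={"kij": kij, "lij": lij},
        )
        if alt.aard_percent < new.aard_percent:
            new = alt
    return {"chen": chen, "new": new}


def reaction_thermo(params: ClusterParams, T: float) -> tuple[float, float]:
    """(dH_rxn, dS_rxn) of complex formation via Gibbs-Helmholtz on dF(T).

    Chen variant (dF = a' - b'*T read as dH - T*dS): dH = a', dS = b'.
    New variant: dH(T) = a'' - b''*T and dS(T) = -b''*(ln T + 1) - c''.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if isinstance(params, ChenParams):
        return params.a_prime, params.b_prime
    dH = params.a_dp - params.b_dp * T
    dS = -params.b_dp * (np.log(T) + 1.0) - params.c_dp
    return float(dH), float(dS)
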