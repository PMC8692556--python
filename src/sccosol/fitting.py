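"""Objective function, error metrics, information criteria, seeded
multistart optimisation, model ranking and enthalpy bookkeeping.

All regressions in the package minimise the summed absolute relative
deviation OF = sum(|y_exp - y_cal| / y_exp); quality is reported as
AARD% = 100 * OF / N.  Models with different parameter counts are ranked
by the small-sample corrected Akaike criterion computed from the raw
squared-error sum on mole fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .core import R, ComponentSpec, SolubilityDataset
from . import density

__all__ = [
    "objective",
    "aard_percent",
    "sse",
    "r_squared",
    "aic",
    "aicc",
    "FitResult",
    "fit_model",
    "fit_density_model",
    "rank_models",
    "EnthalpyReport",
    "enthalpy_report",
]


def _check_pair(y_exp, y_cal):
    y_exp = np.asarray(y_exp, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_exp.shape != y_cal.shape:
        raise ValueError("y_exp and y_cal must have the same length")
    if np.any(y_exp <= 0):
        raise ValueError("experimental mole fractions must be positive")
    return y_exp, y_cal


def objective(y_exp, y_cal) -> float:
    """Summed absolute relative deviation on mole fractions."""
    y_exp, y_cal = _check_pair(y_exp, y_cal)
    return float(np.sum(np.abs(y_exp - y_cal) / y_exp))


def aard_percent(y_exp, y_cal) -> float:
    """Average absolute relative deviation in percent: 100 * OF / N."""
    y_exp, _ = _check_pair(y_exp, y_cal)
    return 100.0 * objective(y_exp, y_cal) / y_exp.size


def sse(y_exp, y_cal) -> float:
    """Squared-error sum on raw mole fractions."""
    y_exp, y_cal = _check_pair(y_exp, y_cal)
    return float(np.sum((y_exp - y_cal) ** 2))


def r_squared(y_exp, y_cal) -> float:
    """1 - SSE / total sum of squares on raw mole fractions."""
    y_exp, y_cal = _check_pair(y_exp, y_cal)
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    return 1.0 - sse(y_exp, y_cal) / ss_tot if ss_tot > 0 else 1.0


def aic(sse_value: float, n: int, n_params: int) -> float:
    """AIC = N ln(SSE/N) + 2 Np."""
    if sse_value <= 0:
        raise ValueError("SSE must be positive for the log-likelihood proxy")
    return n * float(np.log(sse_value / n)) + 2 * n_params


def aicc(sse_value: float, n: int, n_params: int) -> float:
    """Small-sample corrected AIC; requires N > Np + 1."""
    if n <= n_params + 1:
        raise ValueError("AICc requires N > Np + 1")
    return aic(sse_value, n, n_params) + 2 * n_params * (n_params + 1) / (
        n - n_params - 1
    )


@dataclass
class FitResult:
    """Fitted parameter vector with the full metric set."""

    model_id: str
    params: np.ndarray
    aard_percent: float
    sse: float
    r2: float
    aic: float
    aicc: float
    n_points: int
    n_params: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = [float(p) for p in np.asarray(self.params).ravel()]
        return d

    @classmethod
    def from_prediction(
        cls, model_id, params, y_exp, y_cal, seed=None, extra=None
    ) -> "FitResult":
        params = np.asarray(params, dtype=float)
        s = sse(y_exp, y_cal)
        n, npar = np.asarray(y_exp).size, params.size
        return cls(
            model_id=model_id,
            params=params,
            aard_percent=aard_percent(y_exp, y_cal),
            sse=s,
            r2=r_squared(y_exp, y_cal),
            aic=aic(s, n, npar),
            aicc=aicc(s, n, npar),
            n_points=n,
            n_params=npar,
            seed=seed,
            extra=extra or {},
        )


def _penalised_of(predict_fn: Callable, y_exp: np.ndarray) -> Callable:
    def of(theta):
        y_cal = np.asarray(predict_fn(theta), dtype=float)
        if not np.all(np.isfinite(y_cal)):
            return 1e12
        return float(np.sum(np.abs(y_exp - y_cal) / y_exp))

    return of


def fit_model(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    data: SolubilityDataset,
    bounds: Sequence[tuple[float, float]],
    seed: int = 42,
    n_starts: int = 32,
    x0: np.ndarray | None = None,
    model_id: str = "custom",
) -> FitResult:
    """Seeded multistart minimisation of the relative-deviation objective.

    Starts are drawn one at a time from a seeded uniform sampler over the
    bounds (so enlarging ``n_starts`` only appends starts), optionally
    preceded by a caller-supplied ``x0`` and small relative perturbations of
    it; each start is polished with Nelder-Mead.  Deterministic for a given
    (seed, n_starts).
    """
    y_exp = data.y2
    of = _penalised_of(predict_fn, y_exp)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    if x0 is not None:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        starts.append(x0)
        for _ in range(3):
            starts.append(
                np.clip(x0 * (1.0 + 0.05 * rng.standard_normal(x0.size)), lo, hi)
            )
    for _ in range(n_starts):
        starts.append(lo + (hi - lo) * rng.random(lo.size))

    best_x, best_f = None, np.inf
    for s in starts:
        try:
            res = optimize.minimize(
                of,
                s,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
            )
        except Exception:
            continue
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    if best_x is None:
        raise RuntimeError("all optimisation starts failed")
    # second polish from the incumbent
    res = optimize.minimize(
        of,
        best_x,
        method="Nelder-Mead",
        bounds=list(zip(lo, hi)),
        options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-14},
    )
    if res.fun < best_f:
        best_f, best_x = res.fun, res.x
    y_cal = np.asarray(predict_fn(best_x), dtype=float)
    return FitResult.from_prediction(model_id, best_x, y_exp, y_cal, seed=seed)


def fit_density_model(
    model_id: str,
    data: SolubilityDataset,
    solvent: ComponentSpec,
    seed: int = 42,
    n_starts: int = 32,
) -> FitResult:
    """Fit one density model to a dataset.

    The multistart search is seeded with the exact linear least-squares
    solution of the model's log-linearised form, which for these correlations
    lands in the basin of the relative-deviation optimum.
    """
    spec = density.get_spec(model_id)
    T, P, rho1 = data.T, data.P, data.rho1
    x0 = density.linear_init(model_id, T, P, rho1, data.y2, solvent)

    def predict_fn(theta):
        return density.predict(density.ParamVector(model_id, theta), T, P, rho1, solvent)

    return fit_model(
        predict_fn,
        data,
        bounds=spec.bounds,
        seed=seed,
        n_starts=n_starts,
        x0=x0,
        model_id=model_id,
    )


def rank_models(results: Sequence[FitResult]) -> list[FitResult]:
    """Ascending AICc; ties broken by fewer parameters, then lower AARD."""
    if len(results) < 2:
        raise ValueError("ranking needs at least two fitted models")
    return sorted(
        results, key=lambda r: (r.aicc, r.n_params, r.aard_percent)
    )


@dataclass(frozen=True)
class EnthalpyReport:
    """One (total, sublimation, solvation) enthalpy triple in kJ/mol,
    with solvation = total - sublimation."""

    total_model: str
    sub_model: str
    dH_total: float
    dH_sub: float

    @property
    def dH_solv(self) -> float:
        return self.dH_total - self.dH_sub


def enthalpy_report(
    chrastil_E2: float,
    refchrastil_F2: float,
    bartle_B2: float,
    eos_coeffs,
    T_mean: float,
    eos_literal: bool = False,
) -> list[EnthalpyReport]:
    """Thermodynamic bookkeeping from the temperature coefficients.

    Total dissolution enthalpy comes from the Chrastil-type 1/T slopes
    (dH_total = -E2*R, -F2*R), sublimation enthalpy from the
    enhancement-factor slope (dH_sub = -B2*R) or from the EoS sublimation
    form evaluated at the mean experimental temperature; solvation enthalpy
    is the difference for each (total, sublimation) pairing.  kJ/mol.

    ``eos_literal=True`` selects the van't Hoff reading of the EoS
    sublimation form.  The default reading is only meaningful for the
    reference constant set: the three sublimation coefficients are nearly
    collinear over a narrow temperature window, and along that degenerate
    family only the van't Hoff slope is identified by data, so use the
    literal reading with freshly fitted coefficients.
    """
    from .eos import dhsub_eos  # local import to avoid a cycle

    totals = {
        "chrastil": -chrastil_E2 * R / 1000.0,
        "ref_chrastil": -refchrastil_F2 * R / 1000.0,
    }
    subs = {
        "bartle": -bartle_B2 * R / 1000.0,
        "pr_eos": dhsub_eos(eos_coeffs, T_mean, literal=eos_literal) / 1000.0,
    }
    return [
        EnthalpyReport(tm, sm, totals[tm], subs[sm])
        for tm in totals
        for sm in subs
    ]
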