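"""Synthetic solubility datasets for recovery experiments and testing.

The generator emulates the structure of the reference measurement campaign:
a 4-isotherm x 6-pressure grid of (T, P, rho1) states (308-338 K,
12-27 MPa) with mole fractions produced by a chosen model and perturbed by
multiplicative noise.  The default relative noise of 3% mirrors the ~1-5%
replicate standard deviations typical of vial-sampling solubility data.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np

from . import density
from .core import ComponentSpec, IsothermPoint, SolubilityDataset
from .data import load_clemastine_dataset, load_co2


def reference_grid() -> list[tuple[float, float, float]]:
    """The packaged (T, P, rho1) grid of the reference campaign."""
    return [(p.T, p.P, p.rho1) for p in load_clemastine_dataset()]


def generate_synthetic(
    model_id: str | Callable,
    params: Sequence[float],
    grid: Sequence[tuple[float, float, float]] | None = None,
    noise_rel: float = 0.03,
    seed: int = 0,
    noise: str = "gaussian",
    solvent: ComponentSpec | None = None,
    label: str = "synthetic",
) -> SolubilityDataset:
    """Model-generated solubilities with multiplicative noise.

    ``model_id`` is a density-model id, or any callable
    ``f(params, T, P, rho1) -> y2``.  y2 = prediction * (1 + eps) with eps
    Gaussian (default) or uniform of the given relative scale, clipped to
    keep y2 in (0, 1).  Deterministic per seed; grid points on which the
    model fails are dropped with a warning.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    if noise not in ("gaussian", "uniform"):
        raise ValueError("noise must be 'gaussian' or 'uniform'")
    if grid is None:
        grid = reference_grid()
    if solvent is None:
        solvent = load_co2()
    rng = np.random.default_rng(seed)
    if callable(model_id):
        predict = lambda T, P, rho: float(model_id(params, T, P, rho))  # noqa: E731
    else:
        pv = density.ParamVector(model_id, params)
        predict = lambda T, P, rho: float(  # noqa: E731
            density.predict(pv, T, P, rho, solvent)
        )
    points = []
    for T, P, rho1 in grid:
        eps = (
            noise_rel * rng.standard_normal()
            if noise == "gaussian"
            else noise_rel * rng.uniform(-1.0, 1.0)
        )
        try:
            y = predict(T, P, rho1) * (1.0 + eps)
        except Exception as exc:  # model failure on this state point
            warnings.warn(f"dropping grid point {(T, P, rho1)}: {exc}", stacklevel=2)
            continue
        if not np.isfinite(y) or y <= 0 or y >= 1:
            y = float(np.clip(y, 1e-300, 1.0 - 1e-12))
            if y <= 1e-300:
                warnings.warn(
                    f"dropping nonpositive prediction at {(T, P, rho1)}",
                    stacklevel=2,
                )
                continue
        points.append(IsothermPoint(T=T, P=P, rho1=rho1, y2=y))
    if not points:
        raise RuntimeError("model failed on every grid point")
    return SolubilityDataset(points, label=label)
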