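"""Saturation-binding fits for luciferase-fragment affinity measurements.

The large nanoluciferase fragment binds the tandem peptide tag produced by
interaction-induced splicing; its affinity and specificity are established
from equilibrium titrations of purified tagged protein. Readings are fit
to specific binding with a Hill slope,

    y(x) = baseline + bmax · x^h / (kd^h + x^h),

where ``kd`` is the half-saturation concentration in the input units and
``h`` the Hill coefficient. A companion check asks whether a titration
shows any binding at all, by an F-test of the Hill model against a flat
(constant) model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = ["BindingFit", "fit_specific_binding_hill", "flat_binder_check"]


@dataclass(frozen=True)
class BindingFit:
    kd: float
    hill: float
    bmax: float
    baseline: float
    sse: float
    converged: bool
    se: dict[str, float]

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.bmax < 0:
            raise ValueError("bmax must be non-negative")


def _hill_model(x: np.ndarray, kd: float, hill: float, bmax: float, baseline: float) -> np.ndarray:
    xh = x**hill
    return baseline + bmax * xh / (kd**hill + xh)


def _validate(concentrations: Sequence[float], luminescence: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(luminescence, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and luminescence must align")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite luminescence")
    if np.any(y < 0):
        raise ValueError("negative luminescence")
    distinct = np.unique(x)
    if distinct.size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.log10(distinct.max() / distinct.min()) < 2.0:
        raise ValueError("concentration range must span at least two decades")
    return x, y


def fit_specific_binding_hill(
    concentrations: Sequence[float],
    luminescence: Sequence[float],
    replicate_count: int = 1,
) -> BindingFit:
    """Least-squares Hill fit of a saturation-binding titration.

    ``kd`` is reported in the units of ``concentrations``. ``converged``
    is cleared when the optimizer fails or the optimum is pinned at a
    bound (no saturation inside the dosed range).
    """
    x, y = _validate(concentrations, luminescence)
    lo, hi = float(x.min()), float(x.max())
    kd0 = math.sqrt(lo * hi)
    p0 = (kd0, 1.0, float(y.max() - y.min()) or 1.0, float(y.min()))
    bounds = (
        [lo / 100.0, 0.1, 0.0, 0.0],
        [hi * 100.0, 5.0, np.inf, float(y.max()) + 1.0],
    )
    try:
        popt, pcov = optimize.curve_fit(
            _hill_model, x, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise RuntimeError(f"binding fit failed: {exc}") from exc
    resid = y - _hill_model(x, *popt)
    sse = float(resid @ resid)
    se_vals = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    names = ("kd", "hill", "bmax", "baseline")
    pinned = any(
        math.isclose(popt[i], bounds[0][i], rel_tol=1e-6, abs_tol=1e-12)
        or (np.isfinite(bounds[1][i]) and math.isclose(popt[i], bounds[1][i], rel_tol=1e-6))
        for i in (0, 1)
    )
    converged = bool(np.all(np.isfinite(se_vals))) and not pinned
    return BindingFit(
        kd=float(popt[0]),
        hill=float(popt[1]),
        bmax=float(popt[2]),
        baseline=float(popt[3]),
        sse=sse,
        converged=converged,
        se=dict(zip(names, (float(s) for s in se_vals))),
    )


def flat_binder_check(
    concentrations: Sequence[float],
    luminescence: Sequence[float],
    alpha: float = 0.01,
) -> bool:
    """True when a flat model is not rejected against the Hill model.

    Nested F-test: flat model (1 parameter, the mean) vs. the 4-parameter
    Hill model; ``True`` means "no significant binding". A conservative
    alpha of 0.01 is the default. Raises on degenerate residual variance
    (Hill SSE of zero with noisy data cannot happen; an exactly zero SSE
    makes the test inconclusive).
    """
    x, y = _validate(concentrations, luminescence)
    sse_flat = float(np.sum((y - y.mean()) ** 2))
    fit = fit_specific_binding_hill(concentrations, luminescence)
    df_full = y.size - 4
    if df_full <= 0:
        raise ValueError("not enough points for the nested F-test")
    if fit.sse <= 0:
        if sse_flat <= 0:
            raise ValueError("degenerate variance: F-test inconclusive")
        return False  # Hill fits perfectly, flat does not
    f_stat = ((sse_flat - fit.sse) / 3.0) / (fit.sse / df_full)
    p = float(stats.f.sf(max(f_stat, 0.0), 3, df_full))
    return p >= alpha
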