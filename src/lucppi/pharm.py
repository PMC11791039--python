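"""Dose–response pharmacology of PPI modulators.

Raw plate readings are anchored to assay controls: *floor* wells (no
induction, no compound) define 0% and *ceiling* wells (induction, no
compound) define 100%,

    S* = (S − S_F) / (S_C − S_F) · 100%.

Normalized responses are fit to four-parameter logistic (4PL) curves in
log10-dose space; the midpoint is EC50 (agonist) or IC50 (inhibitor).
Bivalent proximity inducers (molecular glues, PROTACs) can show a *hook*:
signal rises then falls as excess compound saturates each partner
separately. Hook detection fits a monotone 4PL against a bell model (a
product of rising and falling logistic phases) and prefers the bell only
when the small-sample-corrected Akaike criterion favors it decisively and
the fitted peak sits in the interior of the dosed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ModulatorPlate",
    "DoseResponseFit",
    "HookResult",
    "floor_ceiling_normalize",
    "fit_dose_response",
    "detect_hook",
    "signal_background_ratio",
]

HILL_BOUNDS = (0.2, 5.0)
HOOK_DELTA_AICC = 2.0


@dataclass(frozen=True)
class ModulatorPlate:
    """Raw readings for one treatment series plus its control wells."""

    doses: tuple[float, ...]
    readings: tuple[tuple[float, ...], ...]  # per dose, per replicate
    floor_readings: tuple[float, ...]
    ceiling_readings: tuple[float, ...]
    treatment: str = ""

    def __post_init__(self) -> None:
        if len(self.floor_readings) == 0 or len(self.ceiling_readings) == 0:
            raise ValueError("floor and ceiling readings must be non-empty")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if len(self.readings) != len(self.doses):
            raise ValueError("one reading group per dose required")


@dataclass(frozen=True)
class DoseResponseFit:
    kind: str  # agonist | inhibitor | bell
    top: float
    bottom: float
    log_mid: float  # rising/only midpoint, log10 molar
    hill: float
    converged: bool
    sse: float
    aicc: float
    ci95: dict[str, tuple[float, float]]
    se: dict[str, float]
    log_mid2: float | None = None  # bell falling midpoint
    hill2: float | None = None
    n: int = 0

    @property
    def ec50(self) -> float:
        """Midpoint on the linear molar scale (EC50 or IC50 by kind)."""
        return 10.0**self.log_mid

    ic50 = ec50


@dataclass(frozen=True)
class HookResult:
    is_biphasic: bool
    peak_dose: float | None
    model_preference: float  # AICc(sigmoid) − AICc(bell); >0 favors bell
    sigmoid_fit: DoseResponseFit | None = None
    bell_fit: DoseResponseFit | None = None
    inconclusive: bool = False


def floor_ceiling_normalize(plate: ModulatorPlate) -> list[tuple[float, ...]]:
    """Map raw wells to percent of the floor→ceiling dynamic range."""
    s_f = float(np.mean(plate.floor_readings))
    s_c = float(np.mean(plate.ceiling_readings))
    if s_c <= s_f:
        raise ValueError("ceiling does not exceed floor: assay did not induce")
    return [
        tuple(100.0 * (r - s_f) / (s_c - s_f) for r in group) for group in plate.readings
    ]


def _sigmoid(logx: np.ndarray, top: float, bottom: float, log_mid: float, hill: float, sign: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (sign * (log_mid - logx) * hill))


def _bell(
    logx: np.ndarray,
    top: float,
    bottom: float,
    log_mid: float,
    hill: float,
    log_mid2: float,
    hill2: float,
) -> np.ndarray:
    x = 10.0**logx
    m1, m2 = 10.0**log_mid, 10.0**log_mid2
    rise = x**hill / (x**hill + m1**hill)
    fall = m2**hill2 / (x**hill2 + m2**hill2)
    return bottom + (top - bottom) * rise * fall


def _aicc(sse: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to constants; k counts curve params + sigma
    k = k + 1
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(sse, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _flatten(doses: Sequence[float], responses) -> tuple[np.ndarray, np.ndarray]:
    logx, y = [], []
    for d, group in zip(doses, responses):
        vals = np.atleast_1d(np.asarray(group, dtype=float))
        logx.extend([math.log10(d)] * vals.size)
        y.extend(vals.tolist())
    return np.asarray(logx), np.asarray(y)


def fit_dose_response(
    doses: Sequence[float],
    responses,
    kind: str,
    conf_level: float = 0.95,
    weighting: str = "relative",
) -> DoseResponseFit:
    """Fit a 4PL (or bell) model to normalized responses.

    ``responses`` may be one value per dose or a replicate group per
    dose. Plate-luminescence noise is multiplicative (roughly constant
    CV), so the default ``weighting="relative"`` refines the unweighted
    optimum with two rounds of 1/fitted² reweighting — the
    maximum-likelihood weighting for constant relative error;
    ``weighting="none"`` keeps plain least squares. Confidence intervals
    are Wald intervals from the Jacobian at the optimum with a t
    critical value. A midpoint landing outside the dosed range clears
    ``converged``.
    """
    if kind not in ("agonist", "inhibitor", "bell"):
        raise ValueError(f"unknown kind {kind!r}")
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    doses = [float(d) for d in doses]
    if len(set(doses)) < (7 if kind == "bell" else 6):
        raise ValueError("not enough distinct dose levels for the fit")
    logx, y = _flatten(doses, responses)
    lo, hi = min(np.log10(doses)), max(np.log10(doses))
    span_pad = 2.0

    if kind == "bell":
        names = ("top", "bottom", "log_mid", "hill", "log_mid2", "hill2")
        p0 = (float(y.max()), float(y.min()), lo + (hi - lo) / 3.0, 1.0, lo + 2 * (hi - lo) / 3.0, 1.0)
        bounds = (
            [-np.inf, -np.inf, lo - span_pad, HILL_BOUNDS[0], lo - span_pad, HILL_BOUNDS[0]],
            [np.inf, np.inf, hi + span_pad, HILL_BOUNDS[1], hi + 2 * span_pad, HILL_BOUNDS[1]],
        )
        model = _bell
    else:
        names = ("top", "bottom", "log_mid", "hill")
        sign = 1.0 if kind == "agonist" else -1.0
        p0 = (float(y.max()), float(y.min()), (lo + hi) / 2.0, 1.0)
        bounds = (
            [-np.inf, -np.inf, lo - span_pad, HILL_BOUNDS[0]],
            [np.inf, np.inf, hi + span_pad, HILL_BOUNDS[1]],
        )
        model = lambda lx, t, b, m, h: _sigmoid(lx, t, b, m, h, sign)  # noqa: E731

    try:
        popt, pcov = optimize.curve_fit(model, logx, y, p0=p0, bounds=bounds, maxfev=20000)
        if weighting == "relative":
            for _ in range(2):
                yhat = model(logx, *popt)
                sigma = np.maximum(np.abs(yhat), 0.05 * np.max(np.abs(yhat)))
                popt, pcov = optimize.curve_fit(
                    model, logx, y, p0=popt, bounds=bounds, sigma=sigma, maxfev=20000
                )
        fit_ok = True
    except RuntimeError:
        popt = np.asarray(p0)
        pcov = np.full((len(p0), len(p0)), np.nan)
        fit_ok = False

    resid = y - model(logx, *popt)
    sse = float(resid @ resid)
    n = y.size
    dof = max(n - len(popt), 1)
    se_vals = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dof)
    ci = {
        nm: (float(p - tcrit * s), float(p + tcrit * s))
        for nm, p, s in zip(names, popt, se_vals)
    }
    params = dict(zip(names, (float(v) for v in popt)))
    in_range = bool(lo - 1e-9 <= params["log_mid"] <= hi + 1e-9)
    converged = bool(fit_ok and np.all(np.isfinite(se_vals)) and in_range)
    return DoseResponseFit(
        kind=kind,
        top=params["top"],
        bottom=params["bottom"],
        log_mid=params["log_mid"],
        hill=params["hill"],
        log_mid2=params.get("log_mid2"),
        hill2=params.get("hill2"),
        converged=converged,
        sse=sse,
        aicc=_aicc(sse, n, len(popt)),
        ci95=ci,
        se=dict(zip(names, (float(s) for s in se_vals))),
        n=n,
    )


def _bell_peak(fit: DoseResponseFit, lo: float, hi: float, n_grid: int = 20001) -> float:
    grid = np.linspace(lo, hi, n_grid)
    curve = _bell(grid, fit.top, fit.bottom, fit.log_mid, fit.hill, fit.log_mid2, fit.hill2)
    return float(10.0 ** grid[int(np.argmax(curve))])


def detect_hook(doses: Sequence[float], responses, delta_aicc: float = HOOK_DELTA_AICC) -> HookResult:
    """Classify a dose series as monotone or biphasic (hook effect).

    The bell model must beat the better monotone 4PL by more than
    ``delta_aicc`` AICc units, place its peak strictly inside the dosed
    range (below 0.8× the top dose), and decline by at least 10% of its
    amplitude from the peak to the top dose.
    """
    doses = [float(d) for d in doses]
    if len(set(doses)) < 7:
        raise ValueError("hook detection needs at least 7 dose levels")
    lo, hi = math.log10(min(doses)), math.log10(max(doses))
    fits: dict[str, DoseResponseFit | None] = {}
    # unweighted fits keep the AICc comparison on one common likelihood
    for kind in ("agonist", "inhibitor", "bell"):
        try:
            fits[kind] = fit_dose_response(doses, responses, kind, weighting="none")
        except (RuntimeError, ValueError):
            fits[kind] = None
    bell = fits["bell"]
    monotone = [f for f in (fits["agonist"], fits["inhibitor"]) if f is not None]
    if bell is None or not monotone:
        return HookResult(
            is_biphasic=False, peak_dose=None, model_preference=math.nan,
            inconclusive=True,
        )
    sig = min(monotone, key=lambda f: f.aicc)
    pref = sig.aicc - bell.aicc
    peak = _bell_peak(bell, lo, hi)
    amp = abs(bell.top - bell.bottom)
    curve_at_peak = float(
        _bell(np.log10([peak]), bell.top, bell.bottom, bell.log_mid, bell.hill,
              bell.log_mid2, bell.hill2)[0]
    )
    curve_at_max = float(
        _bell(np.asarray([hi]), bell.top, bell.bottom, bell.log_mid, bell.hill,
              bell.log_mid2, bell.hill2)[0]
    )
    interior = peak <= 0.8 * max(doses)
    # a claimed falling phase must be supported by dosed data: its midpoint
    # no more than half a decade past the top dose, its slope not pinned at
    # the bound (a pinned slope fits a single noise spike), and a decline
    # larger than the fit's own residual noise
    fall_supported = (
        lo - 1e-9 <= bell.log_mid2 <= hi + 0.5
        and bell.hill2 < 0.95 * HILL_BOUNDS[1]
    )
    rmse = math.sqrt(bell.sse / max(bell.n, 1))
    decline = curve_at_peak - curve_at_max
    declines = amp > 0 and decline >= max(0.1 * amp, 2.0 * rmse)
    is_biphasic = pref > delta_aicc and interior and fall_supported and declines
    return HookResult(
        is_biphasic=is_biphasic,
        peak_dose=peak if is_biphasic else None,
        model_preference=pref,
        sigmoid_fit=sig,
        bell_fit=bell,
    )


def signal_background_ratio(
    ceiling_readings: Sequence[float], floor_readings: Sequence[float]
) -> float:
    """Mean induced signal over mean background signal."""
    floor = float(np.mean(floor_readings))
    ceiling = float(np.mean(ceiling_readings))
    if floor <= 0:
        raise ValueError("floor mean must be positive")
    return ceiling / floor
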