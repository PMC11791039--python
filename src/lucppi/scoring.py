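"""Scoring of split-intein luciferase interaction screens.

A screened bait–prey pair contributes three well groups: the interaction
wells (both tagged proteins co-expressed) and two *handle* wells in which
each protein is co-expressed with an intein-only handle construct. The
handle luminescence proxies that protein's expression level, because
residual intein affinity splices at a rate proportional to protein
abundance.

Three scores are derived per pair, all in log10 units:

* ``s_raw``  — log10 mean interaction luminescence.
* ``s_norm`` — ``s_raw − s_bp`` where ``s_bp = s_b + s_p`` is the log
  expression product; equivalent to dividing the linear signal by the
  product of the two handle signals (second-order mass-action
  normalization).
* ``s_trans`` — ``s_raw − α − β·s_bp`` with (α, β) fitted by ordinary
  least squares to the *random* reference pairs only. Because the
  empirical background slope β is well below 1, this affine correction
  removes the expression-dependent non-specific splicing background more
  faithfully than dividing by the full expression product.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReferencePairRecord",
    "ScoredPair",
    "BackgroundRegression",
    "score_raw",
    "normalize",
    "fit_rrs_regression",
    "transform",
    "score_screen",
]

#: Fraction of the median reading used as a positive floor before logs.
EPSILON_FRACTION = 1e-6


@dataclass(frozen=True)
class ReferencePairRecord:
    """Raw luminescence for one bait–prey pair and its two handle wells."""

    pair_id: str
    bait: str
    prey: str
    interaction_readings: tuple[float, ...]
    b_handle_readings: tuple[float, ...]
    p_handle_readings: tuple[float, ...]
    label: str = "unknown"  # "PRS" | "RRS" | "unknown"

    def __post_init__(self) -> None:
        for name in ("interaction_readings", "b_handle_readings", "p_handle_readings"):
            vals = getattr(self, name)
            object.__setattr__(self, name, tuple(float(v) for v in vals))
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty for pair {self.pair_id!r}")
        if self.label not in ("PRS", "RRS", "unknown"):
            raise ValueError(f"label must be PRS, RRS or unknown, got {self.label!r}")


@dataclass(frozen=True)
class ScoredPair:
    """Log10-scale scores for one pair; ``s_norm``/``s_trans`` filled downstream."""

    pair_id: str
    label: str
    s_raw: float
    s_b: float
    s_p: float
    s_bp: float
    s_norm: float | None = None
    s_trans: float | None = None


@dataclass(frozen=True)
class BackgroundRegression:
    """OLS fit of RRS log-signal on the log expression product."""

    alpha: float
    beta: float
    r2: float
    n: int
    alpha_se: float = math.nan
    beta_se: float = math.nan

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("background regression needs at least 3 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of range: {self.r2}")


def _floored_mean(readings: Sequence[float], agg: str) -> float:
    x = np.asarray(readings, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite luminescence reading")
    eps = EPSILON_FRACTION * max(float(np.median(np.abs(x))), 1.0)
    if np.any(x <= 0):
        warnings.warn("non-positive reading floored before log", stacklevel=3)
        x = np.maximum(x, eps)
    if agg == "linear_mean":
        return float(np.log10(np.mean(x)))
    if agg == "log_mean":
        return float(np.mean(np.log10(x)))
    raise ValueError(f"unknown aggregation {agg!r}")


def score_raw(record: ReferencePairRecord, agg: str = "linear_mean") -> ScoredPair:
    """Aggregate replicates and return log10 raw, handle and product scores.

    Replicates are averaged in linear luminescence then logged (``agg =
    "linear_mean"``, the default); ``"log_mean"`` averages the log readings
    instead.
    """
    s_raw = _floored_mean(record.interaction_readings, agg)
    s_b = _floored_mean(record.b_handle_readings, agg)
    s_p = _floored_mean(record.p_handle_readings, agg)
    return ScoredPair(
        pair_id=record.pair_id,
        label=record.label,
        s_raw=s_raw,
        s_b=s_b,
        s_p=s_p,
        s_bp=s_b + s_p,
    )


def normalize(scored: ScoredPair) -> ScoredPair:
    """Expression-normalized score: subtract the log expression product."""
    return replace(scored, s_norm=scored.s_raw - scored.s_bp)


def fit_rrs_regression(scored_rrs: Iterable[ScoredPair]) -> BackgroundRegression:
    """OLS of ``s_raw`` on ``s_bp`` over random reference pairs.

    Random (non-interacting) pairs isolate the non-specific splicing
    background, so this line is the empirical background law. Positive
    pairs must never enter this calibration.
    """
    pairs = list(scored_rrs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 RRS pairs to fit the background regression")
    x = np.array([p.s_bp for p in pairs])
    y = np.array([p.s_raw for p in pairs])
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in s_bp: background regression is undefined")
    res = stats.linregress(x, y)
    return BackgroundRegression(
        alpha=float(res.intercept),
        beta=float(res.slope),
        r2=float(res.rvalue**2),
        n=len(pairs),
        alpha_se=float(res.intercept_stderr),
        beta_se=float(res.stderr),
    )


def transform(scored: ScoredPair, reg: BackgroundRegression) -> ScoredPair:
    """Background-transformed score: ``s_raw − α − β·s_bp``."""
    return replace(scored, s_trans=scored.s_raw - reg.alpha - reg.beta * scored.s_bp)


def score_screen(
    records: Iterable[ReferencePairRecord], agg: str = "linear_mean"
) -> tuple[list[ScoredPair], BackgroundRegression]:
    """Score a whole reference screen: raw + normalized + RRS-transformed.

    Returns the fully scored pairs (in input order) and the background
    regression fitted on the RRS subset.
    """
    scored = [normalize(score_raw(r, agg=agg)) for r in records]
    reg = fit_rrs_regression([s for s in scored if s.label == "RRS"])
    return [transform(s, reg) for s in scored], reg
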