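"""Synthetic split-intein luciferase screen and dose–response generator.

The generative model for a reference screen mirrors the statistical
structure the downstream analyses assume:

* each protein has a latent log10 expression level
  ``e ~ Normal(expr_log_mean, expr_log_sd)``;
* a handle well reads that expression plus measurement noise on the log
  scale;
* the non-specific splicing background of a pair is log-linear in the
  sum of the two log expressions (equivalently, linear in the log of the
  expression product): ``s_bg = bg_intercept + bg_slope·(e_B + e_P) + ε``;
* a detectable fraction of true-interacting pairs adds a lognormal
  interaction component on top of the background, additively in linear
  luminescence: ``linear_total = 10^s_bg · (1 + δ)``;
* every well is read in replicate with multiplicative Gaussian noise.

Dose–response plates are generated from four curve families: rising and
falling four-parameter logistics (molecular glue agonism, inhibitor
response), a bell product of a rising and a falling phase (hook effect of
bivalent proximity inducers), and a PROTAC variant of the bell whose
amplitude is scaled down unless proteasomal degradation is blocked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import ReferencePairRecord

__all__ = [
    "SimulationConfig",
    "SyntheticScreen",
    "DoseDesign",
    "simulate_reference_screen",
    "simulate_dose_response",
    "expected_dose_curve",
]

CURVE_KINDS = ("agonist", "inhibitor", "bell", "protac")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic reference screen.

    Defaults reproduce the study conditions of a 60-pair positive /
    80-pair random reference screen with an expression-dependent
    background whose coefficients match the empirically fitted
    background law (intercept −0.9426, slope 0.6678 in log10 units).
    """

    seed: int = 0
    n_prs: int = 60
    n_rrs: int = 80
    expr_log_mean: float = 2.5
    expr_log_sd: float = 0.6
    handle_noise_sd: float = 0.1
    bg_intercept: float = -0.9426
    bg_slope: float = 0.6678
    bg_resid_sd: float = 0.3
    detect_frac: float = 0.5
    effect_log_mean: float = 1.0
    effect_log_sd: float = 0.5
    n_replicates: int = 3
    rep_noise_cv: float = 0.1

    def __post_init__(self) -> None:
        for name in ("expr_log_sd", "handle_noise_sd", "bg_resid_sd",
                     "effect_log_sd", "rep_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.detect_frac <= 1.0:
            raise ValueError("detect_frac must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_prs < 0 or self.n_rrs < 0:
            raise ValueError("pair counts must be non-negative")


@dataclass(frozen=True)
class SyntheticScreen:
    """Simulator output: pair records plus hidden generative truth."""

    records: tuple[ReferencePairRecord, ...]
    truth: pd.DataFrame  # pair_id, label, e_b, e_p, effect_delta
    config: SimulationConfig

    def to_long_frame(self, include_label: bool = True) -> pd.DataFrame:
        """Canonical long-format table, one row per well."""
        rows = []
        for rec in self.records:
            groups = (
                ("interaction", rec.interaction_readings),
                ("B_handle", rec.b_handle_readings),
                ("P_handle", rec.p_handle_readings),
            )
            for role, readings in groups:
                for i, lum in enumerate(readings, start=1):
                    rows.append(
                        {
                            "pair_id": rec.pair_id,
                            "bait": rec.bait,
                            "prey": rec.prey,
                            "role": role,
                            "replicate": i,
                            "treatment": "",
                            "dose_molar": np.nan,
                            "luminescence": lum,
                            **({"label": rec.label} if include_label else {}),
                        }
                    )
        return pd.DataFrame(rows)


def _replicate_readings(
    rng: np.random.Generator, expected_linear: float, n: int, cv: float, eps: float
) -> tuple[float, ...]:
    vals = expected_linear * (1.0 + rng.normal(0.0, cv, size=n))
    vals = np.maximum(vals, eps)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite reading generated")
    return tuple(float(v) for v in vals)


def simulate_reference_screen(config: SimulationConfig) -> SyntheticScreen:
    """Draw a full synthetic reference screen with hidden truth.

    Identical ``config`` (including ``seed``) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_prs + config.n_rrs
    labels = ["PRS"] * config.n_prs + ["RRS"] * config.n_rrs

    e_b = rng.normal(config.expr_log_mean, config.expr_log_sd, size=n_total)
    e_p = rng.normal(config.expr_log_mean, config.expr_log_sd, size=n_total)
    handle_b = e_b + rng.normal(0.0, config.handle_noise_sd, size=n_total)
    handle_p = e_p + rng.normal(0.0, config.handle_noise_sd, size=n_total)
    s_bg = (
        config.bg_intercept
        + config.bg_slope * (e_b + e_p)
        + rng.normal(0.0, config.bg_resid_sd, size=n_total)
    )
    detected = rng.random(n_total) < config.detect_frac
    delta = 10.0 ** rng.normal(config.effect_log_mean, config.effect_log_sd, size=n_total)
    effect = np.where(
        (np.array(labels) == "PRS") & detected, delta, 0.0
    )

    lin_interaction = 10.0**s_bg * (1.0 + effect)
    lin_b = 10.0**handle_b
    lin_p = 10.0**handle_p
    eps = 1e-6 * float(np.median(np.concatenate([lin_interaction, lin_b, lin_p])))

    records = []
    truth_rows = []
    for i in range(n_total):
        label = labels[i]
        pid = f"{'P' if label == 'PRS' else 'R'}{i:04d}"
        rec = ReferencePairRecord(
            pair_id=pid,
            bait=f"B_{pid}",
            prey=f"P_{pid}",
            interaction_readings=_replicate_readings(
                rng, lin_interaction[i], config.n_replicates, config.rep_noise_cv, eps
            ),
            b_handle_readings=_replicate_readings(
                rng, lin_b[i], config.n_replicates, config.rep_noise_cv, eps
            ),
            p_handle_readings=_replicate_readings(
                rng, lin_p[i], config.n_replicates, config.rep_noise_cv, eps
            ),
            label=label,
        )
        records.append(rec)
        truth_rows.append(
            {
                "pair_id": pid,
                "label": label,
                "e_b": e_b[i],
                "e_p": e_p[i],
                "s_bg": s_bg[i],
                "effect_delta": effect[i],
            }
        )
    return SyntheticScreen(
        records=tuple(records), truth=pd.DataFrame(truth_rows), config=config
    )


@dataclass(frozen=True)
class DoseDesign:
    """Design of a synthetic modulator plate.

    ``top``/``bottom`` are expected raw luminescence at full and zero
    response. For ``bell`` and ``protac`` kinds the curve is the product
    of a rising phase (midpoint ``10**log_mid``) and a falling phase
    (midpoint ``10**log_mid2``); for ``protac`` the amplitude is further
    multiplied by ``degradation_factor`` unless ``proteasome_blocked``
    (degradation removes spliced reporter before it can be read, an
    effect relieved by proteasome inhibition).
    """

    doses: tuple[float, ...]
    curve_kind: str
    top: float = 100.0
    bottom: float = 0.0
    log_mid: float = -8.0  # log10 molar
    hill: float = 1.0
    log_mid2: float = -5.0  # falling-phase midpoint, bell/protac only
    hill2: float = 1.0
    degradation_factor: float = 0.25
    proteasome_blocked: bool = False
    noise_cv: float = 0.05
    n_replicates: int = 4
    seed: int = 0
    floor_level: float | None = None
    ceiling_level: float | None = None

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        if len(doses) == 0 or any(d <= 0 for d in doses):
            raise ValueError("doses must be strictly positive")
        if any(b >= a for a, b in zip(doses[1:], doses[:-1])):
            raise ValueError("doses must be sorted ascending")
        if self.curve_kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve_kind {self.curve_kind!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def expected_dose_curve(design: DoseDesign, doses: Sequence[float] | None = None) -> np.ndarray:
    """Noiseless expected luminescence at each dose."""
    x = np.asarray(design.doses if doses is None else doses, dtype=float)
    logx = np.log10(x)
    top, bot = design.top, design.bottom
    if design.curve_kind == "agonist":
        return bot + (top - bot) / (1.0 + 10.0 ** ((design.log_mid - logx) * design.hill))
    if design.curve_kind == "inhibitor":
        return bot + (top - bot) / (1.0 + 10.0 ** ((logx - design.log_mid) * design.hill))
    m1, m2 = 10.0**design.log_mid, 10.0**design.log_mid2
    rise = x**design.hill / (x**design.hill + m1**design.hill)
    fall = m2**design.hill2 / (x**design.hill2 + m2**design.hill2)
    amp = top - bot
    if design.curve_kind == "protac" and not design.proteasome_blocked:
        amp *= design.degradation_factor
    return bot + amp * rise * fall


def simulate_dose_response(design: DoseDesign) -> pd.DataFrame:
    """Generate a long-format dose–response plate.

    Includes ``floor`` wells (no induction, no compound) and ``ceiling``
    wells (induction, no compound) so the plate can be normalized exactly
    as a real one.
    """
    rng = np.random.default_rng(design.seed)
    expected = expected_dose_curve(design)
    floor = design.floor_level if design.floor_level is not None else design.bottom
    ceiling = design.ceiling_level if design.ceiling_level is not None else design.top
    eps = 1e-6 * max(float(np.median(np.abs(expected))), 1e-12)

    rows = []

    def emit(role: str, dose: float, mean_val: float) -> None:
        noise = rng.normal(0.0, design.noise_cv, size=design.n_replicates)
        for i, z in enumerate(noise, start=1):
            lum = mean_val * (1.0 + z)
            if mean_val == 0.0:
                lum = 0.0
            rows.append(
                {
                    "pair_id": "plate",
                    "role": role,
                    "replicate": i,
                    "treatment": design.curve_kind,
                    "dose_molar": dose,
                    "luminescence": max(float(lum), eps if mean_val > 0 else 0.0),
                }
            )

    emit("floor", np.nan, floor)
    emit("ceiling", np.nan, ceiling)
    for dose, mu in zip(design.doses, expected):
        emit("interaction", dose, mu)
    return pd.DataFrame(rows)
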