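"""Characterize proximity-inducing modulators: hook effect and degradation.

Simulates a molecular-glue dose series whose expected response peaks
near 3 uM (rising midpoint 1 uM, falling midpoint 10 uM) and verifies
the biphasic classifier recovers the peak; contrasts it with a monotone
glue series that must not be flagged. Then simulates PROTAC plates with
and without proteasome blockade and reports how blockade raises the
signal ceiling and the signal/background ratio.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lucppi import DoseDesign, detect_hook, expected_dose_curve, signal_background_ratio

GLUE_DOSES = tuple(np.logspace(-8, -4, 9))  # 10 nM - 100 uM


def glue_responses(rng, biphasic: bool):
    kind = "bell" if biphasic else "agonist"
    design = DoseDesign(doses=GLUE_DOSES, curve_kind=kind, top=100.0, bottom=0.0,
                        log_mid=-6.0, log_mid2=-5.0, noise_cv=0.05)
    mu = expected_dose_curve(design)
    return [m * (1 + rng.normal(0, 0.05, 4)) for m in mu]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    hook = detect_hook(GLUE_DOSES, glue_responses(rng, biphasic=True))
    mono = detect_hook(GLUE_DOSES, glue_responses(rng, biphasic=False))

    base = dict(doses=GLUE_DOSES, curve_kind="protac", top=1000.0, bottom=50.0,
                log_mid=-7.0, log_mid2=-5.5, noise_cv=0.0)
    degraded = expected_dose_curve(DoseDesign(**base, proteasome_blocked=False))
    blocked = expected_dose_curve(DoseDesign(**base, proteasome_blocked=True))
    sbr_degraded = signal_background_ratio([degraded.max()], [50.0])
    sbr_blocked = signal_background_ratio([blocked.max()], [50.0])

    report = {
        "glue_bell": {
            "is_biphasic": hook.is_biphasic,
            "peak_dose_uM": None if hook.peak_dose is None else hook.peak_dose * 1e6,
            "delta_aicc": hook.model_preference,
        },
        "glue_monotone": {
            "is_biphasic": mono.is_biphasic,
            "delta_aicc": mono.model_preference,
        },
        "protac": {
            "ceiling_degraded": float(degraded.max()),
            "ceiling_proteasome_blocked": float(blocked.max()),
            "signal_background_degraded": sbr_degraded,
            "signal_background_blocked": sbr_blocked,
        },
    }
    (args.out / "glue_protac.json").write_text(json.dumps(report, indent=2))

    peak = report["glue_bell"]["peak_dose_uM"]
    print(f"bell-shaped glue series: biphasic={hook.is_biphasic}, "
          f"peak={peak:.2f} uM (expected ~3.2 uM)" if peak else "bell series not flagged")
    print(f"monotone glue series: biphasic={mono.is_biphasic}")
    print(f"PROTAC ceiling {degraded.max():.0f} -> {blocked.max():.0f} a.u. when "
          f"proteasome is blocked (signal/background {sbr_degraded:.1f} -> {sbr_blocked:.1f})")


if __name__ == "__main__":
    main()
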