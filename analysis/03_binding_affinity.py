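"""Recover the luciferase-fragment binding affinity from titration data.

Simulates equilibrium titrations of the tandem peptide tag against the
large luciferase fragment (0.1-300 nM, 4 replicates, 5% CV) at a
generative Kd of 11.3 nM, fits the specific-binding Hill model, and
checks the flat-binder test on single-tag controls that carry no
binding signal.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lucppi import fit_specific_binding_hill, flat_binder_check

CONCS_NM = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0])
KD_TRUE = 11.3


def titration(rng, kd=KD_TRUE, bmax=1000.0, baseline=10.0, cv=0.05, reps=4):
    x = np.repeat(CONCS_NM, reps)
    mu = baseline + bmax * x / (kd + x)
    return x, mu * (1 + rng.normal(0, cv, x.size))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-repeats", type=int, default=50)
    ap.add_argument("--out", type=Path, default=Path("results/binding"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    x, y = titration(rng)
    fit = fit_specific_binding_hill(x, y, replicate_count=4)

    kds = []
    for k in range(args.n_repeats):
        xx, yy = titration(np.random.default_rng(args.seed * 1000 + k))
        kds.append(fit_specific_binding_hill(xx, yy).kd)

    rng_flat = np.random.default_rng(args.seed + 7)
    flat_y = 100.0 + rng_flat.normal(0, 3, CONCS_NM.size * 3)
    flat = flat_binder_check(np.tile(CONCS_NM, 3), flat_y)

    report = {
        "generative_kd_nM": KD_TRUE,
        "fitted": {"kd_nM": fit.kd, "hill": fit.hill, "bmax": fit.bmax,
                   "baseline": fit.baseline, "converged": fit.converged},
        "median_kd_nM_over_repeats": float(np.median(kds)),
        "n_repeats": args.n_repeats,
        "flat_control_called_nonbinder": bool(flat),
    }
    (args.out / "binding_fit.json").write_text(json.dumps(report, indent=2))

    print(f"single titration: Kd = {fit.kd:.2f} nM (true {KD_TRUE}), hill = {fit.hill:.2f}")
    print(f"median Kd over {args.n_repeats} repeats: {np.median(kds):.2f} nM")
    print(f"flat single-tag control called non-binder: {flat}")


if __name__ == "__main__":
    main()
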