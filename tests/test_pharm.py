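"""Floor/ceiling normalization, 4PL fits and hook-effect detection."""

import itertools

import numpy as np
import pytest

from lucppi import (
    DoseDesign,
    ModulatorPlate,
    detect_hook,
    expected_dose_curve,
    fit_dose_response,
    floor_ceiling_normalize,
    signal_background_ratio,
    simulate_dose_response,
)

DOSES8 = tuple(np.logspace(-9, -5, 8))
DOSES9 = tuple(np.logspace(-8, -4, 9))


def make_plate(doses, readings, floor=(200.0,) * 4, ceiling=(1200.0,) * 4):
    return ModulatorPlate(
        doses=tuple(doses),
        readings=tuple(tuple(np.atleast_1d(r)) for r in readings),
        floor_readings=floor,
        ceiling_readings=ceiling,
    )


class TestFloorCeilingNormalize:
    def test_anchors_and_midpoint(self):
        plate = make_plate((1e-9, 1e-8, 1e-7), [(200.0,), (700.0,), (1200.0,)])
        norm = floor_ceiling_normalize(plate)
        assert norm[0][0] == pytest.approx(0.0)
        assert norm[1][0] == pytest.approx(50.0)
        assert norm[2][0] == pytest.approx(100.0)

    def test_uninduced_assay_rejected(self):
        plate = make_plate((1e-9,), [(500.0,)], floor=(1000.0,), ceiling=(900.0,))
        with pytest.raises(ValueError, match="did not induce"):
            floor_ceiling_normalize(plate)


def sigmoid(x, top, bottom, log_mid, hill, sign):
    return bottom + (top - bottom) / (1 + 10 ** (sign * (log_mid - np.log10(x)) * hill))


class TestDoseResponseFit:
    @pytest.mark.parametrize("kind,sign", [("agonist", 1.0), ("inhibitor", -1.0)])
    def test_noiseless_midpoint_recovered_exactly(self, kind, sign):
        x = np.array(DOSES8)
        y = sigmoid(x, 100.0, 0.0, -7.3, 1.0, sign)
        fit = fit_dose_response(x, y, kind)
        assert fit.converged
        assert fit.log_mid == pytest.approx(-7.3, abs=1e-6)
        assert fit.ec50 == pytest.approx(10**-7.3, rel=1e-4)
        assert fit.top == pytest.approx(100.0, abs=1e-5)

    def test_optimum_beats_coarse_grid_oracle(self, rng):
        x = np.array(DOSES8)
        y = sigmoid(np.repeat(x, 4), 100.0, 0.0, -7.0, 1.0, -1.0)
        y = y + rng.normal(0, 3, y.size)
        groups = [y[4 * i : 4 * i + 4] for i in range(8)]
        fit = fit_dose_response(x, groups, "inhibitor", weighting="none")
        logx = np.log10(np.repeat(x, 4))
        yy = np.concatenate(groups)
        best = np.inf
        for lm, h in itertools.product(np.linspace(-9, -5, 40), np.linspace(0.3, 3, 15)):
            frac = 1 / (1 + 10 ** (-(lm - logx) * h))
            # given shape, (top,bottom) solve a 2-param linear LS
            A = np.column_stack([frac, 1 - frac])
            coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
            best = min(best, float(np.sum((yy - A @ coef) ** 2)))
        assert fit.sse <= best + 1e-6

    def test_wald_ci_brackets_truth_on_well_behaved_data(self, rng):
        x = np.array(DOSES8)
        y = sigmoid(np.repeat(x, 4), 100.0, 0.0, -7.0, 1.0, -1.0)
        y = y + rng.normal(0, 2, y.size)
        fit = fit_dose_response(x, [y[4 * i : 4 * i + 4] for i in range(8)], "inhibitor")
        lo, hi = fit.ci95["log_mid"]
        assert lo < -7.0 < hi

    def test_normalization_affine_invariance_of_midpoint(self):
        design = DoseDesign(doses=DOSES8, curve_kind="inhibitor", top=1200.0,
                            bottom=200.0, log_mid=-7.0, noise_cv=0.05, seed=4,
                            floor_level=200.0, ceiling_level=1200.0)
        df = simulate_dose_response(design)

        def fit_with_offset(offset):
            d = df.copy()
            d["luminescence"] += offset
            inter = d[d.role == "interaction"]
            plate = ModulatorPlate(
                doses=tuple(sorted(inter.dose_molar.unique())),
                readings=tuple(
                    tuple(inter[inter.dose_molar == dose].luminescence)
                    for dose in sorted(inter.dose_molar.unique())
                ),
                floor_readings=tuple(d.loc[d.role == "floor", "luminescence"]),
                ceiling_readings=tuple(d.loc[d.role == "ceiling", "luminescence"]),
            )
            return fit_dose_response(plate.doses, floor_ceiling_normalize(plate), "inhibitor")

        assert fit_with_offset(0.0).log_mid == pytest.approx(
            fit_with_offset(500.0).log_mid, abs=1e-6
        )

    def test_midpoint_outside_range_clears_converged(self):
        x = np.array(DOSES8)
        y = sigmoid(x, 100.0, 0.0, -3.0, 1.0, -1.0)  # midpoint above dosed range
        fit = fit_dose_response(x, y, "inhibitor")
        assert not fit.converged

    def test_recovery_across_many_noisy_plates(self):
        errs = []
        for seed in range(50):
            r = np.random.default_rng(3000 + seed)
            y = sigmoid(np.repeat(np.array(DOSES8), 4), 100.0, 0.0, -7.0, 1.0, -1.0)
            y = y * (1 + r.normal(0, 0.10, y.size))
            fit = fit_dose_response(DOSES8, [y[4 * i : 4 * i + 4] for i in range(8)], "inhibitor")
            errs.append(abs(fit.log_mid - (-7.0)))
        assert np.median(errs) <= 0.1

    def test_too_few_doses_and_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="dose levels"):
            fit_dose_response((1e-9, 1e-8, 1e-7, 1e-6, 1e-5), np.ones(5), "agonist")
        with pytest.raises(ValueError, match="unknown kind"):
            fit_dose_response(DOSES8, np.ones(8), "parabolic")


class TestHookDetection:
    def bell_responses(self, seed, doses=DOSES9, cv=0.05):
        # rising mid 1 uM, falling mid 10 uM -> peak at ~3.2 uM
        design = DoseDesign(doses=doses, curve_kind="bell", top=100.0, bottom=0.0,
                            log_mid=-6.0, log_mid2=-5.0, noise_cv=cv,
                            n_replicates=4, seed=seed)
        mu = expected_dose_curve(design)
        r = np.random.default_rng(seed)
        return [mu[i] * (1 + r.normal(0, cv, 4)) for i in range(len(doses))]

    def test_glue_hook_detected_with_peak_near_3_uM(self):
        res = detect_hook(DOSES9, self.bell_responses(seed=0))
        assert res.is_biphasic
        assert 1.5e-6 <= res.peak_dose <= 6e-6  # within 2-fold of 3 uM

    def test_peak_equals_fine_grid_argmax_of_fitted_curve(self):
        res = detect_hook(DOSES9, self.bell_responses(seed=1))
        bell = res.bell_fit
        grid = np.linspace(np.log10(min(DOSES9)), np.log10(max(DOSES9)), 50001)
        from lucppi.pharm import _bell

        curve = _bell(grid, bell.top, bell.bottom, bell.log_mid, bell.hill,
                      bell.log_mid2, bell.hill2)
        assert res.peak_dose == pytest.approx(10 ** grid[np.argmax(curve)], rel=1e-3)

    def test_monotone_sigmoid_not_called_biphasic(self, rng):
        mu = sigmoid(np.array(DOSES9), 100.0, 0.0, -6.0, 1.0, 1.0)
        responses = [mu[i] * (1 + rng.normal(0, 0.08, 4)) for i in range(9)]
        assert not detect_hook(DOSES9, responses).is_biphasic

    def test_needs_seven_dose_levels(self):
        with pytest.raises(ValueError, match="7 dose"):
            detect_hook(DOSES8[:6], np.ones(6))


class TestSignalBackgroundRatio:
    def test_hand_arithmetic_and_identity(self):
        assert signal_background_ratio([780.0] * 3, [100.0] * 3) == pytest.approx(7.8)
        assert signal_background_ratio([5.0, 5.0], [5.0]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = signal_background_ratio([700, 800], [90, 110])
        b = signal_background_ratio([7000, 8000], [900, 1100])
        assert a == pytest.approx(b)

    def test_zero_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            signal_background_ratio([100.0], [0.0])
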