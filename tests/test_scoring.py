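"""Raw/normalized/transformed scoring and the RRS background regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lucppi import (
    BackgroundRegression,
    ReferencePairRecord,
    fit_rrs_regression,
    normalize,
    score_raw,
    score_screen,
    transform,
)


def make_record(inter, b, p, label="RRS", pid="x"):
    return ReferencePairRecord(
        pair_id=pid, bait="b", prey="p",
        interaction_readings=tuple(inter),
        b_handle_readings=tuple(b),
        p_handle_readings=tuple(p),
        label=label,
    )


class TestScoreRaw:
    @pytest.mark.parametrize(
        "inter,b,p,s_raw,s_bp",
        [
            # triplicate of 100 everywhere: log10(100) = 2
            ((100, 100, 100), (100, 100, 100), (100, 100, 100), 2.0, 4.0),
            # replicates averaged in linear scale before the log
            ((50, 100, 150), (100, 100, 100), (100, 100, 100), 2.0, 4.0),
            # handle means 1e3 and 1e2: log product adds
            ((10, 10, 10), (1000, 1000, 1000), (100, 100, 100), 1.0, 5.0),
        ],
    )
    def test_hand_arithmetic(self, inter, b, p, s_raw, s_bp):
        sp = score_raw(make_record(inter, b, p))
        assert sp.s_raw == pytest.approx(s_raw, abs=1e-12)
        assert sp.s_bp == pytest.approx(s_bp, abs=1e-12)
        assert sp.s_bp == sp.s_b + sp.s_p

    def test_log_mean_aggregation_option(self):
        sp = score_raw(make_record((10, 1000), (100,), (100,)), agg="log_mean")
        assert sp.s_raw == pytest.approx(2.0)  # geometric mean of 10, 1000

    def test_zero_reading_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            sp = score_raw(make_record((0, 0, 0), (100,), (100,)))
        assert math.isfinite(sp.s_raw)

    def test_empty_readings_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_record((), (1,), (1,))


class TestNormalize:
    @given(
        s_i=st.floats(0.1, 1e6), s_b=st.floats(0.1, 1e6), s_p=st.floats(0.1, 1e6)
    )
    @settings(max_examples=60, deadline=None)
    def test_log_and_linear_forms_agree(self, s_i, s_b, s_p):
        sp = normalize(score_raw(make_record((s_i,), (s_b,), (s_p,))))
        assert 10.0**sp.s_norm == pytest.approx(s_i / (s_b * s_p), rel=1e-9)

    def test_hand_values(self):
        sp = normalize(score_raw(make_record((1e6,), (1e2,), (1e3,))))
        assert sp.s_norm == pytest.approx(1.0, abs=1e-12)
        same = normalize(score_raw(make_record((1e4,), (1e2,), (1e2,))))
        assert same.s_norm == pytest.approx(0.0, abs=1e-12)


class TestBackgroundRegression:
    def scored_line(self, xs, alpha, beta, label="RRS"):
        return [
            normalize(
                score_raw(
                    make_record(
                        (10 ** (alpha + beta * x),), (10 ** (x / 2),), (10 ** (x / 2),),
                        label=label, pid=f"r{i}",
                    )
                )
            )
            for i, x in enumerate(xs)
        ]

    def test_exact_line_recovered(self):
        scored = self.scored_line([1, 2, 3, 4, 6], alpha=1.0, beta=0.5)
        reg = fit_rrs_regression(scored)
        assert reg.alpha == pytest.approx(1.0, abs=1e-9)
        assert reg.beta == pytest.approx(0.5, abs=1e-9)
        assert reg.r2 == pytest.approx(1.0, abs=1e-12)

    def test_slope_matches_cov_over_var_summation(self, rng):
        xs = [1.0, 2.2, 3.1, 4.7, 6.0]
        ys = [0.8, 1.9, 2.2, 3.9, 4.1]
        scored = [
            normalize(score_raw(make_record((10**y,), (10 ** (x / 2),), (10 ** (x / 2),), pid=f"r{i}")))
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        reg = fit_rrs_regression(scored)
        # independent closed-form OLS by direct summation
        n = len(xs)
        xbar, ybar = sum(xs) / n, sum(ys) / n
        cov = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
        var = sum((x - xbar) ** 2 for x in xs)
        assert reg.beta == pytest.approx(cov / var, rel=1e-9)
        assert reg.alpha == pytest.approx(ybar - cov / var * xbar, rel=1e-9)

    def test_generative_coefficients_recovered_within_3_se(self):
        from lucppi import SimulationConfig, simulate_reference_screen

        cfg = SimulationConfig(seed=11, n_prs=0, n_rrs=80, handle_noise_sd=0.0,
                               rep_noise_cv=0.0)
        screen = simulate_reference_screen(cfg)
        scored = [normalize(score_raw(r)) for r in screen.records]
        reg = fit_rrs_regression(scored)
        assert abs(reg.beta - cfg.bg_slope) <= 3 * reg.beta_se
        assert abs(reg.alpha - cfg.bg_intercept) <= 3 * reg.alpha_se

    def test_zero_variance_and_too_few_points_fail(self):
        flat = self.scored_line([2, 2, 2], alpha=0, beta=1)
        with pytest.raises(ValueError, match="variance"):
            fit_rrs_regression(flat)
        with pytest.raises(ValueError, match="at least 3"):
            fit_rrs_regression(flat[:2])


class TestTransform:
    def test_identity_regression_reduces_to_normalization(self):
        reg = BackgroundRegression(alpha=0.0, beta=1.0, r2=1.0, n=3)
        sp = normalize(score_raw(make_record((123.0,), (45.0,), (67.0,))))
        assert transform(sp, reg).s_trans == pytest.approx(sp.s_norm, abs=1e-12)

    def test_empirical_coefficients_hand_arithmetic(self):
        reg = BackgroundRegression(alpha=-0.9426, beta=0.6678, r2=0.8, n=80)
        sp = normalize(score_raw(make_record((1e3,), (1e2,), (1e2,))))
        assert sp.s_raw == 3.0 and sp.s_bp == 4.0
        assert transform(sp, reg).s_trans == pytest.approx(1.2714, abs=1e-12)

    def test_rrs_residuals_centered_and_orthogonal(self, small_screen):
        scored, reg = score_screen(list(small_screen.records))
        rrs = [s for s in scored if s.label == "RRS"]
        resid = np.array([s.s_trans for s in rrs])
        x = np.array([s.s_bp for s in rrs])
        # OLS identities: residual mean zero, residuals orthogonal to regressor
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)
        assert float(resid @ (x - x.mean())) == pytest.approx(0.0, abs=1e-8)

    def test_affine_in_inputs_preserves_order_at_equal_sbp(self):
        reg = BackgroundRegression(alpha=0.3, beta=0.7, r2=0.9, n=10)
        lo = normalize(score_raw(make_record((100.0,), (10.0,), (10.0,))))
        hi = normalize(score_raw(make_record((500.0,), (10.0,), (10.0,))))
        assert transform(hi, reg).s_trans > transform(lo, reg).s_trans
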