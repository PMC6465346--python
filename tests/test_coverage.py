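import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from msytools import coverage as cov
from msytools import simulate as sim


class TestSampleProfile:
    def test_male_with_background_rejected(self):
        with pytest.raises(ValueError):
            cov.SampleProfile("m", "male", 20.0, 0.3)

    def test_background_must_be_far_below_diploid(self):
        with pytest.raises(ValueError):
            cov.SampleProfile("f", "female", 20.0, 10.0)
        cov.SampleProfile("f", "female", 20.0, 9.9)  # ok

    def test_c_positive(self):
        with pytest.raises(ValueError):
            cov.SampleProfile("m", "male", 0.0)


class TestDiploidCalibration:
    def test_constant_input(self):
        assert cov.estimate_diploid_calibration([30, 30, 30, 30]) == 30

    def test_plurality_bin(self):
        values = [30] * 10 + [60] * 5
        assert cov.estimate_diploid_calibration(values) == 30

    def test_poisson_draws_match_histogram_argmax(self):
        draws = np.random.default_rng(7).poisson(30, size=1000)
        # independent oracle: histogram argmax with unit bins on the same draws
        oracle = int(np.argmax(np.bincount(draws)))
        c = cov.estimate_diploid_calibration(draws)
        assert c == oracle
        assert 28 <= c <= 32

    def test_empty_and_all_zero_error(self):
        with pytest.raises(ValueError):
            cov.estimate_diploid_calibration([])
        with pytest.raises(ValueError):
            cov.estimate_diploid_calibration([0, 0, 0])

    def test_tie_breaks_to_smaller_bin(self):
        assert cov.estimate_diploid_calibration([10, 10, 20, 20]) == 10


class TestFemaleBackground:
    def test_mean(self):
        assert cov.estimate_female_background([0, 0, 1, 0, 0, 0, 0, 0, 0, 1]) == pytest.approx(0.2)

    def test_all_zero(self):
        assert cov.estimate_female_background([0.0] * 5) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cov.estimate_female_background([])

    def test_simulated_background_recovered(self):
        draws = np.random.default_rng(5).poisson(0.3, size=5000)
        b = cov.estimate_female_background(draws)
        assert 0.27 <= b <= 0.33


class TestWindowModels:
    def test_single_pair_mles(self, one_male_one_female):
        w = cov.WindowRecord("c", 0, 50, {"m1": 10.0, "f1": 0.0})
        v_hat, mu_hat = cov.fit_window_models(w, one_male_one_female)
        assert v_hat == pytest.approx(1.0)
        assert mu_hat == pytest.approx(0.25)

    def test_all_zero_coverage(self, one_male_one_female):
        w = cov.WindowRecord("c", 0, 50, {"m1": 0.0, "f1": 0.0})
        assert cov.fit_window_models(w, one_male_one_female) == (0.0, 0.0)

    def test_two_by_two(self):
        profiles = [
            cov.SampleProfile("m1", "male", 20.0),
            cov.SampleProfile("m2", "male", 20.0),
            cov.SampleProfile("f1", "female", 20.0, 0.2),
            cov.SampleProfile("f2", "female", 20.0, 0.2),
        ]
        w = cov.WindowRecord("c", 0, 50, {"m1": 10.0, "m2": 10.0, "f1": 10.0, "f2": 10.0})
        v_hat, mu_hat = cov.fit_window_models(w, profiles)
        assert v_hat == pytest.approx(1.0)
        assert mu_hat == pytest.approx(0.5)

    def test_single_sex_errors(self):
        males = [cov.SampleProfile("m1", "male", 20.0)]
        w = cov.WindowRecord("c", 0, 50, {"m1": 10.0})
        with pytest.raises(ValueError):
            cov.fit_window_models(w, males)


class TestWindowLogLR:
    def test_msy_like_window(self, one_male_one_female):
        w = cov.WindowRecord("c", 0, 50, {"m1": 10.0, "f1": 0.0})
        fit = cov.window_log_lr(w, one_male_one_female)
        assert fit.log_lr == pytest.approx(10 * math.log(2) - 0.2, abs=1e-9)
        assert fit.posterior_msy == pytest.approx(0.9988, abs=1e-4)

    def test_nonmsy_like_window(self, one_male_one_female):
        w = cov.WindowRecord("c", 0, 50, {"m1": 20.0, "f1": 20.0})
        fit = cov.window_log_lr(w, one_male_one_female)
        assert fit.log_lr == pytest.approx(20 * math.log(0.01) + 19.8, abs=1e-9)
        assert fit.posterior_msy == pytest.approx(0.0, abs=1e-9)

    def test_equal_likelihoods_give_half(self):
        # female y at its nonMSY expectation with b == mu_hat * c makes the
        # female terms identical; the male sits at equality too when v*c/2 == mu*c
        profiles = [
            cov.SampleProfile("m1", "male", 20.0),
            cov.SampleProfile("f1", "female", 20.0, 5.0),
        ]
        w = cov.WindowRecord("c", 0, 50, {"m1": 5.0, "f1": 5.0})
        # v_hat = 0.5 -> male rate 5; mu_hat = 0.25 -> rates 5 and 5; b = 5
        fit = cov.window_log_lr(w, profiles)
        assert fit.log_lr == pytest.approx(0.0, abs=1e-12)
        assert fit.posterior_msy == pytest.approx(0.5)

    def test_zero_background_with_female_coverage_is_floored(self):
        profiles = [
            cov.SampleProfile("m1", "male", 20.0),
            cov.SampleProfile("f1", "female", 20.0, 0.0),
        ]
        w = cov.WindowRecord("c", 0, 50, {"m1": 10.0, "f1": 1.0})
        fit = cov.window_log_lr(w, profiles)
        assert math.isfinite(fit.log_lr)
        assert fit.posterior_msy == pytest.approx(0.0, abs=1e-12)

    def test_oracle_literal_poisson_ratio(self, one_male_one_female):
        # independent oracle: the transcribed likelihood ratio with factorial
        # terms included on both sides (they cancel)
        rng = np.random.default_rng(42)
        for _ in range(50):
            ym, yf = int(rng.integers(0, 30)), int(rng.integers(0, 5))
            w = cov.WindowRecord("c", 0, 50, {"m1": float(ym), "f1": float(yf)})
            v_hat, mu_hat = cov.fit_window_models(w, one_male_one_female)
            if v_hat == 0 or mu_hat == 0:
                continue
            num = poisson.logpmf(ym, v_hat * 20 / 2) + poisson.logpmf(yf, 0.2)
            den = poisson.logpmf(ym, mu_hat * 20) + poisson.logpmf(yf, mu_hat * 20)
            fit = cov.window_log_lr(w, one_male_one_female)
            assert fit.log_lr == pytest.approx(float(num - den), abs=1e-9)

    @given(
        ym=st.floats(0, 60),
        yf=st.floats(0, 10),
        cm=st.floats(5, 60),
        cf=st.floats(5, 60),
        b=st.floats(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_posterior_bounds(self, ym, yf, cm, cf, b):
        profiles = [
            cov.SampleProfile("m1", "male", cm),
            cov.SampleProfile("f1", "female", cf, b),
        ]
        w = cov.WindowRecord("c", 0, 50, {"m1": ym, "f1": yf})
        fit = cov.window_log_lr(w, profiles)
        assert 0.0 <= fit.posterior_msy <= 1.0
        if math.isfinite(fit.log_lr):
            expected = 1.0 / (1.0 + math.exp(-min(max(fit.log_lr, -700), 700)))
            assert fit.posterior_msy == pytest.approx(expected, abs=1e-12)

    def test_female_coverage_monotonicity(self):
        # increasing a female's y strictly decreases log_lr whenever b < mu*c;
        # checked analytically (d/dy = ln b - ln mu*c < 0) vs finite differences
        profiles = [
            cov.SampleProfile("m1", "male", 20.0),
            cov.SampleProfile("f1", "female", 20.0, 0.2),
        ]
        for yf in [1.0, 3.0, 7.0]:
            eps = 1e-4
            w_lo = cov.WindowRecord("c", 0, 50, {"m1": 10.0, "f1": yf})
            w_hi = cov.WindowRecord("c", 0, 50, {"m1": 10.0, "f1": yf + eps})
            # hold the MLEs fixed at the lower point to isolate the partial
            v_hat, mu_hat = cov.fit_window_models(w_lo, profiles)
            assert 0.2 < mu_hat * 20
            lo = cov.window_log_lr(w_lo, profiles).log_lr
            hi = cov.window_log_lr(w_hi, profiles).log_lr
            assert hi < lo
            # sign of the analytic partial matches the finite difference
            analytic = math.log(0.2) - math.log(mu_hat * 20)
            assert (hi - lo) < 0 and analytic < 0

    def test_analytic_derivative_sign_matches_finite_differences(self):
        # by the envelope theorem the derivative of the profile log-LR in a
        # sample's y is ln(rate under MSY) - ln(rate under nonMSY) at the MLEs
        profiles = [
            cov.SampleProfile("m1", "male", 20.0),
            cov.SampleProfile("f1", "female", 20.0, 0.2),
        ]
        eps = 1e-5
        for ym in [5.0, 10.0, 18.0]:
            for yf in [0.5, 2.0, 6.0]:
                w = cov.WindowRecord("c", 0, 50, {"m1": ym, "f1": yf})
                v_hat, mu_hat = cov.fit_window_models(w, profiles)
                base = cov.window_log_lr(w, profiles).log_lr

                w_m = cov.WindowRecord("c", 0, 50, {"m1": ym + eps, "f1": yf})
                fd_m = (cov.window_log_lr(w_m, profiles).log_lr - base) / eps
                analytic_m = math.log(v_hat * 20 / 2) - math.log(mu_hat * 20)
                assert fd_m == pytest.approx(analytic_m, abs=1e-3)

                w_f = cov.WindowRecord("c", 0, 50, {"m1": ym, "f1": yf + eps})
                fd_f = (cov.window_log_lr(w_f, profiles).log_lr - base) / eps
                analytic_f = math.log(0.2) - math.log(mu_hat * 20)
                assert fd_f == pytest.approx(analytic_f, abs=1e-3)
                # increasing female coverage always pushes away from MSY
                # whenever b < mu_hat * c
                if 0.2 < mu_hat * 20:
                    assert fd_f < 0


class TestClassifyWindows:
    @staticmethod
    def _profiles():
        return [
            cov.SampleProfile("m1", "male", 20.0),
            cov.SampleProfile("f1", "female", 20.0, 0.2),
        ]

    def test_scy_label(self):
        w = cov.WindowRecord("c", 0, 50, {"m1": 10.0, "f1": 0.0})
        (wc,) = cov.classify_windows([w], self._profiles())
        assert wc.label == "scY"
        assert wc.fit.male_rel_cov == pytest.approx(0.5)

    def test_mcy_label(self):
        w = cov.WindowRecord("c", 0, 50, {"m1": 36.0, "f1": 0.0})
        (wc,) = cov.classify_windows([w], self._profiles())
        assert wc.label == "mcY"
        assert wc.fit.male_rel_cov == pytest.approx(1.8)

    def test_nonmsy_label(self):
        w = cov.WindowRecord("c", 0, 50, {"m1": 20.0, "f1": 20.0})
        (wc,) = cov.classify_windows([w], self._profiles())
        assert wc.label == "nonMSY"

    def test_missing_sample_named_in_error(self):
        w = cov.WindowRecord("c", 0, 50, {"m1": 10.0})
        with pytest.raises(KeyError, match="f1"):
            cov.classify_windows([w], self._profiles())

    def test_short_windows_dropped(self):
        w_short = cov.WindowRecord("c", 0, 5, {"m1": 10.0, "f1": 0.0})
        w_ok = cov.WindowRecord("c", 5, 55, {"m1": 10.0, "f1": 0.0})
        out = cov.classify_windows([w_short, w_ok], self._profiles())
        assert len(out) == 1 and out[0].window.start == 5

    def test_scale_consistency(self, small_coverage_sim):
        windows, profiles, labels = small_coverage_sim
        config = cov.ClassifierConfig()
        base = cov.classify_windows(windows, profiles, config)
        scaled_profiles = [
            cov.SampleProfile(p.sample_id, p.sex, 3.0 * p.c,
                              None if p.b is None else 3.0 * p.b)
            for p in profiles
        ]
        scaled_windows = [
            cov.WindowRecord(w.contig, w.start, w.end,
                             {s: 3.0 * v for s, v in w.y.items()})
            for w in windows
        ]
        scaled = cov.classify_windows(scaled_windows, scaled_profiles, config)
        for a, b in zip(base, scaled):
            if abs(a.fit.log_lr) > 5:
                assert a.label == b.label


class TestFilterContigs:
    @staticmethod
    def _classes(contig, labels, window=50):
        profiles_fit = cov.WindowFit(1.0, 0.1, 10.0, 0.99, 0.5)
        out = []
        for i, lab in enumerate(labels):
            w = cov.WindowRecord(contig, i * window, (i + 1) * window,
                                 {"m1": 10.0, "f1": 0.0})
            out.append(cov.WindowClass(w, lab, profiles_fit))
        return out

    def test_kept_above_both_thresholds(self):
        classes = self._classes("c1", ["scY"] * 12 + ["nonMSY"] * 8)
        kept, summaries = cov.filter_contigs(classes, {"c1": 1000})
        assert kept == {"c1"}
        assert summaries["c1"].scY_bp == 600
        assert summaries["c1"].nonMSY_bp == 400

    def test_short_contig_discarded(self):
        classes = self._classes("c1", ["scY"] * 5)
        kept, _ = cov.filter_contigs(classes, {"c1": 250})
        assert kept == set()

    def test_length_300_boundary_kept(self):
        classes = self._classes("c1", ["scY"] * 6)
        kept, _ = cov.filter_contigs(classes, {"c1": 300})
        assert kept == {"c1"}

    def test_low_y_content_discarded(self):
        classes = self._classes("c1", ["scY"] * 8 + ["nonMSY"] * 12)
        kept, _ = cov.filter_contigs(classes, {"c1": 1000})
        assert kept == set()

    def test_45_percent_boundary_kept(self):
        classes = self._classes("c1", ["mcY"] * 9 + ["nonMSY"] * 11)
        kept, _ = cov.filter_contigs(classes, {"c1": 1000})
        assert kept == {"c1"}

    def test_zero_window_contig_discarded_with_warning(self, caplog):
        classes = self._classes("c1", ["scY"] * 6)
        with caplog.at_level("WARNING"):
            kept, _ = cov.filter_contigs(classes, {"c1": 300, "ghost": 5000})
        assert kept == {"c1"}
        assert any("ghost" in r.message for r in caplog.records)


class TestRecovery:
    def test_two_pass_background_estimation(self, small_coverage_sim):
        windows, profiles, labels = small_coverage_sim
        blind = [
            p if p.is_male else cov.SampleProfile(p.sample_id, p.sex, p.c)
            for p in profiles
        ]
        calibrated = cov.estimate_backgrounds_two_pass(windows, blind)
        for p in calibrated:
            if not p.is_male:
                assert p.b == pytest.approx(0.3, abs=0.1)

    def test_seed_window_error_when_empty(self):
        with pytest.raises(ValueError, match="seed"):
            cov.estimate_female_background([])
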