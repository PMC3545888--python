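"""Standard curves, absolute quantification, phases and doubling arithmetic."""

import numpy as np
import pytest

from baculokit.errors import BaculokitError, FitError
from baculokit.replication_kinetics import (NormalizedSeries, StandardCurve,
                                            analyze_experiment,
                                            annotate_phases,
                                            fit_standard_curve,
                                            kinetics_summary, normalize,
                                            quantify)
from baculokit.synthetic_data import (GeneratorConfig, QpcrConfig,
                                      simulate_qpcr_experiment)

PERFECT_SLOPE = -3.3219  # 10^(1/3.3219) = 2: one doubling per cycle


class TestStandardCurve:
    def test_analytic_fit(self):
        lg = np.arange(3, 9, dtype=float)
        ct = PERFECT_SLOPE * lg + 35.0
        curve = fit_standard_curve(lg, ct)
        assert curve.slope == pytest.approx(PERFECT_SLOPE)
        assert curve.intercept == pytest.approx(35.0)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)

    def test_noisy_slope_within_3_percent(self, rng):
        lg = np.repeat(np.arange(2, 9, dtype=float), 1)
        ct = PERFECT_SLOPE * lg + 35.0 + rng.normal(0, 0.2, size=lg.size)
        curve = fit_standard_curve(lg, ct)
        assert abs(curve.slope - PERFECT_SLOPE) / abs(PERFECT_SLOPE) < 0.03

    def test_replicates_averaged_on_ct_scale(self):
        lg = np.arange(3, 7, dtype=float)
        base = PERFECT_SLOPE * lg + 35.0
        reps = np.stack([base - 0.5, base, base + 0.5], axis=1)
        curve = fit_standard_curve(lg, reps)
        assert curve.intercept == pytest.approx(35.0)

    def test_too_few_points(self):
        with pytest.raises(FitError, match="at least 3"):
            fit_standard_curve([3, 4], [25.0, 22.0])

    def test_degenerate_copies(self):
        with pytest.raises(FitError, match="variance"):
            fit_standard_curve([5, 5, 5], [25.0, 25.1, 24.9])


class TestQuantify:
    def test_ct_at_intercept_is_one_copy(self):
        c = StandardCurve(PERFECT_SLOPE, 35.0, 1.0)
        assert quantify(c, 35.0) == pytest.approx(1.0)

    def test_closed_form(self):
        c = StandardCurve(PERFECT_SLOPE, 35.0, 1.0)
        assert quantify(c, 35.0 + PERFECT_SLOPE * 5) == pytest.approx(1e5)

    def test_fit_quantify_roundtrip_noiseless(self):
        lg = np.arange(2, 10, dtype=float)
        curve = fit_standard_curve(lg, PERFECT_SLOPE * lg + 38.0)
        for copies in 10.0 ** lg:
            ct = PERFECT_SLOPE * np.log10(copies) + 38.0
            assert quantify(curve, ct) == pytest.approx(copies, rel=1e-9)


class TestNormalize:
    def test_scale_invariance(self):
        for k in (1.0, 3.7, 1e4):
            s = normalize([452.0 * k], [1e5 * k])
            assert s.values[0] == pytest.approx(452.0)

    def test_identity_ratio(self):
        s = normalize([123.0], [123.0], per=1e5)
        assert s.values[0] == pytest.approx(1e5)

    def test_zero_actin_names_time_point(self):
        with pytest.raises(BaculokitError, match="24"):
            normalize([1.0, 2.0], [1e5, 0.0], times=[12.0, 24.0])


class TestPhases:
    def test_constant_series_all_latent(self):
        s = NormalizedSeries(np.arange(5.0), np.full(5, 100.0))
        assert annotate_phases(s).phase_labels == ["latent"] * 4

    def test_canonical_four_phase_trajectory(self):
        times = np.array([0.0, 4.0, 12.0, 24.0, 36.0, 48.0, 96.0])
        v = [1356.0, 452.0, 452.0]
        for t0, t1 in ((12, 24), (24, 36), (36, 48)):
            v.append(v[-1] * 2 ** (0.8 * (t1 - t0)))
        v.append(v[-1] * 4.82)
        s = annotate_phases(NormalizedSeries(times, np.array(v)))
        assert s.phase_labels == ["decreasing", "latent", "exponential",
                                  "exponential", "exponential", "stationary"]

    def test_strictly_decreasing(self):
        s = NormalizedSeries(np.arange(4.0), np.array([8.0, 4.0, 2.0, 1.0]))
        assert annotate_phases(s).phase_labels == ["decreasing"] * 3

    def test_unordered_times_rejected(self):
        s = NormalizedSeries(np.array([0.0, 2.0, 1.0]), np.ones(3))
        with pytest.raises(BaculokitError, match="increasing"):
            annotate_phases(s)

    def test_too_few_points_rejected(self):
        s = NormalizedSeries(np.array([0.0]), np.array([1.0]))
        with pytest.raises(BaculokitError, match="3 time points"):
            annotate_phases(s)


class TestKineticsSummary:
    def test_published_window_arithmetic(self):
        """452 -> 2.02e11 per 1e5 actin over 12-48 h: ~4.47e8-fold,
        29 doublings, 1.24 h per doubling."""
        s = NormalizedSeries(np.array([12.0, 48.0]),
                             np.array([452.0, 2.02e11]))
        out = kinetics_summary(s, (12.0, 48.0))
        assert out.fold_change == pytest.approx(4.469e8, rel=1e-3)
        assert out.rounded_doublings == 29
        assert out.rounded_doubling_time == pytest.approx(36 / 29, abs=1e-9)
        assert round(out.rounded_doubling_time, 2) == 1.24

    def test_doubling_closed_form(self):
        s = NormalizedSeries(np.array([0.0, 1.0]), np.array([5.0, 10.0]))
        out = kinetics_summary(s, (0.0, 1.0))
        assert out.doublings == pytest.approx(1.0)
        assert out.doubling_time == pytest.approx(1.0)

    def test_flat_window_degenerate(self):
        s = NormalizedSeries(np.array([0.0, 1.0]), np.array([5.0, 5.0]))
        out = kinetics_summary(s, (0.0, 1.0))
        assert out.doublings == 0 and out.doubling_time is None


class TestFullPipeline:
    def test_noiseless_roundtrip_exact(self):
        cfg = GeneratorConfig(seed=3, qpcr=QpcrConfig(ct_noise_sd=0.0))
        std, samp, truth = simulate_qpcr_experiment(cfg)
        res = analyze_experiment(std, samp)
        assert np.allclose(res["series"].values, truth.per_actin, rtol=1e-9)
        assert res["summary"].window == (12.0, 48.0)
        assert res["summary"].rounded_doublings == 29

    def test_phases_detected_under_noise(self):
        cfg = GeneratorConfig(seed=9)
        std, samp, _ = simulate_qpcr_experiment(cfg)
        res = analyze_experiment(std, samp)
        labels = res["series"].phase_labels
        assert labels[0] == "decreasing"
        assert "exponential" in labels
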