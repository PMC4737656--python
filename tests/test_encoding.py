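"""Tuning curves, linear-encoding fits, directionality, encoding range."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import whiskcode as wc
from whiskcode.encoding import (
    directionality_index,
    directionality_ratio,
    encoding_range_stats,
    fit_linear_encoding,
    tuning_curve,
)
from whiskcode.spikes import RateSeries


@pytest.fixture(scope="module")
def encoding_session():
    cfg = wc.SimConfig(duration=600.0, seed=21, gain=15.0,
                       direction_mode="bidirectional", latency=0.0)
    s = wc.simulate_session(cfg)
    ep = wc.segment_epochs(s.kin)
    return s, ep, cfg


class TestDirectionalityIndex:
    def test_exact_formula_examples(self):
        assert directionality_index(10.0, -5.0) == pytest.approx(0.5)
        assert directionality_index(12.0, 0.0) == 0.0
        assert directionality_index(7.5, -7.5) == pytest.approx(1.0)

    @given(st.floats(-200, 200), st.floats(-200, 200))
    def test_bounded_and_symmetric(self, a, b):
        r = directionality_index(a, b)
        assert 0.0 <= r <= 1.0
        assert r == pytest.approx(directionality_index(b, a))


class TestTuningCurve:
    def test_occupancy_conservation(self, encoding_session):
        s, ep, _ = encoding_session
        curve = tuning_curve(s.spikes, s.kin, ep)
        assert curve.occupancy.sum() == pytest.approx(ep.total("whisking"),
                                                      abs=2e-3)

    def test_constant_rate_cell_flat_curve(self, encoding_session):
        s, ep, _ = encoding_session
        flat = RateSeries(fs=1000.0, rate=np.full(s.kin.n, 60.0))
        curve = tuning_curve(flat, s.kin, ep)
        v = curve.rate[curve.valid]
        assert np.allclose(v, 60.0, atol=1e-6)

    def test_noiseless_line_exact_gain(self, encoding_session):
        s, ep, _ = encoding_session
        x0 = 15.0
        rate = np.clip(60.0 + 10.0 * (s.kin.angle_f - x0), 0, None)
        curve = tuning_curve(RateSeries(fs=1000.0, rate=rate), s.kin, ep)
        fit = fit_linear_encoding(curve)
        assert fit.gain == pytest.approx(10.0, rel=0.02)
        assert fit.r2 > 0.999

    def test_insufficient_whisking_rejected(self):
        s = wc.simulate_session(wc.SimConfig(duration=120.0, seed=4))
        ep = wc.segment_epochs(s.kin)
        with pytest.raises(ValueError, match="60 s"):
            tuning_curve(s.spikes, s.kin, ep)


class TestFitAndClassification:
    def test_bidirectional_gain_recovered(self, encoding_session):
        s, ep, cfg = encoding_session
        curve = tuning_curve(s.spikes, s.kin, ep)
        fit = fit_linear_encoding(curve)
        assert fit.direction_class == "bidirectional"
        assert fit.gain == pytest.approx(15.0, rel=0.05)
        assert fit.significant

    def test_retraction_cell_side_and_sign(self):
        cfg = wc.SimConfig(duration=600.0, seed=23, gain=10.0,
                           direction_mode="unidirectional-retraction")
        s = wc.simulate_session(cfg)
        ep = wc.segment_epochs(s.kin)
        curve = tuning_curve(s.spikes, s.kin, ep, lag_s=cfg.latency)
        fit = fit_linear_encoding(curve)
        assert fit.direction_class == "unidirectional-retraction"
        # modulated side is posterior of the resting point
        assert fit.fit_range[1] <= curve.resting_point + 1.0
        assert fit.gain > 0

    def test_position_shuffled_curve_fails_criterion(self, encoding_session):
        s, ep, _ = encoding_session
        curve = tuning_curve(s.spikes, s.kin, ep)
        rng = np.random.default_rng(0)
        fails = 0
        for _ in range(10):
            shuf = wc.TuningCurve(
                position_bins=curve.position_bins,
                rate=np.where(curve.valid,
                              rng.permutation(curve.rate[curve.valid]).take(
                                  np.cumsum(curve.valid) - 1),
                              np.nan),
                occupancy=curve.occupancy,
                resting_point=curve.resting_point,
                spontaneous_rate=curve.spontaneous_rate,
            )
            fit = fit_linear_encoding(shuf)
            if fit.r2 is None or not (fit.r2 > 0.86 and fit.p < 0.05):
                fails += 1
        assert fails >= 9

    def test_gain_translation_invariance(self, encoding_session):
        from dataclasses import replace

        s, ep, _ = encoding_session
        curve = tuning_curve(s.spikes, s.kin, ep)
        g1 = fit_linear_encoding(curve).gain
        kin2 = replace(s.kin, angle_f=s.kin.angle_f + 5.0)
        curve2 = tuning_curve(s.spikes, kin2, ep)
        g2 = fit_linear_encoding(curve2).gain
        assert g2 == pytest.approx(g1, rel=0.02)

    def test_gain_scale_equivariance(self, encoding_session):
        from dataclasses import replace

        s, ep, _ = encoding_session
        curve = tuning_curve(s.spikes, s.kin, ep)
        g1 = fit_linear_encoding(curve).gain
        # doubling the position axis halves the slope; bins also double
        kin2 = replace(s.kin, angle_f=2.0 * s.kin.angle_f)
        curve2 = tuning_curve(s.spikes, kin2, ep, bin_deg=2.0)
        g2 = fit_linear_encoding(curve2).gain
        assert g2 == pytest.approx(g1 / 2.0, rel=0.05)

    def test_directionality_from_curves(self, encoding_session):
        s, ep, _ = encoding_session
        curve = tuning_curve(s.spikes, s.kin, ep)
        ratio, cls, d_pro, d_ret = directionality_ratio(curve)
        assert cls == "bidirectional"
        assert 0.2 <= ratio <= 1.0
        assert d_pro > 0 > d_ret

    def test_bidirectional_population_no_baseline_shift(self):
        # normalized curves pass near (resting point, spontaneous rate)
        for seed, g in [(31, 10.0), (32, 12.0)]:
            cfg = wc.SimConfig(duration=600.0, seed=seed, gain=g,
                               direction_mode="bidirectional", latency=0.0)
            s = wc.simulate_session(cfg)
            ep = wc.segment_epochs(s.kin)
            curve = tuning_curve(s.spikes, s.kin, ep)
            fit = fit_linear_encoding(curve)
            assert fit.direction_class == "bidirectional"
            rate_at_rest = fit.intercept  # fit is in resting-centered coords
            assert abs(rate_at_rest - curve.spontaneous_rate) < 2.0


class TestEncodingRange:
    def test_clipped_cell_range_gain_identity(self):
        # decreasing protraction cell clips at 0 Hz: range * |gain| ~ rate span
        cfg = wc.SimConfig(duration=600.0, seed=77, gain=-30.0,
                           direction_mode="unidirectional-protraction")
        s = wc.simulate_session(cfg)
        ep = wc.segment_epochs(s.kin)
        curve = tuning_curve(s.spikes, s.kin, ep, lag_s=cfg.latency)
        fit = fit_linear_encoding(curve)
        assert fit.significant
        fit = encoding_range_stats(curve, fit, s.kin, ep)
        rates = curve.rate[curve.valid]
        span = np.nanmax(rates) - np.nanmin(rates)
        assert fit.encoding_range * abs(fit.gain) == pytest.approx(span, rel=0.10)
        assert fit.encoding_range < np.ptp(curve.position_bins[curve.valid])
        assert 0.0 < fit.occupancy_fraction < 1.0

    def test_inverse_range_gain_relationship(self):
        ranges = {}
        for g in (5.0, 30.0):
            cfg = wc.SimConfig(duration=600.0, seed=78, gain=-g,
                               direction_mode="unidirectional-protraction")
            s = wc.simulate_session(cfg)
            ep = wc.segment_epochs(s.kin)
            curve = tuning_curve(s.spikes, s.kin, ep, lag_s=cfg.latency)
            fit = fit_linear_encoding(curve)
            fit = encoding_range_stats(curve, fit, s.kin, ep)
            ranges[g] = fit.encoding_range
        # same ~62 Hz rate span in both cells: ranges scale as 1/gain
        assert ranges[5.0] / ranges[30.0] == pytest.approx(6.0, rel=0.15)

    def test_full_range_linear_cell_high_occupancy_fraction(self,
                                                            encoding_session):
        s, ep, _ = encoding_session
        x0 = 15.0
        rate = np.clip(60.0 + 3.0 * (s.kin.angle_f - x0), 0, None)
        curve = tuning_curve(RateSeries(fs=1000.0, rate=rate), s.kin, ep)
        fit = fit_linear_encoding(curve)
        fit = encoding_range_stats(curve, fit, s.kin, ep)
        assert fit.occupancy_fraction > 0.95
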