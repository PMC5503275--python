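import numpy as np
import pytest

from fetalhrv.fsi import (FSI_A, FSI_B, FSI_DENOM, IndexTrace,
                          center_and_normalize, envelopes, fsi_from_auc,
                          fsi_trace, fsi_window, highpass_wavelet, period_mean,
                          subareas)

RATE = 8.0


class TestCenterAndNormalize:
    def test_symmetric_toy(self):
        m, s, norm = center_and_normalize(np.array([1.0, -1.0, 1.0, -1.0]))
        assert m == 0.0
        assert s == pytest.approx(2.0)
        np.testing.assert_allclose(norm, [0.5, -0.5, 0.5, -0.5])

    def test_two_sample_toy(self):
        m, s, norm = center_and_normalize(np.array([390.0, 410.0]))
        assert m == pytest.approx(400.0)
        assert s == pytest.approx(np.sqrt(200.0))
        np.testing.assert_allclose(norm, [-0.70711, 0.70711], atol=1e-5)

    def test_constant_window_invalid(self):
        _, _, norm = center_and_normalize(np.full(512, 400.0))
        assert norm is None

    def test_unit_norm(self, rng):
        _, _, norm = center_and_normalize(rng.normal(400, 20, size=512))
        assert np.linalg.norm(norm) == pytest.approx(1.0, abs=1e-9)


class TestEnvelopes:
    def test_sinusoid_envelopes(self, tone):
        t = np.arange(512) / RATE
        f = 0.7 * np.sin(2 * np.pi * 0.5 * t)
        upper, lower = envelopes(f)
        interior = slice(32, -32)
        assert np.all(upper[interior] > 0.7 * 0.95)
        assert np.all(lower[interior] < -0.7 * 0.95)

    def test_triangle_vertices_exact(self):
        # triangle wave: vertices alternate +-a every 8 samples
        a = 0.3
        seg = np.concatenate([np.linspace(-a, a, 9)[:-1], np.linspace(a, -a, 9)[:-1]])
        f = np.tile(seg, 32)
        upper, lower = envelopes(f)
        peaks = np.flatnonzero(f == a)
        troughs = np.flatnonzero(f == -a)
        assert np.allclose(upper[peaks], a)
        assert np.allclose(lower[troughs], -a)

    def test_single_cycle_invalid(self):
        t = np.arange(512) / RATE
        f = np.sin(2 * np.pi * t / 64.0)  # one oscillation across the window
        assert envelopes(f) is None

    def test_clamped_ordering(self, rng):
        f = highpass_wavelet(center_and_normalize(rng.normal(400, 15, 512))[2])
        upper, lower = envelopes(f)
        assert np.all(upper >= f - 1e-12)
        assert np.all(lower <= f + 1e-12)

    def test_plateau_midpoint(self):
        f = np.zeros(64)
        f[10:13] = 1.0  # 3-sample plateau -> single maximum at its midpoint
        f[30] = 1.0
        f[5] = -1.0
        f[45] = -1.0
        upper, _ = envelopes(f)
        assert upper[11] == 1.0


class TestSubareas:
    def test_constant_gap(self):
        c = 0.05
        upper = np.full(512, c)
        lower = np.zeros(512)
        a1, a2, a3, a4, auc = subareas(upper, lower)
        for a in (a1, a2, a3, a4, auc):
            assert a == pytest.approx(16.0 * c)

    def test_minimum_selection(self):
        c = 0.08
        gap = np.full(512, c)
        gap[384:] = c / 2.0
        a1, a2, a3, a4, auc = subareas(gap, np.zeros(512))
        assert a4 == pytest.approx(8.0 * c)
        assert auc == pytest.approx(a4)

    def test_random_envelopes_match_bruteforce(self, rng):
        upper = np.abs(rng.normal(0.1, 0.02, size=512))
        lower = -np.abs(rng.normal(0.1, 0.02, size=512))
        areas = subareas(upper, lower)
        # independent oracle: explicit python summation per quarter
        for q in range(4):
            total = 0.0
            for i in range(q * 128, (q + 1) * 128):
                total += (upper[i] - lower[i]) / RATE
            assert areas[q] == pytest.approx(total, abs=1e-12)
        assert areas[4] == pytest.approx(min(areas[:4]), abs=1e-15)

    def test_inverted_envelopes_rejected(self):
        with pytest.raises(ValueError):
            subareas(np.zeros(512), np.ones(512))


class TestFsiFromAuc:
    def test_zero(self):
        assert fsi_from_auc(0.0) == pytest.approx(100.0 * FSI_B / FSI_DENOM)
        assert fsi_from_auc(0.0) == pytest.approx(9.375)

    def test_upper_bound_inversion(self):
        auc = (FSI_DENOM / 100.0 * 100.0 - FSI_B) / FSI_A  # 11.6 / 5.1
        assert fsi_from_auc(auc) == pytest.approx(100.0)

    def test_clipping(self):
        raw = 100.0 * (FSI_A * 3.0 + FSI_B) / FSI_DENOM
        assert raw > 100.0
        assert fsi_from_auc(3.0) == 100.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fsi_from_auc(-0.1)


class TestFsiWindow:
    def test_composition_matches_steps(self, tone):
        w = tone(0.5, amp=12.0)
        res = fsi_window(w)
        assert res.valid
        m, s, norm = center_and_normalize(w)
        filt = highpass_wavelet(norm)
        upper, lower = envelopes(filt)
        areas = subareas(upper, lower)
        assert res.m == pytest.approx(m)
        assert res.s == pytest.approx(s)
        np.testing.assert_allclose(res.filtered, filt)
        assert res.auc_min == pytest.approx(areas[4])
        assert res.fsi == pytest.approx(fsi_from_auc(areas[4]))

    def test_constant_window_invalid(self):
        res = fsi_window(np.full(512, 400.0))
        assert not res.valid
        assert res.fsi is None
        assert "constant" in res.reason

    def test_invariants(self, tone, rng):
        w = tone(0.5, amp=8.0) + rng.normal(0, 2, 512)
        res = fsi_window(w)
        assert np.linalg.norm(res.rr_norm) == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.upper_env >= res.filtered - 1e-12)
        assert np.all(res.lower_env <= res.filtered + 1e-12)
        assert all(a >= 0 for a in res.areas)
        assert res.auc_min == min(res.areas)
        assert 0.0 <= res.fsi <= 100.0


class TestFsiTrace:
    def test_window_arithmetic(self, uniform_factory, rng):
        n = int(300 * RATE) + 1
        sig = uniform_factory(400 + rng.normal(0, 10, n))
        trace = fsi_trace(sig)
        assert len(trace) == 237

    def test_times_centered_1hz(self, uniform_factory, rng):
        sig = uniform_factory(400 + rng.normal(0, 10, int(100 * RATE) + 1), start=50.0)
        trace = fsi_trace(sig)
        assert trace.times[0] == pytest.approx(50.0 + 32.0)
        np.testing.assert_allclose(np.diff(trace.times), 1.0)

    def test_stationary_signal_low_cv(self, uniform_factory, rng):
        t = np.arange(int(300 * RATE) + 1) / RATE
        sig = uniform_factory(400 + 10 * np.sin(2 * np.pi * 0.5 * t)
                              + 5 * np.sin(2 * np.pi * 0.1 * t)
                              + rng.normal(0, 1.0, t.size))
        trace = fsi_trace(sig)
        vals = trace.values[trace.valid]
        assert vals.std() < 0.2 * vals.mean()

    def test_constant_segment_windows_missing(self, uniform_factory):
        t = np.arange(int(300 * RATE) + 1) / RATE
        v = 400 + 10 * np.sin(2 * np.pi * 0.5 * t)
        const = (t >= 100) & (t < 170)
        v[const] = 400.0
        trace = fsi_trace(uniform_factory(v))
        # windows fully inside [100, 170) start in [100, 106]
        inside = (trace.times - 32.0 >= 100.0) & (trace.times + 32.0 <= 170.0)
        assert inside.any()
        assert not trace.valid[inside].any()
        assert np.isnan(trace.values[inside]).all()

    def test_per_window_results_match(self, uniform_factory, rng):
        n = int(80 * RATE) + 1
        sig = uniform_factory(400 + rng.normal(0, 10, n))
        trace, wins = fsi_trace(sig, keep_windows=True)
        for k in [0, 7, len(trace) - 1]:
            start = int(k * RATE)
            direct = fsi_window(sig.values[start:start + 512])
            assert wins[k].fsi == pytest.approx(direct.fsi, abs=1e-9)
            assert trace.values[k] == pytest.approx(direct.fsi, abs=1e-9)

    def test_too_short_rejected(self, uniform_factory):
        with pytest.raises(ValueError):
            fsi_trace(uniform_factory(np.full(int(60 * RATE), 400.0)))

    def test_wrong_rate_rejected(self, uniform_factory):
        with pytest.raises(ValueError):
            fsi_trace(uniform_factory(np.full(1000, 400.0), rate=4.0))


class TestPeriodMean:
    def _trace(self, values, t0=0.0):
        values = np.asarray(values, dtype=float)
        return IndexTrace(times=t0 + np.arange(values.size), values=values)

    def test_constant(self):
        tr = self._trace(np.full(100, 40.0))
        assert period_mean(tr, 10.0, 60.0) == pytest.approx(40.0)

    def test_mean_over_valid(self):
        tr = self._trace([10.0, 20.0, np.nan, 30.0])
        assert period_mean(tr, 0.0, 4.0) == pytest.approx(20.0)

    def test_outside_span_rejected(self):
        tr = self._trace(np.full(50, 40.0))
        with pytest.raises(ValueError):
            period_mean(tr, 200.0, 300.0)

    def test_mostly_invalid_returns_nan(self):
        vals = np.full(100, np.nan)
        vals[:10] = 40.0
        tr = self._trace(vals)
        with pytest.warns(UserWarning, match="valid"):
            out = period_mean(tr, 0.0, 100.0)
        assert np.isnan(out)

    def test_half_open_interval(self):
        tr = self._trace([1.0, 2.0, 3.0, 4.0])
        # centre at t1 excluded
        assert period_mean(tr, 0.0, 3.0) == pytest.approx(2.0)
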