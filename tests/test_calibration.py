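import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathfield.calibration import (
    FieldProfileSeries,
    PhaseSeries,
    average_field_in_mask,
    calibrate,
    detect_outlier_frames,
    fit_trace_coupling,
    phase_to_field,
    unwrap_phase_temporal,
)
from breathfield.correction import RespTrace
from breathfield.simulation import BreathingModel, SequenceSpec, make_phantom, make_trace, simulate_flash

TE_S = 4.08e-3


def _series(phase, te_s=TE_S):
    phase = np.asarray(phase, dtype=float)
    nt = phase.shape[-1]
    return PhaseSeries(
        phase=phase,
        magnitude=np.ones_like(phase),
        te_s=te_s,
        frame_times=np.arange(nt, dtype=float),
        z_mm=np.arange(phase.shape[0], dtype=float),
    )


def _wrap(phi):
    return np.angle(np.exp(1j * phi))


class TestTemporalUnwrap:
    def test_constant_series_unchanged(self):
        s = _series(np.full((2, 3, 5), 0.7))
        out = unwrap_phase_temporal(s)
        np.testing.assert_array_equal(out.phase, s.phase)

    def test_wrapped_linear_ramp_recovered(self):
        true = 2.5 * np.arange(10)[None, None, :] + 0.3
        out = unwrap_phase_temporal(_series(_wrap(true)))
        # recovered up to the wrap of the initial frame
        np.testing.assert_allclose(out.phase - out.phase[..., :1],
                                   true - true[..., :1], atol=1e-12)
        assert np.all(np.abs(np.diff(out.phase, axis=-1)) <= np.pi + 1e-12)

    def test_large_sinusoid_recovered_to_machine_precision(self):
        t = np.linspace(0, 2 * np.pi, 200)
        true = 4.0 * np.sin(t)[None, None, :]
        out = unwrap_phase_temporal(_series(_wrap(true)))
        np.testing.assert_allclose(out.phase, true, atol=1e-10)

    def test_single_frame_warns_noop(self):
        s = _series(np.zeros((1, 1, 1)))
        with pytest.warns(UserWarning):
            out = unwrap_phase_temporal(s)
        np.testing.assert_array_equal(out.phase, s.phase)


class TestPhaseToField:
    def test_zero_phase_gives_zero_field(self):
        f0 = phase_to_field(_series(np.zeros((2, 2, 4))))
        np.testing.assert_array_equal(f0, 0.0)

    def test_two_pi_deviation_at_408ms_te(self):
        # a +2π phase excursion at one of N frames → 1/TE = 245.098 Hz there,
        # minus the mean shift it induces (2π/N spread over all frames)
        n = 8
        phase = np.zeros((1, 1, n))
        phase[0, 0, 3] = 2 * np.pi
        f0 = phase_to_field(_series(phase))
        hz = 1.0 / TE_S
        np.testing.assert_allclose(f0[0, 0, 3], hz * (1 - 1 / n), rtol=1e-12)
        np.testing.assert_allclose(f0[0, 0, 0], -hz / n, rtol=1e-12)
        assert abs(hz - 245.098) < 0.001

    def test_quarter_turn_deviation_is_61hz(self):
        assert abs((-np.pi / 2) / (2 * np.pi * TE_S) - (-61.2745)) < 1e-3

    def test_invalid_te_rejected(self):
        with pytest.raises(ValueError):
            PhaseSeries(
                phase=np.zeros((1, 1, 2)), magnitude=np.ones((1, 1, 2)),
                te_s=0.0, frame_times=np.arange(2.0), z_mm=np.zeros(1),
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_zero_temporal_mean_invariant(self, seed):
        rng = np.random.default_rng(seed)
        phase = rng.normal(0, 2, size=(3, 4, 11))
        f0 = phase_to_field(_series(phase))
        np.testing.assert_allclose(f0.mean(axis=-1), 0.0, atol=1e-10)


class TestMaskAverage:
    def _args(self, nz, nx, nt):
        return np.arange(nz, dtype=float) * 3.0, np.arange(nt, dtype=float)

    def test_uniform_field_preserved(self):
        z, t = self._args(2, 6, 4)
        f = np.full((2, 6, 4), 5.0)
        mask = np.ones((2, 6), dtype=bool)
        prof = average_field_in_mask(f, mask, z, t)
        np.testing.assert_array_equal(prof.f0, 5.0)

    def test_arithmetic_mean_of_two_voxels(self):
        z, t = self._args(1, 4, 1)
        f = np.zeros((1, 4, 1))
        f[0, 1, 0], f[0, 2, 0] = 2.0, 4.0
        mask = np.zeros((1, 4), dtype=bool)
        mask[0, 1:3] = True
        prof = average_field_in_mask(f, mask, z, t)
        assert prof.f0[0, 0] == 3.0

    def test_empty_slice_dropped_with_warning(self):
        z, t = self._args(2, 4, 2)
        f = np.ones((2, 4, 2))
        mask = np.zeros((2, 4), dtype=bool)
        mask[0] = True
        with pytest.warns(UserWarning):
            prof = average_field_in_mask(f, mask, z, t)
        assert prof.dropped_slices == [1]
        assert prof.z_mm.tolist() == [0.0]

    def test_noise_averages_down_as_clt_predicts(self):
        rng = np.random.default_rng(7)
        n_vox, nt, sigma = 64, 100, 0.5
        c, z = 6.0, np.array([0.0])
        t = np.arange(nt, dtype=float)
        r = np.sin(2 * np.pi * t / 13.0)
        truth = c * r
        f = truth[None, None, :] + rng.normal(0, sigma, (1, n_vox, nt))
        mask = np.ones((1, n_vox), dtype=bool)
        prof = average_field_in_mask(f, mask, z, t)
        dev = np.abs(prof.f0[0] - truth)
        bound = 3 * sigma / np.sqrt(n_vox)
        assert np.mean(dev < bound) >= 0.99
        assert dev.max() < 5 * sigma / np.sqrt(n_vox)


def _resp_from(times, values):
    return RespTrace(time=times, value=values - values.mean())


class TestOutlierDetection:
    def _profile(self, f0, t):
        return FieldProfileSeries(z_mm=np.arange(f0.shape[0], dtype=float),
                                  f0=f0, frame_times=t)

    def test_perfectly_linear_data_flags_nothing(self):
        t = np.arange(40, dtype=float)
        r = np.sin(t / 3.0)
        f0 = np.vstack([2.0 * r, 5.0 * r])
        # tiny heteroscedastic residual so MAD is nonzero
        rng = np.random.default_rng(0)
        f0 = f0 + rng.normal(0, 1e-3, f0.shape)
        trace = _resp_from(t, r)
        assert detect_outlier_frames(self._profile(f0, t), trace) == []

    def test_forty_hz_swallow_burst_flagged(self):
        t = np.arange(60, dtype=float)
        r = np.sin(t / 3.0)
        rng = np.random.default_rng(1)
        f0 = 5.0 * r[None, :] + rng.normal(0, 0.3, (3, t.size))
        f0[:, 25] += 40.0
        trace = _resp_from(t, r)
        assert 25 in detect_outlier_frames(self._profile(f0, t), trace)

    def test_null_false_positive_rate_below_one_percent(self):
        # pure-noise residuals at k = 4 MAD: the Gaussian tail gives ~6e-5
        rng = np.random.default_rng(2)
        nt = 1000
        t = np.arange(nt, dtype=float)
        r = np.sin(t / 3.0)
        f0 = rng.normal(0, 1.0, (1, nt))
        trace = _resp_from(t, r)
        flagged = detect_outlier_frames(self._profile(f0, t), trace, k=4.0)
        assert len(flagged) / nt < 0.01


class TestCouplingFit:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0, 35, 0.35)
        r = np.sin(2 * np.pi * t / 4.5)
        c_true = np.array([3.0, -7.5])
        f0 = c_true[:, None] * (r - r.mean())[None, :]
        prof = FieldProfileSeries(z_mm=np.array([0.0, 3.0]), f0=f0, frame_times=t)
        calib = fit_trace_coupling(prof, _resp_from(t, r), window_s=30.0)
        np.testing.assert_allclose(calib.coupling, c_true, rtol=1e-10)

    def test_closed_form_three_frame_toy(self):
        # R = [1,2,3], f0 = [2,4,6] Hz → c = Σ R·f0 / Σ R² = 2 Hz/unit
        from breathfield.calibration import _demeaned_lsq

        c, rms = _demeaned_lsq(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
        assert c == pytest.approx(2.0, abs=1e-14)
        assert rms == pytest.approx(0.0, abs=1e-14)

    def test_fewer_than_ten_frames_rejected(self):
        t = np.arange(12, dtype=float)
        r = np.sin(t)
        prof = FieldProfileSeries(z_mm=np.array([0.0]), f0=r[None, :], frame_times=t)
        with pytest.raises(ValueError):
            fit_trace_coupling(prof, _resp_from(t, r), window_s=5.0)

    def test_closed_form_matches_normal_equation(self):
        # oracle: c = Σ r̃·f̃0 / Σ r̃² on demeaned windowed samples
        rng = np.random.default_rng(3)
        t = np.arange(0, 40, 0.4)
        r = np.sin(2 * np.pi * t / 5.0) + 0.1 * rng.standard_normal(t.size)
        f0 = (4.0 * r + rng.normal(0, 0.5, t.size))[None, :]
        prof = FieldProfileSeries(z_mm=np.array([0.0]), f0=f0, frame_times=t)
        resp = _resp_from(t, r)
        calib = fit_trace_coupling(prof, resp, window_s=30.0)
        keep = t <= t[0] + 30.0
        rw = np.interp(t[keep], resp.time, resp.value)
        rw = rw - rw.mean()
        fw = f0[0, keep] - f0[0, keep].mean()
        np.testing.assert_allclose(calib.coupling[0], np.sum(rw * fw) / np.sum(rw**2),
                                   rtol=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        c_true = 5.0
        n_pass = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(0, 31.0, 0.344)
            r = np.sin(2 * np.pi * t / 4.5)
            field_rms = c_true * np.sqrt(np.mean(r**2))
            f0 = (c_true * r + rng.normal(0, 0.1 * field_rms, t.size))[None, :]
            prof = FieldProfileSeries(z_mm=np.array([0.0]), f0=f0, frame_times=t)
            calib = fit_trace_coupling(prof, _resp_from(t, r), window_s=30.0)
            if abs(calib.coupling[0] - c_true) / c_true < 0.05:
                n_pass += 1
        assert n_pass >= 95

    def test_degenerate_trace_rejected(self):
        t = np.arange(20, dtype=float)
        prof = FieldProfileSeries(z_mm=np.array([0.0]),
                                  f0=np.ones((1, 20)), frame_times=t)
        flat = RespTrace(time=t, value=np.zeros(20))
        with pytest.raises(ValueError):
            fit_trace_coupling(prof, flat, window_s=19.0)

    def test_all_frames_excluded_rejected(self):
        t = np.arange(20, dtype=float)
        r = np.sin(t)
        prof = FieldProfileSeries(z_mm=np.array([0.0]),
                                  f0=r[None, :], frame_times=t)
        with pytest.raises(ValueError):
            fit_trace_coupling(prof, _resp_from(t, r), window_s=19.0,
                               excluded=list(range(20)))


class TestEndToEndCalibration:
    def test_noiseless_flash_recovers_generating_profile(self):
        model = BreathingModel(period_sd_s=0.3)
        trace = make_trace(60.0, seed=11)
        phantom = make_phantom(n_slices=4, seed=0)
        sim = simulate_flash(phantom, SequenceSpec.flash(), trace, model,
                             noise_sd=0.0, seed=12)
        calib = calibrate(sim.series, sim.cord_mask, sim.resp)
        rel = np.linalg.norm(calib.coupling - sim.truth_coupling) / np.linalg.norm(
            sim.truth_coupling)
        assert rel < 1e-8

    def test_snr20_flash_recovers_within_five_percent(self):
        model = BreathingModel(period_sd_s=0.3)
        trace = make_trace(60.0, seed=21)
        phantom = make_phantom(n_slices=4, seed=0)
        sim = simulate_flash(phantom, SequenceSpec.flash(), trace, model,
                             noise_sd=0.05, seed=22)
        calib = calibrate(sim.series, sim.cord_mask, sim.resp)
        rel = np.linalg.norm(calib.coupling - sim.truth_coupling) / np.linalg.norm(
            sim.truth_coupling)
        assert rel < 0.05
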