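import numpy as np
import pytest
import pywt

from ptkit import ImuRecording, ParameterError, PTSpec, SimulationConfig, simulate_session
from ptkit.posture import (
    G0,
    detect_stationary,
    dwt_denoise,
    estimate_tilt,
    tilt_active,
    tilt_stationary,
)
from ptkit.preprocess import preprocess

FS = 128.0


def _pre(accel, gyro=None, fs=FS):
    n = accel.shape[0]
    gyro = np.zeros((n, 3)) if gyro is None else gyro
    rec = ImuRecording(fs, np.arange(n) / fs, accel, gyro)
    return preprocess(rec)


class TestDetectStationary:
    def test_still_recording_all_sp_after_warmup(self, still_rec):
        mask = detect_stationary(preprocess(still_rec))
        assert np.all(mask.stationary[127:])
        assert not np.any(mask.stationary[:127])

    def test_continuous_rocking_all_ap(self):
        # A sustained 1 Hz rocking motion: the gyro-magnitude variance
        # stays far above threshold, so no sample is ever stationary.
        n = int(10 * FS)
        t = np.arange(n) / FS
        theta = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        rate = 0.5 * 2 * np.pi * np.cos(2 * np.pi * 1.0 * t)
        accel = G0 * np.column_stack([np.cos(theta), np.zeros(n), np.sin(theta)])
        gyro = np.column_stack([np.zeros(n), rate, np.zeros(n)])
        mask = detect_stationary(_pre(accel, gyro))
        assert not np.any(mask.stationary)
        assert "no stationary anchor" in mask.flags

    def test_sp_aligns_with_simulated_rest(self, benchmark_session):
        rec, truth, result = benchmark_session
        mask = result.mask
        changes = np.flatnonzero(np.diff(mask.stationary.astype(int))) / FS
        # Movement onset is caught almost immediately; the return to sp
        # lags by up to two windows (2 s), because the short-term variance
        # is evaluated against per-lag trailing means that themselves
        # reach one window further back.
        for ev in truth.annotation:
            assert np.min(np.abs(changes - ev.start)) < 0.5
            assert np.min(np.abs(changes - ev.end)) < 2.5

    def test_threshold_monotonicity(self, benchmark_session):
        rec, _, result = benchmark_session
        pre = preprocess(rec)
        base = detect_stationary(pre).stationary.sum()
        wider = detect_stationary(
            pre, accel_dev_thresh=0.1, accel_var_thresh=0.02, gyro_var_thresh=0.02
        ).stationary.sum()
        assert wider >= base

    def test_short_sp_runs_merged(self, still_rec):
        pre = preprocess(still_rec)
        # Punch 1-sample ap holes every 16 samples after warm-up: the
        # surviving sp islands (15 samples < 32) must all dissolve into ap.
        pre.accel_var[1280::16] = 1.0
        mask = detect_stationary(pre)
        assert not np.any(mask.stationary[1280:])


class TestTiltStationary:
    @pytest.mark.parametrize(
        "accel, expected",
        [
            ((9.81, 0.0, 0.0), 0.0),
            ((0.0, 0.0, 9.81), np.pi / 2),
            ((0.0, 0.0, -9.81), 3 * np.pi / 2),
        ],
    )
    def test_gravity_component_angles(self, accel, expected, still_rec):
        mask = detect_stationary(preprocess(still_rec))
        theta = tilt_stationary(np.array([accel]), mask)
        assert theta[0] == pytest.approx(expected, abs=1e-12)


class TestTiltActive:
    def test_zero_rate_constant_angle(self, still_rec):
        pre = preprocess(still_rec)
        mask = detect_stationary(pre)
        theta, _ = estimate_tilt(pre, mask)
        assert np.allclose(theta[127:], theta[127], atol=1e-9)

    def test_constant_residual_rate_exactly_cancelled(self):
        # Still accel but a constant fictitious omega_y during a forced ap
        # window: integration gives a linear ramp, which the drift removal
        # eliminates, so tilt returns to the anchors.
        n = int(20 * FS)
        accel = np.tile([G0, 0.0, 0.0], (n, 1))
        gyro = np.zeros((n, 3))
        pre = _pre(accel, gyro)
        mask = detect_stationary(pre)
        # Force an ap window in the middle by inflating the gyro variance.
        pre2 = _pre(accel, gyro)
        pre2.gyro_var[1000:1500] = 1.0
        mask = detect_stationary(pre2)
        pre2.gyro_unbiased[:, 1] = 0.0
        # Constant residual from the left anchor (999) through the window.
        pre2.gyro_unbiased[999:1500, 1] = 0.05
        theta, _ = estimate_tilt(pre2, mask)
        theta_sp = tilt_stationary(pre2.accel, mask)
        seg = next(s for s in mask.ap_segments if s.first >= 900)
        wrapped = np.angle(np.exp(1j * (theta - theta_sp)))
        assert abs(wrapped[seg.n_ls]) < 1e-9
        assert abs(wrapped[seg.n_rs]) < 1e-9
        # The linear ramp is cancelled exactly: tilt constant over the window.
        assert np.max(np.abs(np.diff(theta[seg.n_ls : seg.n_rs]))) < 1e-9

    def test_recovers_simulated_flexion_peak(self):
        cfg = SimulationConfig(
            seed=3,
            duration=30.0,
            pt_schedule=[PTSpec(12.0, "SiSt", tilt_peak=np.deg2rad(40.0))],
        )
        rec, truth = simulate_session(cfg)
        pre = preprocess(rec)
        mask = detect_stationary(pre)
        theta, _ = estimate_tilt(pre, mask)
        wrapped = np.angle(np.exp(1j * theta))
        sl = slice(int(12 * FS), int(14.5 * FS))
        peak = np.min(wrapped[sl])  # forward flexion is negative
        assert peak == pytest.approx(-np.deg2rad(40.0), abs=np.deg2rad(2.0))

    def test_anchor_exactness(self, benchmark_session):
        rec, _, result = benchmark_session
        pre = preprocess(rec)
        mask = result.mask
        theta_sp = tilt_stationary(pre.accel, mask)
        theta, _ = estimate_tilt(pre, mask)
        for seg in mask.ap_segments:
            if seg.n_ls is None or seg.n_rs is None:
                continue
            for anchor in (seg.n_ls, seg.n_rs):
                d = np.angle(np.exp(1j * (theta[anchor] - theta_sp[anchor])))
                assert abs(d) < 1e-9


class TestDwtDenoise:
    def test_constant_input_denoises_to_zero(self):
        _, _, dn = dwt_denoise(np.full(4000, 0.37))
        assert np.max(np.abs(dn)) < 1e-6

    def test_band_energies_of_slow_sine(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 0.5 * t)
        r3, r10, dn = dwt_denoise(x)
        e = (x**2).sum()
        assert (r3**2).sum() / e > 0.95
        assert (r10**2).sum() / e < 0.05
        assert np.corrcoef(dn, x)[0, 1] > 0.97

    def test_white_noise_energy_ordering(self):
        x = np.random.default_rng(11).standard_normal(5000)
        r3, r10, _ = dwt_denoise(x)
        assert (r10**2).sum() < (r3**2).sum() < (x**2).sum()

    def test_linearity(self):
        rng = np.random.default_rng(4)
        u = rng.standard_normal(3000)
        v = rng.standard_normal(3000)
        r3a, r10a, da = dwt_denoise(2.0 * u - 0.5 * v)
        _, _, du = dwt_denoise(u)
        _, _, dv = dwt_denoise(v)
        assert np.allclose(da, 2.0 * du - 0.5 * dv, atol=1e-8)

    def test_single_level_perfect_reconstruction(self):
        # Oracle for the filter bank itself: keeping BOTH branches of one
        # decomposition step reproduces the input.
        x = np.random.default_rng(9).standard_normal(1024)
        a, d = pywt.dwt(x, "coif5", mode="symmetric")
        back = pywt.idwt(a, d, "coif5", mode="symmetric")[: x.size]
        assert np.allclose(back, x, atol=1e-8)

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            dwt_denoise(np.zeros(8))
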