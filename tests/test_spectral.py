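"""DC removal, artifact subtraction, spectrogram calibration, dB summaries."""

import numpy as np
import pytest

from ictal.session import ContinuousSignal, EpochSet
from ictal import spectral


def _sig(x, rate=1000.0, t0=0.0):
    return ContinuousSignal(name="s", samples=np.asarray(x, float), rate_hz=rate, t0_s=t0, units="uV")


class TestRemoveDC:
    def test_constant_rejected(self):
        out = spectral.remove_dc(_sig(np.full(5000, 3.7)), 0.1)
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_high_frequency_sinusoid_preserved(self):
        """Closed-form high-pass gain |H| = 2*pi*f*tau / sqrt(1+(2*pi*f*tau)^2)."""
        rate, f, tau = 1000.0, 50.0, 0.1
        t = np.arange(20000) / rate
        out = spectral.remove_dc(_sig(np.sin(2 * np.pi * f * t), rate), tau)
        gain = np.abs(out.samples[5000:]).max()
        expected = 2 * np.pi * f * tau / np.sqrt(1 + (2 * np.pi * f * tau) ** 2)
        assert gain == pytest.approx(expected, rel=0.01)

    def test_step_decays_with_efold_tau(self):
        rate, tau = 1000.0, 0.1
        x = np.zeros(5000)
        x[1000:] = 1.0
        out = spectral.remove_dc(_sig(x, rate), tau).samples
        # fit log of the decaying tail
        seg = out[1010:1400]
        t = np.arange(seg.size) / rate
        slope = np.polyfit(t, np.log(seg), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.02)


class TestRemoveStimArtifact:
    def test_exact_cubic_removed(self):
        rate = 1000.0
        t = np.arange(30000) / rate
        cubic = np.where((t >= 10) & (t < 20), 5 + 3 * (t - 10) - 2 * (t - 10) ** 2 + 0.5 * (t - 10) ** 3, 0.0)
        out = spectral.remove_stim_artifact(_sig(cubic, rate), stim_off_s=10.0)
        assert np.abs(out.samples).max() <= 1e-9 * np.abs(cubic).max()

    def test_order_zero_subtracts_window_mean(self):
        rate = 100.0
        x = np.ones(3000) * 4.0
        out = spectral.remove_stim_artifact(_sig(x, rate), stim_off_s=5.0, poly_order=0)
        win = slice(500, 1500)
        assert np.allclose(out.samples[win], 0.0)
        assert np.allclose(out.samples[1500:], 4.0)

    def test_sinusoid_survives_cubic_fit(self):
        """Leakage is bounded by the sinusoid's projection onto the cubic basis."""
        rate = 1000.0
        t = np.arange(30000) / rate
        sine = np.sin(2 * np.pi * 1.5 * t)
        win = (t >= 10) & (t < 20)
        cubic = np.where(win, 1 + (t - 10) ** 3, 0.0)
        out = spectral.remove_stim_artifact(_sig(sine + cubic, rate), stim_off_s=10.0)
        # independent oracle: residual of the sinusoid after cubic projection
        tw = t[win] - 10.0
        basis = np.vander(tw, 4)
        proj = basis @ np.linalg.lstsq(basis, sine[win], rcond=None)[0]
        expected = sine[win] - proj
        assert np.allclose(out.samples[win], expected, atol=1e-5)
        # the cubic basis absorbs only a bounded sliver of a 1.5 Hz sinusoid
        assert np.abs(proj).max() < 0.25
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(out.samples[win]) == pytest.approx(rms(sine[win]), rel=0.05)

    def test_window_too_short_errors(self):
        from ictal.session import ValidationError

        with pytest.raises(ValidationError):
            spectral.remove_stim_artifact(_sig(np.ones(20), 1.0), stim_off_s=18.0)


class TestSpectrogram:
    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        sigma = 2.5
        tf = spectral.compute_spectrogram(_sig(rng.standard_normal(30000) * sigma))
        df = tf.freqs_hz[1] - tf.freqs_hz[0]
        total = tf.psd.sum(axis=0) * df
        assert np.mean(total) == pytest.approx(sigma**2, rel=0.15)

    def test_sinusoid_power_scales_quadratically(self):
        t = np.arange(10000) / 1000.0
        tf1 = spectral.compute_spectrogram(_sig(np.sin(2 * np.pi * 10 * t)))
        tf2 = spectral.compute_spectrogram(_sig(2 * np.sin(2 * np.pi * 10 * t)))
        bin10 = np.argmin(np.abs(tf1.freqs_hz - 10.0))
        assert np.allclose(tf2.psd[bin10], 4 * tf1.psd[bin10])

    def test_zero_signal_zero_psd(self):
        tf = spectral.compute_spectrogram(_sig(np.zeros(5000)))
        assert np.all(tf.psd == 0)

    def test_too_short_errors(self):
        from ictal.session import ValidationError

        with pytest.raises(ValidationError):
            spectral.compute_spectrogram(_sig(np.ones(100)))


class TestNormalization:
    def test_amplitude_doubling_gives_6db(self):
        """x2 amplitude = x4 power = +6.0206 dB, exactly for a repeated segment."""
        rng = np.random.default_rng(1)
        n = rng.standard_normal(20000)
        sig = _sig(np.concatenate([n, 2 * n]))
        tf = spectral.compute_spectrogram(sig)
        ntf = spectral.normalize_to_baseline(tf, (0.0, 20.0))
        sel = spectral._windows_within(ntf.times_s, 1.0, (20.0, 40.0))
        db = 10 * np.log10(ntf.ratio[:, sel].mean())
        assert db == pytest.approx(10 * np.log10(4), abs=0.2)

    def test_self_normalization_near_zero_db(self):
        rng = np.random.default_rng(2)
        sig = _sig(rng.standard_normal(60000))
        tf = spectral.compute_spectrogram(sig)
        ntf = spectral.normalize_to_baseline(tf, (0.0, 60.0))
        db = 10 * np.log10(ntf.ratio.mean())
        assert abs(db) < 0.5

    def test_scale_equivariance(self):
        """Multiplying the raw signal by c leaves normalized dB unchanged."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30000)
        tf1 = spectral.compute_spectrogram(_sig(x))
        tf2 = spectral.compute_spectrogram(_sig(17.3 * x))
        n1 = spectral.normalize_to_baseline(tf1, (0.0, 10.0))
        n2 = spectral.normalize_to_baseline(tf2, (0.0, 10.0))
        assert np.allclose(n1.ratio, n2.ratio)

    def test_too_few_baseline_windows_errors(self):
        from ictal.session import ValidationError

        tf = spectral.compute_spectrogram(_sig(np.random.default_rng(0).standard_normal(30000)))
        with pytest.raises(ValidationError):
            spectral.normalize_to_baseline(tf, (0.0, 2.0))


class TestBandPeriodSummary:
    @pytest.fixture()
    def generated(self, lean_session):
        session, truth = lean_session
        sig = spectral.remove_stim_artifact(
            session.signals["ofc_lfp"], session.annotation.stim_off_s
        )
        tf = spectral.compute_spectrogram(sig)
        ntf = spectral.normalize_to_baseline(tf, truth.epochs.baseline)
        return session, truth, ntf

    def test_baseline_period_near_zero_db(self, generated):
        session, truth, ntf = generated
        summ = spectral.band_period_summary(ntf, truth.epochs)
        assert abs(summ["delta"].period_db["baseline"]) < 0.5
        assert abs(summ["beta"].period_db["baseline"]) < 0.5

    def test_beta_unprogrammed_near_zero(self, generated):
        session, truth, ntf = generated
        summ = spectral.band_period_summary(
            ntf,
            truth.epochs,
            mask_intervals=[(session.annotation.stim_on_s, session.annotation.stim_off_s)],
        )
        assert abs(summ["beta"].period_db["ictal"]) < 1.5


class TestEventAligned:
    def test_baseline_events_near_zero_and_deterministic(self, lean_session):
        session, truth = lean_session
        sig = session.signals["ofc_lfp"]
        tf = spectral.compute_spectrogram(sig)
        ntf = spectral.normalize_to_baseline(tf, truth.epochs.baseline)
        base_sounds = truth.sounds.loc[truth.sounds["period"] == "baseline", "time_s"].to_numpy()
        ev1, dropped1 = spectral.event_aligned_spectrum(sig, base_sounds, ntf.baseline_mean_psd)
        ev2, _ = spectral.event_aligned_spectrum(sig, base_sounds, ntf.baseline_mean_psd)
        assert [e.delta_db for e in ev1] == [e.delta_db for e in ev2]
        assert abs(np.mean([e.delta_db for e in ev1])) < 1.5

    def test_uncovered_events_dropped_with_count(self, lean_session):
        session, truth = lean_session
        sig = session.signals["ofc_lfp"]
        tf = spectral.compute_spectrogram(sig)
        ntf = spectral.normalize_to_baseline(tf, truth.epochs.baseline)
        times = np.array([1.0, 80.0])  # first lacks the 2 s pre-window
        ev, dropped = spectral.event_aligned_spectrum(sig, times, ntf.baseline_mean_psd)
        assert dropped == 1 and len(ev) == 1
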