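"""Synthetic generators: determinism, ground-truth fidelity, noise targeting."""

import numpy as np
import pytest

from bioqc import (DEFAULT_MORPHOLOGY, ECGMorphology, NNGenSpec, NoiseSpec,
                   Signal, add_noise, generate_nn_series, synthesize_ecg,
                   synthesize_eeg, synthesize_emg)
from bioqc.synth import NNSeries


class TestGenerateNN:
    def test_degenerate_constant(self):
        spec = NNGenSpec(mean_nn=1000.0, lf_mod=(0.1, 0.0),
                         hf_mod=(0.25, 0.0), jitter_sd=0.0, n_beats=11)
        nn = generate_nn_series(spec)
        np.testing.assert_allclose(nn.nn, 1000.0)

    def test_deterministic_under_seed(self):
        spec = NNGenSpec(n_beats=50, seed=3)
        a = generate_nn_series(spec)
        b = generate_nn_series(spec)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)
        c = generate_nn_series(NNGenSpec(n_beats=50, seed=4))
        assert not np.array_equal(a.beat_times, c.beat_times)

    def test_modulation_averages_out(self):
        spec = NNGenSpec(mean_nn=1000.0, lf_mod=(0.1, 50.0),
                         hf_mod=(0.25, 0.0), jitter_sd=0.0, n_beats=301)
        nn = generate_nn_series(spec)
        assert abs(nn.nn.mean() - 1000.0) < 5.0

    def test_nonphysiologic_nn_rejected(self):
        spec = NNGenSpec(mean_nn=260.0, lf_mod=(0.1, 50.0),
                         hf_mod=(0.25, 0.0), jitter_sd=0.0, n_beats=50)
        with pytest.raises(ValueError, match="non-physiologic"):
            generate_nn_series(spec)


class TestSynthesizeECG:
    def test_r_peak_at_argmax(self):
        nn = generate_nn_series(NNGenSpec(mean_nn=1000.0, jitter_sd=0.0,
                                          lf_mod=(0.1, 0.0), hf_mod=(0.25, 0.0),
                                          n_beats=11))
        sig, r_times = synthesize_ecg(nn, fs=1000.0)
        for rt in r_times:
            i = int(round(rt * 1000))
            w = sig.samples[max(0, i - 50):i + 51]
            assert abs((np.argmax(w) + max(0, i - 50)) / 1000.0 - rt) <= 0.002

    def test_zero_pt_leaves_only_qrs(self):
        morph = ECGMorphology(p=(0.0, -0.20, 0.025), t=(0.0, 0.30, 0.060))
        nn = generate_nn_series(NNGenSpec(mean_nn=1000.0, jitter_sd=0.0,
                                          lf_mod=(0.1, 0.0), hf_mod=(0.25, 0.0),
                                          n_beats=6))
        sig, r_times = synthesize_ecg(nn, morph)
        # outside +-80 ms of any R, the trace is numerically zero
        t = sig.times()
        near_r = np.zeros(sig.n, bool)
        for rt in r_times:
            near_r |= np.abs(t - rt) < 0.080
        assert np.max(np.abs(sig.samples[~near_r])) < 1e-6

    def test_undersampled_rejected(self):
        nn = generate_nn_series(NNGenSpec(n_beats=5))
        with pytest.raises(ValueError, match="undersampled"):
            synthesize_ecg(nn, fs=100.0)

    def test_morphology_validation(self):
        with pytest.raises(ValueError):
            ECGMorphology(r=(50.0, 0.0, 0.012))  # R must dominate Q/S


class TestSynthesizeEMG:
    def test_rms_increases_with_force(self):
        epochs = [((2.0, 6.0), 1), ((10.0, 14.0), 2), ((18.0, 22.0), 3)]
        sig, truth = synthesize_emg(epochs, duration=24.0, seed=0)
        rms = []
        for (a, b), _ in epochs:
            seg = sig.samples[int(a * 1000):int(b * 1000)]
            rms.append(np.sqrt(np.mean((seg - seg.mean()) ** 2)))
        assert rms[0] < rms[1] < rms[2]
        np.testing.assert_allclose(rms, [50, 100, 150], rtol=0.02)

    def test_quiescent_baseline(self):
        sig, _ = synthesize_emg([], duration=10.0, seed=1)
        assert np.sqrt(np.mean(sig.samples ** 2)) <= 2.0

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthesize_emg([((0.0, 5.0), 1), ((4.0, 8.0), 2)], duration=10.0)

    def test_deterministic(self):
        a, _ = synthesize_emg([((1.0, 3.0), 2)], duration=5.0, seed=9)
        b, _ = synthesize_emg([((1.0, 3.0), 2)], duration=5.0, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSynthesizeEEG:
    TIMELINE = [((0.0, 20.0), "eyes_closed"), ((20.0, 40.0), "eyes_open_calm")]

    def test_alpha_band_contrast_at_least_6_db(self):
        from bioqc.iosig import slice_signal
        from bioqc.spectral import band_power, psd
        sig, _ = synthesize_eeg(self.TIMELINE, seed=2)
        closed = band_power(psd(slice_signal(sig, 0, 20)), 8, 13)
        opened = band_power(psd(slice_signal(sig, 20, 40)), 8, 13)
        assert 10 * np.log10(closed / opened) >= 6.0

    def test_open_epoch_has_no_alpha(self):
        from bioqc.spectral import alpha_detect
        sig, _ = synthesize_eeg([((0.0, 30.0), "eyes_open_calm")], seed=3)
        verdict = alpha_detect(sig, [(5.0, 25.0)])[0]
        assert not verdict.present

    def test_zero_alpha_amplitude_not_detected(self):
        from bioqc.spectral import alpha_detect
        sig, _ = synthesize_eeg([((0.0, 30.0), "eyes_closed")], seed=4,
                                alpha_pp_range=(0.0, 0.0))
        assert not alpha_detect(sig, [(5.0, 25.0)])[0].present

    def test_moving_state_adds_low_freq_power(self):
        from bioqc.iosig import slice_signal
        from bioqc.spectral import band_power, psd
        tl = [((0.0, 20.0), "eyes_open_calm"), ((20.0, 40.0), "eyes_open_moving")]
        sig, _ = synthesize_eeg(tl, seed=5)
        calm = band_power(psd(slice_signal(sig, 0, 20)), 0.5, 4)
        moving = band_power(psd(slice_signal(sig, 20, 40)), 0.5, 4)
        assert moving > 4 * calm

    def test_overlapping_states_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthesize_eeg([((0.0, 10.0), "eyes_closed"),
                            ((5.0, 15.0), "eyes_open_calm")])


class TestAddNoise:
    def test_target_snr_inversion(self):
        rng = np.random.default_rng(0)
        sig = Signal(rng.standard_normal(100_000), 1000.0)
        noisy, achieved, trace = add_noise(
            sig, NoiseSpec(baseline=(0.3, 0.0), powerline=(60.0, 0.0),
                           target_snr_db=20.0, seed=1))
        assert achieved == pytest.approx(20.0, abs=1e-9)
        rms_sig = np.sqrt(np.mean((sig.samples - sig.samples.mean()) ** 2))
        rms_noise = np.sqrt(np.mean((trace - trace.mean()) ** 2))
        assert rms_noise / rms_sig == pytest.approx(0.1, rel=1e-6)

    def test_zero_noise_flags_infinite_snr(self):
        sig = Signal(np.sin(np.arange(5000) / 20.0), 1000.0)
        spec = NoiseSpec(baseline=(0.3, 0.0), powerline=(60.0, 0.0),
                         white_sd=0.0)
        _, achieved, trace = add_noise(sig, spec)
        assert np.isinf(achieved)
        assert np.all(trace == 0)

    def test_noise_floor_exceeding_target_rejected(self):
        sig = Signal(np.sin(2 * np.pi * 10 * np.arange(20000) / 1000.0), 1000.0)
        spec = NoiseSpec(baseline=(0.3, 10.0), powerline=(60.0, 10.0),
                         target_snr_db=40.0)
        with pytest.raises(ValueError, match="noise floor"):
            add_noise(sig, spec)

    def test_energy_additivity(self):
        """var(noisy) ~ var(clean) + var(noise) for independent components."""
        nn = generate_nn_series(NNGenSpec(n_beats=150, seed=11))
        clean, _ = synthesize_ecg(nn)
        noisy, _, trace = add_noise(clean, NoiseSpec(seed=12))
        lhs = np.var(noisy.samples)
        rhs = np.var(clean.samples) + np.var(trace)
        assert lhs == pytest.approx(rhs, rel=0.01)

    def test_reported_operating_point_oracle(self):
        """Noise injected at 28.3 dB is measured back exactly from the trace."""
        from bioqc.metrics import snr
        nn = generate_nn_series(NNGenSpec(n_beats=100, seed=21))
        clean, _ = synthesize_ecg(nn)
        _, achieved, trace = add_noise(clean,
                                       NoiseSpec(target_snr_db=28.3, seed=22))
        assert achieved == pytest.approx(28.3, abs=0.01)
        assert snr(clean.samples, trace).snr_db == pytest.approx(28.3, abs=0.01)
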