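"""Distortion suite: the condition grid and each family operator."""

import numpy as np
import pytest
from scipy.signal import fftconvolve, hilbert
from scipy.ndimage import uniform_filter1d

from audscene import distortions as D
from audscene.signal import Waveform, rms


class TestConditionGrid:
    def test_total_and_per_family_counts(self):
        conds = D.enumerate_conditions()
        assert len(conds) == 68
        counts = {}
        for c in conds:
            counts[c.family] = counts.get(c.family, 0) + 1
        assert counts == {
            "original": 1, "highpass": 5, "lowpass": 5, "bandpass_cf": 6,
            "bandpass_bw": 5, "tempo": 7, "reverb": 12, "local_reversal": 6,
            "peak_clip": 6, "vocode": 6, "spectral_modlp": 5,
            "temporal_modlp": 4,
        }
        assert sum(counts.values()) == 1 + 5 + 5 + 6 + 5 + 7 + 12 + 6 + 6 + 6 + 5 + 4

    def test_order_is_stable(self):
        a = [c.label() for c in D.enumerate_conditions()]
        b = [c.label() for c in D.enumerate_conditions()]
        assert a == b
        assert a[0] == "original()"

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            D.DistortionSpec("chorus", {})


class TestPostChain:
    @pytest.mark.parametrize("spec", [
        D.DistortionSpec("original"),
        D.DistortionSpec("highpass", {"cutoff_hz": 1600}),
        D.DistortionSpec("bandpass_bw", {"low_hz": 472, "high_hz": 4762}),
        D.DistortionSpec("tempo", {"factor": 1.25}),
        D.DistortionSpec("reverb", {"drr_db": 20, "rt60_ms": 400}),
        D.DistortionSpec("local_reversal", {"segment_ms": 30}),
        D.DistortionSpec("peak_clip", {"percentile": 0.5}),
        D.DistortionSpec("vocode", {"n_channels": 4}),
        D.DistortionSpec("temporal_modlp", {"cutoff_hz": 6}),
        D.DistortionSpec("spectral_modlp", {"cutoff_cyc_per_khz": 2}),
    ])
    def test_one_second_windowed_rms_contract(self, noise_1s_44k, spec):
        out = D.apply_distortion(noise_1s_44k, spec, seed=5)
        assert out.n_samples == 44100
        assert np.isfinite(out.samples).all()
        assert rms(out) == pytest.approx(0.01, abs=1e-9)
        # half-Hanning onsets: first and last samples are (near) zero
        assert abs(out.samples[0]) < 1e-6 and abs(out.samples[-1]) < 1e-6

    def test_original_is_identity_up_to_post_chain(self, noise_1s_44k):
        from audscene.signal import apply_onset_offset_window, normalize_rms

        out = D.apply_distortion(noise_1s_44k, D.DistortionSpec("original"))
        manual = normalize_rms(apply_onset_offset_window(noise_1s_44k), 0.01)
        assert np.allclose(out.samples, manual.samples)

    def test_subthreshold_clip_is_identity(self, noise_1s_44k):
        out = D.apply_distortion(
            noise_1s_44k, D.DistortionSpec("peak_clip", {"percentile": 1.0}))
        ref = D.apply_distortion(noise_1s_44k, D.DistortionSpec("original"))
        assert np.allclose(out.samples, ref.samples)


class TestButterworth:
    def test_lowpass_stopband_attenuation(self, noise_1s_44k):
        # Spectrum-integration oracle on Welch PSDs (windowing avoids the
        # leakage floor of a raw periodogram).
        from scipy.signal import welch

        out = D.butterworth_filter(noise_1s_44k, "low", 400)
        f, p_in = welch(noise_1s_44k.samples, fs=out.sr, nperseg=4096)
        _, p_out = welch(out.samples, fs=out.sr, nperseg=4096)
        passband = p_out[f < 300].sum() / p_in[f < 300].sum()
        stopband = p_out[f > 800].sum() / p_in[f > 800].sum()
        assert 10 * np.log10(passband / stopband) >= 40

    def test_highpass_removes_low_tone(self):
        t = np.arange(44100) / 44100
        tone = Waveform(0.01 * np.sin(2 * np.pi * 100 * t), 44100)
        out = D.butterworth_filter(tone, "high", 6400)
        assert rms(out) < 1e-3 * rms(tone)

    def test_zero_phase_forward_backward(self, noise_1s_44k):
        out = D.butterworth_filter(noise_1s_44k, "low", 4000)
        xc = fftconvolve(out.samples, noise_1s_44k.samples[::-1])
        assert abs(int(np.argmax(xc)) - (noise_1s_44k.n_samples - 1)) == 0

    def test_cutoff_above_nyquist_rejected(self, noise_1s_44k):
        with pytest.raises(ValueError):
            D.butterworth_filter(noise_1s_44k, "low", 30000)


class TestLocalTimeReverse:
    def test_tiny_example(self):
        wave = Waveform(np.array([1.0, 2.0, 3.0, 4.0]), 2000)
        out = D.local_time_reverse(wave, segment_ms=1.0)  # 2 samples
        assert np.array_equal(out.samples, [2.0, 1.0, 4.0, 3.0])

    def test_involution_is_bit_exact(self, noise_1s_44k):
        twice = D.local_time_reverse(
            D.local_time_reverse(noise_1s_44k, 37.0), 37.0)
        assert np.array_equal(twice.samples, noise_1s_44k.samples)

    def test_matches_index_permutation_oracle(self, noise_1s_44k):
        seg = int(round(0.1 * 44100))
        out = D.local_time_reverse(noise_1s_44k, 100.0)
        idx = np.arange(44100)
        perm = np.concatenate([idx[k:k + seg][::-1]
                               for k in range(0, 44100, seg)])
        assert np.array_equal(out.samples, noise_1s_44k.samples[perm])

    def test_partial_trailing_segment(self):
        wave = Waveform(np.arange(5.0), 1000)
        out = D.local_time_reverse(wave, 2.0)  # 2-sample segments
        assert np.array_equal(out.samples, [1.0, 0.0, 3.0, 2.0, 4.0])


class TestPeakClip:
    def test_full_percentile_is_identity(self, noise_1s_44k):
        out = D.peak_clip(noise_1s_44k, 1.0)
        assert np.array_equal(out.samples, noise_1s_44k.samples)

    def test_zero_percentile_collapses_to_min_magnitude(self):
        wave = Waveform(np.array([-2.0, 0.5, 1.0, -0.25]), 1000)
        out = D.peak_clip(wave, 0.0)
        m = np.abs(wave.samples).min()
        assert np.allclose(np.abs(out.samples), m)
        assert np.array_equal(np.sign(out.samples), np.sign(wave.samples))

    def test_quantile_count_matches_sorting_oracle(self):
        n = 10_000
        ramp = Waveform(np.linspace(-1.0, 1.0, n), 44100)
        out = D.peak_clip(ramp, 0.9)
        altered = int((out.samples != ramp.samples).sum())
        threshold = np.sort(np.abs(ramp.samples))[int(np.ceil(0.9 * (n - 1)))]
        expected = int((np.abs(ramp.samples) > threshold).sum())
        assert altered == pytest.approx(expected, abs=2)
        assert altered == pytest.approx(0.1 * n, rel=0.02)

    def test_idempotent_at_fixed_threshold(self, noise_1s_44k):
        once = D.peak_clip(noise_1s_44k, 0.8)
        twice = D.peak_clip(once, 1.0)  # same threshold: already at quantile 1
        assert np.array_equal(once.samples, twice.samples)


class TestNoiseVocode:
    @staticmethod
    def _channel_envelope(wave, n_channels, smooth):
        kernels = D._vocoder_bands(wave.sr).astype(np.float32)
        groups = D._group_bounds(kernels.shape[0], n_channels)
        sub = fftconvolve(wave.samples[None, :].astype(np.float32), kernels,
                          mode="full", axes=-1)[:, : wave.n_samples]
        chans = np.stack([sub[g].sum(axis=0) for g in groups])
        env = np.abs(hilbert(chans, axis=-1))
        return uniform_filter1d(env, size=smooth, axis=-1)

    @staticmethod
    def _am_noise(rate_hz=4.0, seed=2):
        t = np.arange(44100) / 44100
        gen = np.random.default_rng(seed)
        return Waveform(0.01 * gen.standard_normal(44100)
                        * (1 + 0.9 * np.sin(2 * np.pi * rate_hz * t)), 44100)

    def test_single_channel_preserves_broadband_envelope(self):
        am = self._am_noise()
        out = D.noise_vocode(am, 1, seed=7)
        e_in = self._channel_envelope(am, 1, smooth=882)[0]  # 20 ms
        e_out = self._channel_envelope(out, 1, smooth=882)[0]
        assert np.corrcoef(e_in, e_out)[0, 1] > 0.95

    def test_every_channel_envelope_is_preserved(self):
        # 50 ms smoothing: the comparison targets the slow modulations the
        # vocoder is meant to transmit, not the carrier's intrinsic
        # narrowband fluctuations.
        am = self._am_noise(seed=8)
        out = D.noise_vocode(am, 4, seed=3)
        e_in = self._channel_envelope(am, 4, smooth=2205)
        e_out = self._channel_envelope(out, 4, smooth=2205)
        for c in range(4):
            assert np.corrcoef(e_in[c], e_out[c])[0, 1] > 0.9

    def test_deterministic_given_seed(self, noise_1s_44k):
        a = D.noise_vocode(noise_1s_44k, 8, seed=11)
        b = D.noise_vocode(noise_1s_44k, 8, seed=11)
        assert np.array_equal(a.samples, b.samples)


class TestReverbIr:
    def test_rt60_and_drr_within_tolerance(self):
        ir = D.synth_reverb_ir(400, 20, sr=44100, seed=1)
        assert D.measure_rt60(ir) == pytest.approx(400, rel=0.15)
        assert D.measure_drr(ir) == pytest.approx(20, abs=1.0)

    def test_doubling_rt60_doubles_decay_time(self):
        short = D.synth_reverb_ir(300, 50, sr=44100, seed=2)
        long = D.synth_reverb_ir(600, 50, sr=44100, seed=2)
        ratio = D.measure_rt60(long) / D.measure_rt60(short)
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestTempoChange:
    def test_unit_factor_keeps_duration(self, noise_1s_44k):
        out = D.tempo_change(noise_1s_44k, 1.0)
        assert out.n_samples == noise_1s_44k.n_samples

    def test_double_tempo_halves_duration(self, noise_1s_44k):
        out = D.tempo_change(noise_1s_44k, 2.0)
        assert out.n_samples == pytest.approx(44100 / 2, abs=1103)  # 1 frame

    def test_pitch_preserved_under_slowdown(self):
        t = np.arange(44100) / 44100
        tone = Waveform(0.01 * np.sin(2 * np.pi * 440 * t), 44100)
        out = D.tempo_change(tone, 0.5)
        spec = np.abs(np.fft.rfft(out.samples * np.hanning(out.n_samples)))
        f = np.fft.rfftfreq(out.n_samples, 1 / 44100)
        assert f[np.argmax(spec)] == pytest.approx(440, rel=0.01)


class TestModulationLowpass:
    @staticmethod
    def _envelope_peak_db(wave, freq):
        env = np.abs(hilbert(wave.samples))
        env = env - env.mean()
        spec = np.abs(np.fft.rfft(env)) ** 2
        f = np.fft.rfftfreq(env.size, 1 / wave.sr)
        peak = spec[(f > freq - 1) & (f < freq + 1)].max()
        floor = np.median(spec[(f > 0.5) & (f < 64)])
        return 10 * np.log10(peak / floor)

    def test_slow_am_survives_high_cutoff(self):
        t = np.arange(44100) / 44100
        gen = np.random.default_rng(4)
        carrier = 0.01 * gen.standard_normal(44100)
        am = Waveform(carrier * (1 + 0.9 * np.sin(2 * np.pi * 4 * t)), 44100)
        out = D.modulation_lowpass(am, "temporal", 24)
        assert self._envelope_peak_db(out, 4) >= self._envelope_peak_db(am, 4) - 3

    def test_fast_am_removed_by_low_cutoff(self):
        t = np.arange(44100) / 44100
        gen = np.random.default_rng(5)
        carrier = 0.01 * gen.standard_normal(44100)
        am = Waveform(carrier * (1 + 0.9 * np.sin(2 * np.pi * 16 * t)), 44100)
        out = D.modulation_lowpass(am, "temporal", 3)
        assert self._envelope_peak_db(out, 16) <= self._envelope_peak_db(am, 16) - 10

    def test_huge_cutoff_approaches_passthrough(self, noise_1s_44k):
        from scipy.signal import stft

        out = D.modulation_lowpass(noise_1s_44k, "temporal", 1e6, n_iter=5)
        _, _, a = stft(noise_1s_44k.samples, fs=44100, nperseg=1024,
                       noverlap=768)
        _, _, b = stft(out.samples, fs=44100, nperseg=1024, noverlap=768)
        rel = np.linalg.norm(np.abs(a) - np.abs(b)) / np.linalg.norm(np.abs(a))
        assert rel < 0.1

    def test_invalid_domain_rejected(self, noise_1s_44k):
        with pytest.raises(ValueError):
            D.modulation_lowpass(noise_1s_44k, "cepstral", 4)


class TestSeverityOrdering:
    def test_vocode_channel_count_and_dprime_increase_together(self, small_bank):
        """More vocoder channels preserve more spectral detail, so a fixed
        linear recognizer's sensitivity should rise with channel count."""
        from audscene.models import TrainConfig, predict, scene_features, train
        from audscene.psychometrics import auc_dprime

        cats = small_bank.category_ids
        waves, labels = [], []
        for (cat, ex), wave in small_bank.exemplars.items():
            waves.append(wave)
            row = np.zeros(len(cats))
            row[cats.index(cat)] = 1.0
            labels.append(row)
        X = scene_features(waves, "coch_mean", n_channels=48, frame_rate=200)
        head = train(X, np.asarray(labels), categories=cats,
                     cfg=TrainConfig(learning_rate=3e-2, seed=1,
                                     max_epochs=200))

        gen = np.random.default_rng(5)
        dprimes = []
        for n_ch in (1, 8, 32):
            spec = D.DistortionSpec("vocode", {"n_channels": n_ch})
            distorted = [D.apply_distortion(w, spec, seed=9) for w in waves]
            Xd = scene_features(distorted, "coch_mean", n_channels=48,
                                frame_rate=200)
            scores = predict(head, Xd)
            present, absent = [], []
            for i, (cat, _ex) in enumerate(small_bank.exemplars):
                j = cats.index(cat)
                present.append(scores[i, j])
                absent.append(scores[i, int(gen.choice(
                    [k for k in range(len(cats)) if k != j]))])
            dprimes.append(auc_dprime(present, absent))
        assert dprimes[0] <= dprimes[1] <= dprimes[2]
        assert dprimes[2] > dprimes[0]
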