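"""Parametric audio distortion suite.

Implements the twelve stimulus conditions of the distortion benchmark —
the unmodified original plus eleven distortion families — and enumerates
the full 68-condition grid:

====================  ==============================================
family                levels
====================  ==============================================
original              (none)
highpass              cutoffs 400, 800, 1600, 3200, 6400 Hz
lowpass               cutoffs 400, 800, 1600, 3200, 6400 Hz
bandpass_cf           [150,300] ... [4800,9600] Hz (6 bands)
bandpass_bw           [1124,2002] ... [149,15119] Hz (5 bands)
tempo                 factors 0.5 ... 2 (7 values, WSOLA)
reverb                DRR {20,50,80} dB x RT60 {200,400,800,1600} ms
local_reversal        segments 10, 20, 30, 40, 50, 100 ms
peak_clip             percentiles 0, 0.25, 0.5, 0.75, 0.9, 0.98
vocode                1, 2, 4, 8, 16, 32 channels
spectral_modlp        0.5, 1, 2, 4, 8 cycles/kHz
temporal_modlp        3, 6, 12, 24 Hz
====================  ==============================================

Every distorted stimulus goes through a common post-chain: truncation to
1 s, 10 ms half-Hanning onset/offset windows, and RMS normalization to
0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import butter, fftconvolve, hilbert, sosfiltfilt, stft, istft

from .frontend import _gammatone_kernels, erb_number, erb_number_to_hz
from .signal import Waveform, apply_onset_offset_window, normalize_rms, rms

__all__ = [
    "DistortionSpec",
    "ImpulseResponse",
    "enumerate_conditions",
    "apply_distortion",
    "butterworth_filter",
    "local_time_reverse",
    "peak_clip",
    "noise_vocode",
    "synth_reverb_ir",
    "measure_rt60",
    "measure_drr",
    "tempo_change",
    "modulation_lowpass",
]

FAMILIES = (
    "original",
    "highpass",
    "lowpass",
    "bandpass_cf",
    "bandpass_bw",
    "tempo",
    "reverb",
    "local_reversal",
    "peak_clip",
    "vocode",
    "spectral_modlp",
    "temporal_modlp",
)

HIGHPASS_CUTOFFS_HZ = (400, 800, 1600, 3200, 6400)
LOWPASS_CUTOFFS_HZ = (400, 800, 1600, 3200, 6400)
BANDPASS_CF_HZ = ((150, 300), (300, 600), (600, 1200), (1200, 2400),
                  (2400, 4800), (4800, 9600))
BANDPASS_BW_HZ = ((1124, 2002), (842, 2673), (472, 4762), (265, 8485),
                  (149, 15119))
TEMPO_FACTORS = (0.5, 0.75, 0.875, 1.125, 1.25, 1.5, 2.0)
REVERB_DRR_DB = (20, 50, 80)
REVERB_RT60_MS = (200, 400, 800, 1600)
REVERSAL_SEGMENTS_MS = (10, 20, 30, 40, 50, 100)
CLIP_PERCENTILES = (0.0, 0.25, 0.5, 0.75, 0.9, 0.98)
VOCODE_CHANNELS = (1, 2, 4, 8, 16, 32)
SPECTRAL_MODLP_CYC_PER_KHZ = (0.5, 1, 2, 4, 8)
TEMPORAL_MODLP_HZ = (3, 6, 12, 24)

STIMULUS_DUR_S = 1.0
STIMULUS_RMS = 0.01


@dataclass(frozen=True)
class DistortionSpec:
    """A distortion family plus its level parameters."""

    family: str
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distortion family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))

    def label(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.params.items())
        return f"{self.family}({inner})"


def enumerate_conditions() -> list[DistortionSpec]:
    """The 68 benchmark conditions in stable (table) order."""
    conditions = [DistortionSpec("original")]
    conditions += [DistortionSpec("highpass", {"cutoff_hz": c})
                   for c in HIGHPASS_CUTOFFS_HZ]
    conditions += [DistortionSpec("lowpass", {"cutoff_hz": c})
                   for c in LOWPASS_CUTOFFS_HZ]
    conditions += [DistortionSpec("bandpass_cf", {"low_hz": lo, "high_hz": hi})
                   for lo, hi in BANDPASS_CF_HZ]
    conditions += [DistortionSpec("bandpass_bw", {"low_hz": lo, "high_hz": hi})
                   for lo, hi in BANDPASS_BW_HZ]
    conditions += [DistortionSpec("tempo", {"factor": f}) for f in TEMPO_FACTORS]
    conditions += [DistortionSpec("reverb", {"drr_db": drr, "rt60_ms": rt})
                   for drr in REVERB_DRR_DB for rt in REVERB_RT60_MS]
    conditions += [DistortionSpec("local_reversal", {"segment_ms": s})
                   for s in REVERSAL_SEGMENTS_MS]
    conditions += [DistortionSpec("peak_clip", {"percentile": p})
                   for p in CLIP_PERCENTILES]
    conditions += [DistortionSpec("vocode", {"n_channels": n})
                   for n in VOCODE_CHANNELS]
    conditions += [DistortionSpec("spectral_modlp", {"cutoff_cyc_per_khz": c})
                   for c in SPECTRAL_MODLP_CYC_PER_KHZ]
    conditions += [DistortionSpec("temporal_modlp", {"cutoff_hz": c})
                   for c in TEMPORAL_MODLP_HZ]
    return conditions


# ---------------------------------------------------------------------------
# Family operators
# ---------------------------------------------------------------------------


def butterworth_filter(wave: Waveform, kind: str, cutoffs) -> Waveform:
    """Zero-phase 4th-order Butterworth filter (forward and reverse passes).

    ``kind`` is 'high', 'low' or 'band'; ``cutoffs`` a scalar (high/low)
    or (low, high) pair in Hz, all below the Nyquist frequency.
    """
    nyq = wave.sr / 2
    c = np.atleast_1d(np.asarray(cutoffs, dtype=np.float64))
    if np.any(c >= nyq):
        raise ValueError(f"cutoff {cutoffs} at or above Nyquist ({nyq} Hz)")
    btype = {"high": "highpass", "low": "lowpass", "band": "bandpass"}[kind]
    sos = butter(4, c if c.size > 1 else c[0], btype=btype, fs=wave.sr,
                 output="sos")
    return wave.with_samples(sosfiltfilt(sos, wave.samples))


def local_time_reverse(wave: Waveform, segment_ms: float) -> Waveform:
    """Reverse the signal within adjacent non-overlapping segments.

    Complete segments are reversed in place; a trailing partial segment is
    reversed as-is. Applying the operator twice restores the input exactly.
    """
    if segment_ms <= 0:
        raise ValueError("segment duration must be positive")
    seg = max(int(round(segment_ms * wave.sr / 1000.0)), 1)
    out = wave.samples.copy()
    for start in range(0, out.size, seg):
        out[start : start + seg] = out[start : start + seg][::-1]
    return wave.with_samples(out)


def peak_clip(wave: Waveform, percentile: float) -> Waveform:
    """Clip sample magnitudes above the given quantile of |amplitude|.

    The threshold is the ``percentile`` quantile of absolute sample values;
    samples beyond it are replaced by ``sign(x) * threshold``. 1.0 is the
    identity; 0 collapses the signal to a near-square wave.
    """
    if not 0.0 <= percentile <= 1.0:
        raise ValueError("percentile must lie in [0, 1]")
    threshold = float(np.quantile(np.abs(wave.samples), percentile))
    return wave.with_samples(np.clip(wave.samples, -threshold, threshold))


def _vocoder_bands(sr: int, n_bands: int = 64) -> np.ndarray:
    """ERB-spaced gammatone analysis filters covering 80 Hz to ~0.9 Nyquist."""
    hi = min(0.45 * sr, 20000.0)
    kernels, _ = _gammatone_kernels(n_bands, 80.0, hi, sr)
    return kernels


def _group_bounds(n_bands: int, n_channels: int) -> list[slice]:
    """Split band indices into contiguous groups of (near-)equal ERB span."""
    edges = np.linspace(0, n_bands, n_channels + 1).round().astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def noise_vocode(wave: Waveform, n_channels: int, seed: int,
                 n_bands: int = 64) -> Waveform:
    """Replace the sound's fine structure with envelope-modulated noise.

    The signal is decomposed with ERB-spaced filters grouped into
    ``n_channels`` contiguous channels (each spanning an equal slice of the
    ERB axis); Hilbert envelopes of each channel provide the targets.
    Seeded Gaussian noise is passed through the same channels, its envelope
    divided out and the target envelope imposed, and the channels summed.
    """
    if n_channels < 1:
        raise ValueError("need at least one vocoder channel")
    kernels = _vocoder_bands(wave.sr, n_bands).astype(np.float32)
    groups = _group_bounds(kernels.shape[0], n_channels)

    def channel_signals(x: np.ndarray) -> np.ndarray:
        sub = fftconvolve(x[None, :].astype(np.float32), kernels,
                          mode="full", axes=-1)[:, : x.size]
        return np.stack([sub[g].sum(axis=0) for g in groups])

    target = channel_signals(wave.samples)
    target_env = np.abs(hilbert(target, axis=-1))

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(wave.n_samples)
    carrier = channel_signals(noise)
    carrier_env = np.abs(hilbert(carrier, axis=-1))
    eps = 1e-8 * max(carrier_env.max(), np.finfo(np.float32).tiny)
    vocoded = carrier / np.maximum(carrier_env, eps) * target_env
    return wave.with_samples(vocoded.sum(axis=0).astype(np.float64))


@dataclass(frozen=True)
class ImpulseResponse:
    """Synthesized room impulse response with nominal RT60 (ms) and DRR (dB)."""

    samples: np.ndarray
    sr: int
    rt60: float  # ms
    drr: float  # dB
    direct_end: int = 0  # sample index separating direct sound from tail


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spectrum /= np.sqrt(f)
    return np.fft.irfft(spectrum, n)


def _rt60_profile(f_hz: np.ndarray) -> np.ndarray:
    """Frequency-dependent RT60 scale: 1 below 4 kHz, shrinking to 0.5 at 20 kHz.

    The shortening is linear on a log-frequency axis, mimicking the faster
    high-frequency decay of real rooms (air and material absorption).
    """
    scale = np.ones_like(f_hz, dtype=np.float64)
    hi = f_hz > 4000.0
    frac = np.log(f_hz[hi] / 4000.0) / np.log(20000.0 / 4000.0)
    scale[hi] = 1.0 - 0.5 * np.clip(frac, 0.0, 1.0)
    return scale


def synth_reverb_ir(rt60: float, drr: float, sr: int, seed: int,
                    n_bands: int = 32, gap_ms: float = 5.0) -> ImpulseResponse:
    """Synthesize a room impulse response with given RT60 (ms) and DRR (dB).

    Pink noise is decomposed into cochlear (gammatone) subbands; each
    subband is multiplied by an exponentially decaying envelope whose decay
    anchors the nominal RT60 (shortened at high frequencies per
    :func:`_rt60_profile`); subbands are summed to form the reverberant
    tail. A direct impulse is prepended and scaled so that the
    direct-to-reverberant energy ratio equals ``drr`` exactly.
    """
    if rt60 <= 0:
        raise ValueError("rt60 must be positive")
    rng = np.random.default_rng(seed)
    rt60_s = rt60 / 1000.0
    tail_dur = 1.5 * rt60_s
    n_tail = int(round(tail_dur * sr))
    noise = _pink_noise(n_tail, rng)
    hi = min(0.45 * sr, 20000.0)
    kernels, cfs = _gammatone_kernels(n_bands, 80.0, hi, sr)
    sub = fftconvolve(noise[None, :], kernels.astype(np.float64), mode="full",
                      axes=-1)[:, :n_tail]
    t = np.arange(n_tail) / sr
    band_rt60 = rt60_s * _rt60_profile(cfs)
    # Amplitude envelope 10^(-3 t / RT60): energy falls 60 dB at t = RT60.
    env = 10.0 ** (-3.0 * t[None, :] / band_rt60[:, None])
    tail = (sub * env).sum(axis=0)

    gap = int(round(gap_ms * sr / 1000.0))
    e_tail = float(np.sum(tail**2))
    direct_amp = np.sqrt(e_tail * 10.0 ** (drr / 10.0))
    ir = np.concatenate([np.zeros(gap), tail])
    ir[0] = direct_amp
    return ImpulseResponse(samples=ir, sr=sr, rt60=rt60, drr=drr,
                           direct_end=gap)


def measure_rt60(ir: ImpulseResponse) -> float:
    """RT60 (ms) of the reverberant tail via Schroeder backward integration.

    Returns the time at which the energy-decay curve of the tail first
    falls 60 dB below its initial value.
    """
    tail = ir.samples[ir.direct_end :]
    edc = np.cumsum(tail[::-1] ** 2)[::-1]
    edc_db = 10.0 * np.log10(np.maximum(edc / edc[0], 1e-30))
    below = np.nonzero(edc_db <= -60.0)[0]
    if below.size == 0:
        return 1000.0 * tail.size / ir.sr
    return 1000.0 * below[0] / ir.sr


def measure_drr(ir: ImpulseResponse) -> float:
    """Direct-to-reverberant energy ratio in dB."""
    direct = ir.samples[: ir.direct_end]
    tail = ir.samples[ir.direct_end :]
    return 10.0 * np.log10(np.sum(direct**2) / np.sum(tail**2))


def tempo_change(wave: Waveform, factor: float,
                 frame_ms: float = 25.0, search_ms: float = 10.0) -> Waveform:
    """Change tempo by ``factor`` without changing pitch (WSOLA).

    Output duration is approximately ``duration / factor``. Overlap-add
    with 50%-overlapping Hann-windowed frames; each analysis frame is
    chosen within +/- ``search_ms`` of its nominal position to maximize
    cross-correlation with the natural continuation of the previous frame.
    """
    if factor <= 0:
        raise ValueError("tempo factor must be positive")
    x = wave.samples
    n = x.size
    frame = max(int(round(frame_ms * wave.sr / 1000.0)), 16)
    frame -= frame % 2
    hop_syn = frame // 2
    hop_ana = factor * hop_syn
    tol = int(round(search_ms * wave.sr / 1000.0))
    window = np.hanning(frame)

    n_out = int(round(n / factor))
    out = np.zeros(n_out + frame)
    norm = np.zeros(n_out + frame)
    x_pad = np.pad(x, (tol, frame + tol))

    prev_sel = None
    k = 0
    while k * hop_syn < n_out:
        nominal = int(round(k * hop_ana))
        if nominal >= n:
            break
        if prev_sel is None:
            sel = nominal
        else:
            # Natural continuation of the previously copied frame.
            target = x_pad[prev_sel + hop_syn + tol : prev_sel + hop_syn + tol + frame]
            lo = max(nominal - tol, 0)
            region = x_pad[lo + tol - tol : lo + tol + tol + frame]  # len 2*tol+frame
            corr = fftconvolve(region, target[::-1], mode="valid")
            sel = lo - tol + int(np.argmax(corr))
        seg = x_pad[sel + tol : sel + tol + frame]
        pos = k * hop_syn
        out[pos : pos + frame] += seg * window
        norm[pos : pos + frame] += window
        prev_sel = sel
        k += 1
    out = out[:n_out] / np.maximum(norm[:n_out], 1e-8)
    return wave.with_samples(out)


def modulation_lowpass(wave: Waveform, domain: str, cutoff: float,
                       n_iter: int = 50, nperseg: int = 1024,
                       tol: float = 1e-4) -> Waveform:
    """Lowpass-filter the signal's modulation spectrum and resynthesize.

    The magnitude spectrogram's 2-D Fourier transform (the modulation
    spectrum) is attenuated beyond ``cutoff`` along the stated axis —
    spectral modulations in cycles/kHz or temporal modulations in Hz — with
    a raised-cosine edge reaching zero at 1.4x the cutoff. The filtered
    magnitude is combined with the original phase and refined by iterative
    phase recovery (alternating projection onto the target magnitude),
    stopping after ``n_iter`` iterations or when the relative spectrogram
    change drops below ``tol``.
    """
    if domain not in ("spectral", "temporal"):
        raise ValueError("domain must be 'spectral' or 'temporal'")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    noverlap = nperseg * 3 // 4
    f, t, Z = stft(wave.samples, fs=wave.sr, nperseg=nperseg, noverlap=noverlap)
    mag, phase = np.abs(Z), np.angle(Z)

    if domain == "spectral":
        # Modulation frequencies along the (linear) spectral axis, cyc/kHz.
        df_khz = (f[1] - f[0]) / 1000.0
        mod_f = np.abs(np.fft.fftfreq(mag.shape[0], d=df_khz))
        axis = 0
    else:
        dt = t[1] - t[0]
        mod_f = np.abs(np.fft.fftfreq(mag.shape[1], d=dt))
        axis = 1
    ramp = np.clip((1.4 * cutoff - mod_f) / (0.4 * cutoff), 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * ramp)
    mask[mod_f <= cutoff] = 1.0

    spec = np.fft.fft(mag, axis=axis)
    shape = [1, 1]
    shape[axis] = mask.size
    mag_f = np.real(np.fft.ifft(spec * mask.reshape(shape), axis=axis))
    mag_f = np.maximum(mag_f, 0.0)

    # Phase recovery: alternate between the target magnitude and the STFT
    # of the current time-domain estimate, starting from the input's phase.
    Zk = mag_f * np.exp(1j * phase)
    prev = None
    for _ in range(n_iter):
        _, y = istft(Zk, fs=wave.sr, nperseg=nperseg, noverlap=noverlap)
        _, _, Zy = stft(y, fs=wave.sr, nperseg=nperseg, noverlap=noverlap)
        Zy = Zy[:, : mag_f.shape[1]]
        if Zy.shape[1] < mag_f.shape[1]:
            Zy = np.pad(Zy, ((0, 0), (0, mag_f.shape[1] - Zy.shape[1])))
        cur = np.abs(Zy)
        if prev is not None:
            denom = max(np.linalg.norm(prev), 1e-12)
            if np.linalg.norm(cur - prev) / denom < tol:
                Zk = mag_f * np.exp(1j * np.angle(Zy))
                break
        prev = cur
        Zk = mag_f * np.exp(1j * np.angle(Zy))
    _, y = istft(Zk, fs=wave.sr, nperseg=nperseg, noverlap=noverlap)
    y = y[: wave.n_samples]
    if y.size < wave.n_samples:
        y = np.pad(y, (0, wave.n_samples - y.size))
    return wave.with_samples(y)


# ---------------------------------------------------------------------------
# Dispatch + common post-chain
# ---------------------------------------------------------------------------


def _finalize(wave: Waveform) -> Waveform:
    n_target = int(round(STIMULUS_DUR_S * wave.sr))
    samples = wave.samples[:n_target]
    if samples.size < n_target:
        samples = np.pad(samples, (0, n_target - samples.size))
    out = apply_onset_offset_window(wave.with_samples(samples))
    return normalize_rms(out, STIMULUS_RMS)


def apply_distortion(wave: Waveform, spec: DistortionSpec, seed: int = 0) -> Waveform:
    """Apply one benchmark distortion and the common post-chain.

    The post-chain truncates (or zero-pads) to 1 s, applies 10 ms
    half-Hanning onset/offset windows, and RMS-normalizes to 0.01. The
    ``seed`` is consumed only by the stochastic families (vocode, reverb).
    """
    family, p = spec.family, spec.params
    if family == "original":
        out = wave
    elif family == "highpass":
        out = butterworth_filter(wave, "high", p["cutoff_hz"])
    elif family == "lowpass":
        out = butterworth_filter(wave, "low", p["cutoff_hz"])
    elif family in ("bandpass_cf", "bandpass_bw"):
        high = min(p["high_hz"], 0.99 * wave.sr / 2)
        out = butterworth_filter(wave, "band", (p["low_hz"], high))
    elif family == "tempo":
        out = tempo_change(wave, p["factor"])
    elif family == "reverb":
        ir = synth_reverb_ir(p["rt60_ms"], p["drr_db"], wave.sr, seed)
        mix = fftconvolve(wave.samples, ir.samples)[: wave.n_samples]
        out = wave.with_samples(mix)
    elif family == "local_reversal":
        out = local_time_reverse(wave, p["segment_ms"])
    elif family == "peak_clip":
        out = peak_clip(wave, p["percentile"])
    elif family == "vocode":
        out = noise_vocode(wave, p["n_channels"], seed)
    elif family == "spectral_modlp":
        out = modulation_lowpass(wave, "spectral", p["cutoff_cyc_per_khz"])
    elif family == "temporal_modlp":
        out = modulation_lowpass(wave, "temporal", p["cutoff_hz"])
    else:  # pragma: no cover - guarded by DistortionSpec
        raise ValueError(f"unknown family {family!r}")
    return _finalize(out)
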