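"""Core audio carriers and shared signal utilities.

The :class:`Waveform` dataclass is the universal audio container used
throughout the package: a 1-D float array of samples plus a sample rate.
This module also hosts the handful of primitives every other module leans
on — RMS normalization, half-Hanning onset/offset windows, Kaiser-windowed
sinc resampling, and plain-text-friendly WAV I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import upfirdn

__all__ = [
    "Waveform",
    "rms",
    "normalize_rms",
    "half_hann_window",
    "apply_onset_offset_window",
    "kaiser_sinc_kernel",
    "resample",
    "read_wav",
    "write_wav",
]

# Resampling anti-aliasing filter constants (Kaiser-best windowed sinc).
KAISER_WIDTH = 64
KAISER_ROLLOFF = 0.94759
KAISER_BETA = 14.76965


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal: ``samples`` (float array) at sample rate ``sr`` Hz."""

    samples: np.ndarray
    sr: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"waveform must be 1-D, got shape {samples.shape}")
        if self.sr <= 0:
            raise ValueError(f"sample rate must be positive, got {self.sr}")
        if samples.size and not np.isfinite(samples).any():
            raise ValueError("waveform contains no finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sr

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def rms(x: np.ndarray | Waveform) -> float:
    """Root-mean-square amplitude."""
    samples = x.samples if isinstance(x, Waveform) else np.asarray(x, dtype=np.float64)
    if samples.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(samples**2)))


def normalize_rms(wave: Waveform, target: float = 0.01) -> Waveform:
    """Scale ``wave`` so its RMS amplitude equals ``target``.

    Silent input is returned unchanged (there is no finite gain that can
    reach the target).
    """
    level = rms(wave)
    if level == 0.0:
        return wave
    return wave.with_samples(wave.samples * (target / level))


def half_hann_window(n: int) -> np.ndarray:
    """Rising half of a Hann window of ``n`` samples (0 -> 1)."""
    if n <= 0:
        return np.ones(0)
    # Rising half of a (2n)-point Hann; endpoint reaches exactly 1.
    k = np.arange(n, dtype=np.float64)
    return 0.5 * (1.0 - np.cos(np.pi * k / max(n - 1, 1)))


def apply_onset_offset_window(wave: Waveform, ramp_s: float = 0.010) -> Waveform:
    """Apply multiplicative half-Hanning ramps at onset and offset.

    ``ramp_s`` is the ramp duration in seconds (10 ms default). Ramps longer
    than half the signal are shortened to fit.
    """
    n_ramp = int(round(ramp_s * wave.sr))
    n_ramp = min(n_ramp, wave.n_samples // 2)
    if n_ramp == 0:
        return wave
    out = wave.samples.copy()
    ramp = half_hann_window(n_ramp)
    out[:n_ramp] *= ramp
    out[-n_ramp:] *= ramp[::-1]
    return wave.with_samples(out)


def kaiser_sinc_kernel(
    sr_in: int,
    sr_out: int,
    width: int = KAISER_WIDTH,
    rolloff: float = KAISER_ROLLOFF,
    beta: float = KAISER_BETA,
) -> tuple[np.ndarray, int, int]:
    """Windowed-sinc anti-aliasing FIR for polyphase resampling.

    The lowpass cutoff is ``rolloff`` times the Nyquist frequency of the
    slower of the two rates, and the sinc extends ``width`` zero crossings
    to each side, tapered by a Kaiser window of parameter ``beta``.

    Returns ``(kernel, up, down)`` where the kernel is sampled at rate
    ``sr_in * up`` and normalized to unit DC gain after polyphase
    decimation.
    """
    g = math.gcd(int(sr_in), int(sr_out))
    up, down = sr_out // g, sr_in // g
    # Cutoff as a fraction of the high (upsampled) rate.
    cutoff = rolloff * 0.5 * min(sr_in, sr_out) / (sr_in * up)
    half_len = int(math.ceil(width / (2.0 * cutoff)))
    n = np.arange(-half_len, half_len + 1, dtype=np.float64)
    kernel = 2.0 * cutoff * np.sinc(2.0 * cutoff * n)
    kernel *= np.kaiser(kernel.size, beta)
    kernel *= up / kernel.sum()
    return kernel, up, down


def resample(wave: Waveform, sr_out: int) -> Waveform:
    """Resample to ``sr_out`` Hz with the Kaiser-windowed sinc filter.

    Output length is ``round(n * sr_out / sr_in)``; the polyphase output is
    trimmed/padded symmetrically about the filter's group delay.
    """
    if sr_out <= 0:
        raise ValueError("output sample rate must be positive")
    if sr_out == wave.sr:
        return wave
    kernel, up, down = kaiser_sinc_kernel(wave.sr, sr_out)
    y = upfirdn(kernel, wave.samples, up=up, down=down)
    delay = (kernel.size - 1) // 2  # taps at the upsampled rate
    start = delay // down
    n_out = int(round(wave.n_samples * sr_out / wave.sr))
    y = y[start : start + n_out]
    if y.size < n_out:
        y = np.pad(y, (0, n_out - y.size))
    return Waveform(y, sr_out)


def read_wav(path) -> Waveform:
    """Read a WAV file to a float64 mono :class:`Waveform` in [-1, 1]."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Waveform(data.astype(np.float64), int(sr))


def write_wav(path, wave: Waveform) -> None:
    """Write a :class:`Waveform` as 32-bit float PCM."""
    wavfile.write(path, wave.sr, wave.samples.astype(np.float32))
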