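"""Synthetic, ground-truth-known stand-ins for benchmark inputs.

Two generators:

* a bank of category-structured sound exemplars — each category is a
  band-limited noise with optional amplitude modulation and a harmonic
  component, so categories differ in both spectral and temporal structure,
  and exemplars within a category are jittered versions of the category
  prototype;

* synthetic voxel-response datasets — noisy linear readouts of a model
  stage's features across repeated scans, for exercising the encoding
  analyses with known ground truth.

Both are pure functions of their seeds and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import Waveform, normalize_rms, write_wav

__all__ = [
    "CategorySpec",
    "synth_exemplar",
    "CategoryBank",
    "make_category_bank",
    "SyntheticVoxelSet",
    "synth_voxel_dataset",
]

DEFAULT_SR = 48000
DEFAULT_DURATION_S = 1.0
EXEMPLAR_RMS = 0.01
AM_DEPTH = 0.9


@dataclass(frozen=True)
class CategorySpec:
    """Acoustic parameters defining one synthetic sound category."""

    category_id: int
    center_freq: float  # Hz, in [80, 12000]
    bandwidth: float  # Hz, > 0
    am_rate: float  # Hz, in [0, 64]; 0 disables amplitude modulation
    harmonic_weight: float  # in [0, 1]: relative level of the harmonic stack
    exemplar_jitter: float = 0.0  # fractional s.d. of per-exemplar perturbation

    def __post_init__(self):
        if not 80.0 <= self.center_freq <= 12000.0:
            raise ValueError(f"center_freq {self.center_freq} outside [80, 12000] Hz")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not 0.0 <= self.am_rate <= 64.0:
            raise ValueError(f"am_rate {self.am_rate} outside [0, 64] Hz")
        if not 0.0 <= self.harmonic_weight <= 1.0:
            raise ValueError("harmonic_weight must lie in [0, 1]")


def synth_exemplar(spec: CategorySpec, duration: float = DEFAULT_DURATION_S,
                   sr: int = DEFAULT_SR, seed: int = 0) -> Waveform:
    """Synthesize one exemplar waveform for a category.

    Band-limited Gaussian noise is built directly in the frequency domain
    (bins outside ``center_freq +/- bandwidth/2`` are zero), mixed with a
    harmonic stack weighted by ``harmonic_weight``, and amplitude-modulated
    at ``am_rate`` Hz. Output has exactly ``round(duration * sr)`` samples,
    RMS 0.01, and is bit-reproducible for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sr < 2 * (spec.center_freq + spec.bandwidth):
        raise ValueError(
            f"sample rate {sr} too low for center_freq {spec.center_freq} "
            f"+ bandwidth {spec.bandwidth}"
        )
    n = int(round(duration * sr))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, 1.0 / sr)
    lo = max(spec.center_freq - spec.bandwidth / 2, 0.0)
    hi = spec.center_freq + spec.bandwidth / 2
    band = (freqs >= lo) & (freqs <= hi)
    spectrum = np.zeros(freqs.size, dtype=complex)
    spectrum[band] = rng.standard_normal(band.sum()) + 1j * rng.standard_normal(band.sum())
    noise = np.fft.irfft(spectrum, n)
    noise /= max(np.sqrt(np.mean(noise**2)), 1e-30)

    if spec.harmonic_weight > 0:
        f0 = spec.center_freq / 2.0
        t = np.arange(n) / sr
        tone = np.zeros(n)
        for h in range(1, 5):
            fh = h * f0
            if fh < sr / 2:
                tone += np.sin(2 * np.pi * fh * t + rng.uniform(0, 2 * np.pi)) / h
        tone /= max(np.sqrt(np.mean(tone**2)), 1e-30)
        x = (1 - spec.harmonic_weight) * noise + spec.harmonic_weight * tone
    else:
        x = noise

    if spec.am_rate > 0:
        t = np.arange(n) / sr
        x = x * (1.0 + AM_DEPTH * np.sin(2 * np.pi * spec.am_rate * t))

    return normalize_rms(Waveform(x, sr), EXEMPLAR_RMS)


@dataclass
class CategoryBank:
    """Category specs plus their synthesized exemplar waveforms."""

    specs: list  # of CategorySpec
    exemplars: dict = field(repr=False)  # (category_id, exemplar_id) -> Waveform
    n_exemplars: int = 1
    sr: int = DEFAULT_SR
    seed: int = 0

    @property
    def n_categories(self) -> int:
        return len(self.specs)

    @property
    def category_ids(self) -> list:
        return [s.category_id for s in self.specs]

    def get_exemplar(self, category_id: int, exemplar_id: int) -> Waveform:
        return self.exemplars[(category_id, exemplar_id)]

    def save(self, out_dir) -> None:
        """Write exemplars as WAV plus a CSV manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for (cat, ex), wave in self.exemplars.items():
            path = out / f"cat{cat:03d}_ex{ex:02d}.wav"
            write_wav(path, wave)
            rows.append({"path": path.name, "category_id": cat,
                         "exemplar_id": ex, "seed": self.seed})
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def _prototype_specs(n_categories: int, exemplar_jitter: float) -> list[CategorySpec]:
    """Parameter-distinct category prototypes covering the spectral and
    temporal parameter space."""
    cfs = np.geomspace(250.0, 8000.0, n_categories)
    am_grid = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    hw_grid = (0.0, 0.3, 0.7)
    specs = []
    for i, cf in enumerate(cfs):
        specs.append(CategorySpec(
            category_id=i,
            center_freq=float(cf),
            bandwidth=float(0.5 * cf),
            am_rate=am_grid[i % len(am_grid)],
            harmonic_weight=hw_grid[i % len(hw_grid)],
            exemplar_jitter=exemplar_jitter,
        ))
    return specs


def make_category_bank(n_categories: int = 51, n_exemplars: int = 10,
                       seed: int = 0, duration: float = DEFAULT_DURATION_S,
                       sr: int = DEFAULT_SR,
                       exemplar_jitter: float = 0.1) -> CategoryBank:
    """Build a bank of parameter-distinct categories with jittered exemplars.

    Exemplar 0 of each category is its unperturbed prototype. Later
    exemplars perturb the prototype: multiplicatively in log center
    frequency and bandwidth, additively in AM rate (clipped to [0, 64] Hz).
    """
    if n_categories < 2:
        raise ValueError("need at least two categories")
    rng = np.random.default_rng(seed)
    specs = _prototype_specs(n_categories, exemplar_jitter)
    exemplars = {}
    for spec in specs:
        for ex in range(n_exemplars):
            if ex == 0 or exemplar_jitter == 0:
                ex_spec = spec
            else:
                z = rng.standard_normal(3)
                cf = float(np.clip(spec.center_freq * np.exp(exemplar_jitter * z[0]),
                                   80.0, 12000.0))
                bw = float(spec.bandwidth * np.exp(exemplar_jitter * z[1]))
                am = float(np.clip(spec.am_rate + 4.0 * exemplar_jitter * z[2],
                                   0.0, 64.0)) if spec.am_rate > 0 else 0.0
                ex_spec = replace(spec, center_freq=cf, bandwidth=bw, am_rate=am)
            wave_seed = int(rng.integers(2**31))
            exemplars[(spec.category_id, ex)] = synth_exemplar(
                ex_spec, duration=duration, sr=sr, seed=wave_seed)
    return CategoryBank(specs=specs, exemplars=exemplars,
                        n_exemplars=n_exemplars, sr=sr, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic voxel responses
# ---------------------------------------------------------------------------


@dataclass
class SyntheticVoxelSet:
    """Voxel responses generated as noisy linear readouts of model features."""

    responses: np.ndarray  # (sounds, voxels, scans)
    true_weights: np.ndarray  # (features, voxels)
    noise_sd: float
    feature_ref: str = ""

    @property
    def n_scans(self) -> int:
        return self.responses.shape[2]

    def scan_average(self) -> np.ndarray:
        """Responses averaged over scans: (sounds, voxels)."""
        return self.responses.mean(axis=2)

    def save(self, out_dir) -> None:
        """Write one delimited matrix per scan plus a JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k in range(self.n_scans):
            np.savetxt(out / f"scan_{k}.csv", self.responses[:, :, k],
                       delimiter=",")
        (out / "meta.json").write_text(json.dumps({
            "noise_sd": self.noise_sd, "feature_ref": self.feature_ref,
            "n_scans": self.n_scans,
        }))

    @classmethod
    def load(cls, in_dir) -> "SyntheticVoxelSet":
        path = Path(in_dir)
        meta = json.loads((path / "meta.json").read_text())
        scans = [np.loadtxt(path / f"scan_{k}.csv", delimiter=",", ndmin=2)
                 for k in range(meta["n_scans"])]
        return cls(responses=np.stack(scans, axis=2),
                   true_weights=np.zeros((0, scans[0].shape[1])),
                   noise_sd=meta["noise_sd"], feature_ref=meta["feature_ref"])


def synth_voxel_dataset(features: np.ndarray, n_voxels: int,
                        noise_sd: float, n_scans: int = 3, seed: int = 0,
                        feature_ref: str = "") -> SyntheticVoxelSet:
    """Generate voxel responses as ``features @ true_weights`` plus scan noise.

    ``true_weights`` is drawn once (standard normal, seed-fixed); each scan
    adds independent Gaussian noise of scale ``noise_sd``. With
    ``noise_sd = 0`` every scan is identical.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("features must be a (sounds >= 2, features) matrix")
    if n_scans < 2:
        raise ValueError("need at least two scans for reliability estimation")
    rng = np.random.default_rng(seed)
    weights = rng.standard_normal((features.shape[1], n_voxels))
    signal = features @ weights
    noise = noise_sd * rng.standard_normal((features.shape[0], n_voxels, n_scans))
    responses = signal[:, :, None] + noise
    return SyntheticVoxelSet(responses=responses, true_weights=weights,
                             noise_sd=noise_sd, feature_ref=feature_ref)
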