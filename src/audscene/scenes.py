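"""Multi-source auditory scene synthesis.

Scenes mix 1-5 single-source excerpts, each truncated/padded to 1 s,
windowed, RMS-equalized, and onset-jittered uniformly within [0, 1] s, so
mixtures last up to 2 s. Two modes are supported:

* ``experiment`` — the psychophysics stimulus recipe: plain summation, final
  RMS normalized to 0.01.
* ``training`` — the recognition-training recipe: each source is attenuated
  by 1/distance (distance uniform in [1.4, 29] m), convolved with a
  synthesized room impulse response, assigned a direction from a 504-point
  azimuth x elevation grid, and the mixture padded to 2.5 s. Output is
  monaural; the direction is bookkeeping for the scene manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .distortions import synth_reverb_ir
from .signal import Waveform, apply_onset_offset_window, normalize_rms, rms

__all__ = [
    "Direction",
    "SourcePlacement",
    "Scene",
    "SceneDataset",
    "excerpt_and_window",
    "direction_grid",
    "make_scene",
    "build_dataset",
]

SOURCE_DUR_S = 1.0
MAX_SCENE_SIZE = 5
SCENE_RMS = 0.01
TRAINING_DUR_S = 2.5
DISTANCE_RANGE_M = (1.4, 29.0)
AZIMUTHS_DEG = tuple(range(0, 360, 5))  # 72 values
ELEVATIONS_DEG = tuple(range(0, 61, 10))  # 7 values

# Default nominal room used to synthesize training-mode impulse responses.
TRAINING_RT60_MS = 400.0
TRAINING_DRR_DB = 20.0


@dataclass(frozen=True)
class Direction:
    azimuth: float  # degrees, 0-355 in 5 deg steps
    elevation: float  # degrees, 0-60 in 10 deg steps

    def __post_init__(self):
        if self.azimuth not in AZIMUTHS_DEG:
            raise ValueError(f"azimuth {self.azimuth} not on the 5-degree grid")
        if self.elevation not in ELEVATIONS_DEG:
            raise ValueError(f"elevation {self.elevation} not on the 10-degree grid")


def direction_grid() -> list[Direction]:
    """All 504 = 72 azimuth x 7 elevation source directions."""
    return [Direction(az, el) for az in AZIMUTHS_DEG for el in ELEVATIONS_DEG]


@dataclass(frozen=True)
class SourcePlacement:
    category_id: int
    exemplar_id: int
    onset_s: float
    direction: Direction | None = None
    distance_m: float | None = None


@dataclass(frozen=True)
class Scene:
    mixture: Waveform
    sources: tuple  # of SourcePlacement
    mode: str  # 'experiment' | 'training'
    rms_target: float = SCENE_RMS

    @property
    def scene_size(self) -> int:
        return len(self.sources)


def excerpt_and_window(wave: Waveform) -> Waveform:
    """First-second excerpt with 10 ms half-Hanning onset/offset windows.

    Sounds longer than 1 s are truncated (preserving the onset); shorter
    sounds are zero-padded to 1 s after windowing, so the window sits on
    the audible portion.
    """
    n_target = int(round(SOURCE_DUR_S * wave.sr))
    samples = wave.samples[:n_target]
    windowed = apply_onset_offset_window(wave.with_samples(samples))
    out = windowed.samples
    if out.size < n_target:
        out = np.pad(out, (0, n_target - out.size))
    return wave.with_samples(out)


def _place(samples: np.ndarray, onset_idx: int, total: int) -> np.ndarray:
    out = np.zeros(total)
    end = min(onset_idx + samples.size, total)
    out[onset_idx:end] = samples[: end - onset_idx]
    return out


def make_scene(bank, categories, seed: int, mode: str = "experiment",
               jitter_range: tuple = (0.0, 1.0)) -> Scene:
    """Mix one scene from the given bank categories.

    ``bank`` is a :class:`~audscene.synthetic_data.CategoryBank` (or any
    object with ``get_exemplar(category_id, exemplar_id)`` and
    ``n_exemplars``). ``categories`` lists 1-5 distinct category ids; an
    exemplar is drawn at random for each. Onsets are jittered uniformly in
    ``jitter_range`` (default [0, 1] s) at sample resolution.
    """
    categories = list(categories)
    if not 1 <= len(categories) <= MAX_SCENE_SIZE:
        raise ValueError(f"scene size must be 1-{MAX_SCENE_SIZE}")
    if len(set(categories)) != len(categories):
        raise ValueError("scene categories must be distinct")
    if mode not in ("experiment", "training"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    sr = bank.sr
    total = int(round((TRAINING_DUR_S if mode == "training" else 2 * SOURCE_DUR_S) * sr))

    directions = direction_grid() if mode == "training" else None
    mix = np.zeros(total)
    placements = []
    for cat in categories:
        ex = int(rng.integers(bank.n_exemplars))
        src = excerpt_and_window(bank.get_exemplar(cat, ex))
        src = normalize_rms(src, SCENE_RMS)
        onset = float(rng.uniform(*jitter_range))
        direction = distance = None
        samples = src.samples
        if mode == "training":
            direction = directions[int(rng.integers(len(directions)))]
            distance = float(rng.uniform(*DISTANCE_RANGE_M))
            samples = samples / distance
            ir = synth_reverb_ir(TRAINING_RT60_MS, TRAINING_DRR_DB, sr,
                                 seed=int(rng.integers(2**31)))
            ir_norm = ir.samples / np.sqrt(np.sum(ir.samples**2))
            samples = fftconvolve(samples, ir_norm)
        mix += _place(samples, int(round(onset * sr)), total)
        placements.append(SourcePlacement(cat, ex, onset, direction, distance))

    mixture = Waveform(mix, sr)
    if mode == "experiment":
        mixture = normalize_rms(mixture, SCENE_RMS)
    return Scene(mixture=mixture, sources=tuple(placements), mode=mode)


@dataclass
class SceneDataset:
    """A collection of scenes with a manifest and multi-hot labels."""

    scenes: list  # of Scene
    labels: np.ndarray  # (n_scenes, n_categories) multi-hot
    category_ids: np.ndarray  # column order of `labels`
    manifest: pd.DataFrame
    seed: int

    def __len__(self) -> int:
        return len(self.scenes)

    def save(self, out_dir) -> None:
        """Write WAV files, a manifest CSV and a labels CSV."""
        from .signal import write_wav

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        wav_dir = out / "wav"
        wav_dir.mkdir(exist_ok=True)
        for i, scene in enumerate(self.scenes):
            write_wav(wav_dir / f"scene_{i:05d}.wav", scene.mixture)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        labels = pd.DataFrame(self.labels, columns=[str(c) for c in self.category_ids])
        labels.insert(0, "scene_id", np.arange(len(self.scenes)))
        labels.to_csv(out / "labels.csv", index=False)
        (out / "meta.json").write_text(json.dumps({"seed": self.seed}))


def build_dataset(bank, n_scenes: int, seed: int,
                  mode: str = "experiment") -> SceneDataset:
    """Sample ``n_scenes`` scenes with sizes uniform on {1..5}.

    Categories are drawn without replacement within each scene. Each scene
    carries a multi-hot label vector over the bank's categories.
    """
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    cat_ids = np.asarray(bank.category_ids)
    if cat_ids.size < MAX_SCENE_SIZE:
        raise ValueError("bank too small for the largest scene size")
    rng = np.random.default_rng(seed)
    scenes, rows, labels = [], [], np.zeros((n_scenes, cat_ids.size), dtype=int)
    col = {c: j for j, c in enumerate(cat_ids)}
    for i in range(n_scenes):
        size = int(rng.integers(1, MAX_SCENE_SIZE + 1))
        cats = list(rng.choice(cat_ids, size=size, replace=False))
        scene = make_scene(bank, cats, seed=int(rng.integers(2**31)), mode=mode)
        scenes.append(scene)
        for s in scene.sources:
            labels[i, col[s.category_id]] = 1
        rows.append({
            "scene_id": i,
            "size": size,
            "categories": ";".join(str(c) for c in cats),
            "exemplars": ";".join(str(s.exemplar_id) for s in scene.sources),
            "onsets_s": ";".join(f"{s.onset_s:.6f}" for s in scene.sources),
            "seed": seed,
        })
    return SceneDataset(scenes=scenes, labels=labels, category_ids=cat_ids,
                        manifest=pd.DataFrame(rows), seed=seed)
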