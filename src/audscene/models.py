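"""Baseline recognition models and the benchmark evaluation harness.

The baselines are multi-label linear readouts: one independent sigmoid
output per sound category on top of a fixed front-end representation
(cochleagram or spectrotemporal modulation features). Training minimizes
summed per-category binary cross-entropy with Adam (lr 1e-4, beta1 0.9,
beta2 0.999, eps 1e-7, batch 32) and early-stops when validation loss has
not improved for 3 validation cycles, a cycle being a pass through a tenth
of the training data.

The evaluation harness is model-agnostic: it consumes per-trial scores
(from :func:`predict` or any external model's score table) and converts
them to per-condition d' via the AUC route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frontend import (MODULATION_FRAME_RATE, cochleagram,
                       make_modulation_filterbank, st_features)
from .psychometrics import auc_dprime
from .signal import Waveform

__all__ = [
    "TrainConfig",
    "ClassifierHead",
    "scene_features",
    "train",
    "predict",
    "make_probe_trials",
    "evaluate_benchmark",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and early-stopping constants for readout training."""

    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7
    batch_size: int = 32
    early_stop_patience: int = 3  # validation cycles without improvement
    cycle_fraction: float = 0.1  # of training data per validation cycle
    val_fraction: float = 0.1  # scenes held out for validation
    max_epochs: int = 200
    init_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "adam_beta1", "adam_beta2", "adam_eps",
                     "batch_size", "early_stop_patience", "cycle_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ClassifierHead:
    """Independent per-category sigmoid readout: scores = sigmoid(XW + b)."""

    weights: np.ndarray  # (features, categories)
    biases: np.ndarray  # (categories,)
    categories: np.ndarray  # label per output column
    history: pd.DataFrame | None = field(default=None, repr=False)

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path, weights=self.weights, biases=self.biases)
        path.with_suffix(".json").write_text(
            json.dumps({"categories": [int(c) for c in self.categories]}))

    @classmethod
    def load(cls, path) -> "ClassifierHead":
        path = Path(path)
        arrays = np.load(path if path.suffix else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(weights=arrays["weights"], biases=arrays["biases"],
                   categories=np.asarray(meta["categories"]))


def _pad_to(wave: Waveform, duration_s: float) -> Waveform:
    n_target = int(round(duration_s * wave.sr))
    deficit = n_target - wave.n_samples
    if deficit <= 0:
        return wave
    return wave.with_samples(np.pad(wave.samples, (deficit // 2, deficit - deficit // 2)))


def scene_features(waves, source: str = "coch_mean",
                   n_channels: int = 211, frame_rate: int = 8000) -> np.ndarray:
    """Front-end feature matrix (n_stimuli x features) for a list of waveforms.

    ``source`` selects the representation:

    * ``'cochleagram'`` — flattened cochleagram (channels x frames);
    * ``'coch_mean'`` — time-averaged cochleagram (one value per channel),
      the compact default for linear readouts;
    * ``'st_features'`` — flattened time-averaged modulation power
      (filters x channels) from the 200 Hz pathway.

    Stimuli shorter than the front end's native 2.5 s are symmetrically
    zero-padded. All waveforms must be at 48 kHz.
    """
    rows = []
    fb = make_modulation_filterbank(n_channels=n_channels) \
        if source == "st_features" else None
    for wave in waves:
        wave = _pad_to(wave, 2.5)
        if source in ("cochleagram", "coch_mean"):
            coch = cochleagram(wave, frame_rate=frame_rate, n_channels=n_channels)
            rows.append(coch.values.mean(axis=1) if source == "coch_mean"
                        else coch.values.ravel())
        elif source == "st_features":
            coch = cochleagram(wave, frame_rate=MODULATION_FRAME_RATE,
                               n_channels=n_channels)
            rows.append(st_features(coch, fb).flat)
        else:
            raise ValueError(f"unknown feature source {source!r}")
    return np.asarray(rows)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    """Binary cross-entropy, averaged over samples and summed over categories."""
    eps = 1e-12
    per_cat = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean(axis=0)
    return float(per_cat.sum())


def train(features: np.ndarray, labels: np.ndarray, categories=None,
          cfg: TrainConfig = TrainConfig()) -> ClassifierHead:
    """Train the per-category sigmoid readout with Adam + early stopping.

    ``features`` is (n_scenes, d); ``labels`` is the multi-hot
    (n_scenes, n_categories) matrix. A seeded ``val_fraction`` of scenes is
    held out; validation loss is evaluated once per cycle (a pass through a
    tenth of the training data) and training stops when it has not
    improved for ``early_stop_patience`` consecutive cycles. Deterministic
    for a fixed config seed.
    """
    X = np.asarray(features, dtype=np.float64)
    Y = np.asarray(labels, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature/label misalignment")
    n, d = X.shape
    n_cat = Y.shape[1]
    if categories is None:
        categories = np.arange(n_cat)

    rng = np.random.default_rng(cfg.seed)
    n_val = max(int(round(cfg.val_fraction * n)), 1) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, Yt = X[train_idx], Y[train_idx]
    Xv, Yv = X[val_idx], Y[val_idx]

    W = cfg.init_sd * rng.standard_normal((d, n_cat))
    b = np.zeros(n_cat)
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    step = 0

    cycle_len = max(int(round(cfg.cycle_fraction * Xt.shape[0])), cfg.batch_size)
    since_cycle = 0
    best_val = np.inf
    bad_cycles = 0
    history = []
    stop = False

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(Xt.shape[0])
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            Xb, Yb = Xt[batch], Yt[batch]
            P = _sigmoid(Xb @ W + b)
            G = (P - Yb) / Xb.shape[0]
            gW = Xb.T @ G
            gb = G.sum(axis=0)
            step += 1
            for g, m, v, param in ((gW, mW, vW, W), (gb, mb, vb, b)):
                m *= cfg.adam_beta1; m += (1 - cfg.adam_beta1) * g
                v *= cfg.adam_beta2; v += (1 - cfg.adam_beta2) * g * g
                mhat = m / (1 - cfg.adam_beta1**step)
                vhat = v / (1 - cfg.adam_beta2**step)
                param -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)

            since_cycle += batch.size
            if since_cycle >= cycle_len:
                since_cycle = 0
                val_loss = (_bce(_sigmoid(Xv @ W + b), Yv) if n_val
                            else _bce(_sigmoid(Xt @ W + b), Yt))
                history.append({"epoch": epoch, "step": step,
                                "val_loss": val_loss})
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    bad_cycles = 0
                else:
                    bad_cycles += 1
                    if bad_cycles >= cfg.early_stop_patience:
                        stop = True
                        break
        if stop:
            break

    return ClassifierHead(weights=W, biases=b,
                          categories=np.asarray(categories),
                          history=pd.DataFrame(history))


def predict(head: ClassifierHead, features: np.ndarray) -> np.ndarray:
    """Per-category scores in (0, 1): sigmoid(features @ W + b)."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != head.weights.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != head dimension "
            f"{head.weights.shape[0]}")
    return _sigmoid(X @ head.weights + head.biases)


def make_probe_trials(dataset, seed: int = 0) -> pd.DataFrame:
    """Balanced probe trials for a :class:`~audscene.scenes.SceneDataset`.

    For each scene, one present category (drawn from its sources) and one
    absent category are probed, yielding a trial table with columns
    ``stimulus_index``, ``probe_category``, ``target_present`` and
    ``scene_size``.
    """
    rng = np.random.default_rng(seed)
    cat_ids = np.asarray(dataset.category_ids)
    rows = []
    for i, scene in enumerate(dataset.scenes):
        present_cats = [s.category_id for s in scene.sources]
        absent_cats = [c for c in cat_ids if c not in present_cats]
        rows.append({"stimulus_index": i,
                     "probe_category": int(rng.choice(present_cats)),
                     "target_present": True,
                     "scene_size": scene.scene_size})
        rows.append({"stimulus_index": i,
                     "probe_category": int(rng.choice(absent_cats)),
                     "target_present": False,
                     "scene_size": scene.scene_size})
    return pd.DataFrame(rows)


def evaluate_benchmark(scores: np.ndarray, trials: pd.DataFrame,
                       grouping: str, categories=None) -> pd.DataFrame:
    """Per-condition d' table from per-stimulus category scores.

    ``scores`` is (n_stimuli, n_categories) — typically
    ``predict(head, features)``. ``trials`` must contain
    ``stimulus_index``, ``probe_category``, ``target_present`` and the
    ``grouping`` column ('scene_size', 'probe_category', or
    'distortion_index'). Within each condition group, the probed-category
    scores are split by target presence and d' is computed from the AUC.
    """
    scores = np.atleast_2d(scores)
    if categories is None:
        categories = np.arange(scores.shape[1])
    col = {c: j for j, c in enumerate(categories)}
    trials = trials.copy()
    trials["score"] = [
        scores[int(row.stimulus_index), col[row.probe_category]]
        for row in trials.itertuples()
    ]
    out = []
    for cond, group in trials.groupby(grouping):
        s = group["score"].to_numpy()
        present = group["target_present"].to_numpy(bool)
        if present.all() or not present.any():
            raise ValueError(f"condition {cond!r} lacks present or absent trials")
        out.append({"condition": cond,
                    "dprime": auc_dprime(s[present], s[~present]),
                    "n_trials": len(group)})
    return pd.DataFrame(out)
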