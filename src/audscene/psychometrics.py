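"""Signal-detection and reliability statistics.

Sensitivity is quantified as d' = Phi^-1(hit rate) - Phi^-1(false-alarm
rate). For models that emit graded scores rather than binary responses,
d' is derived criterion-free from the AUC via the equal-variance Gaussian
identity d' = sqrt(2) * Phi^-1(AUC). Reliability machinery (split-half
correlation, Spearman-Brown correction, noise ceilings, an exact
permutation test over subsets of correlations, bootstrap RMSE, and
sample-size extrapolation) supports comparing human and model performance
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "DetectionCounts",
    "dprime",
    "auc",
    "auc_dprime",
    "split_half_reliability",
    "spearman_brown",
    "noise_ceiling",
    "exact_permutation_test",
    "rmse_bootstrap",
    "sample_size_extrapolation",
]


@dataclass(frozen=True)
class DetectionCounts:
    """Yes/no detection outcome counts."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self):
        if min(self.hits, self.misses, self.false_alarms,
               self.correct_rejections) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_present(self) -> int:
        return self.hits + self.misses

    @property
    def n_absent(self) -> int:
        return self.false_alarms + self.correct_rejections


def _edge_corrected_rate(count: int, n: int) -> float:
    """Rate with 1/(2N) correction for 0 and 1 to keep Phi^-1 finite."""
    if n < 1:
        raise ValueError("need at least one trial")
    rate = count / n
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime(counts: DetectionCounts) -> float:
    """d' from hit/false-alarm counts with 1/(2N) edge correction."""
    h = _edge_corrected_rate(counts.hits, counts.n_present)
    fa = _edge_corrected_rate(counts.false_alarms, counts.n_absent)
    return float(stats.norm.ppf(h) - stats.norm.ppf(fa))


def auc(scores_present, scores_absent) -> float:
    """Rank-statistic AUC with ties counted one half."""
    pos = np.asarray(scores_present, dtype=np.float64)
    neg = np.asarray(scores_absent, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def auc_dprime(scores_present, scores_absent) -> float:
    """Criterion-free d' from graded scores.

    AUC is computed from the empirical score distributions, clamped to
    [1/(2n), 1 - 1/(2n)] (n = total score count) so perfect separation
    maps to a finite value, and converted via d' = sqrt(2) * Phi^-1(AUC)
    (equal-variance Gaussian identity).
    """
    a = auc(scores_present, scores_absent)
    n = len(scores_present) + len(scores_absent)
    a = float(np.clip(a, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    return float(np.sqrt(2.0) * stats.norm.ppf(a))


def _correlate(x, y, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation {method!r}")


def split_half_reliability(values_by_unit: np.ndarray,
                           split_rule: str = "odd_even",
                           correlation: str = "spearman",
                           seed: int | None = None) -> float:
    """Correlation of condition-wise aggregates across two halves of units.

    ``values_by_unit`` is (units x conditions) — units are participants or
    trials. Units are split by ``split_rule`` ('odd_even' by run order, or
    'random' with ``seed``), each half is averaged per condition, and the
    two aggregate vectors are correlated across conditions. The result is
    the reliability of a *half* sample; apply :func:`spearman_brown` with
    factor 2 to estimate full-sample reliability.
    """
    values = np.asarray(values_by_unit, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 4:
        raise ValueError("need a (units >= 4, conditions) matrix")
    idx = np.arange(values.shape[0])
    if split_rule == "random":
        idx = np.random.default_rng(seed).permutation(idx)
    elif split_rule != "odd_even":
        raise ValueError(f"unknown split rule {split_rule!r}")
    half_a = values[idx[0::2]].mean(axis=0)
    half_b = values[idx[1::2]].mean(axis=0)
    return _correlate(half_a, half_b, correlation)


def spearman_brown(r: float, factor: float = 2.0) -> float:
    """Spearman-Brown prophecy: reliability after lengthening by ``factor``."""
    if not -1.0 < r <= 1.0:
        raise ValueError("r must lie in (-1, 1]")
    if factor <= 0:
        raise ValueError("factor must be positive")
    return factor * r / (1.0 + (factor - 1.0) * r)


def noise_ceiling(rel_a: float, rel_b: float) -> float:
    """Maximum attainable correlation: geometric mean of two reliabilities."""
    if rel_a < 0 or rel_b < 0:
        raise ValueError("reliabilities must be nonnegative")
    return float(np.sqrt(rel_a * rel_b))


def exact_permutation_test(values, designated,
                           statistic: str = "mean_difference") -> float:
    """Exact one-sided permutation test over all subsets of ``values``.

    ``designated`` indexes the observed subset (e.g., the four correlations
    involving single-source scenes among the ten scene-size pairs). For
    every same-size subset S, the statistic T(S) = mean(values outside S) -
    mean(values in S) is computed; the p-value is the fraction of subsets
    with T at least as large as the designated subset's. With
    ``statistic='indicator'`` the test instead counts subsets whose maximum
    is <= the designated subset's maximum (the "all lowest" event).
    """
    values = np.asarray(values, dtype=np.float64)
    designated = sorted(designated)
    k = len(designated)
    if not 0 < k < values.size:
        raise ValueError("designated subset must be a proper nonempty subset")
    total = values.sum()

    def t(subset) -> float:
        inside = values[list(subset)].sum()
        return (total - inside) / (values.size - k) - inside / k

    if statistic == "mean_difference":
        t_obs = t(designated)
        count = sum(t(s) >= t_obs - 1e-12
                    for s in combinations(range(values.size), k))
    elif statistic == "indicator":
        m_obs = values[designated].max()
        count = sum(values[list(s)].max() <= m_obs + 1e-12
                    for s in combinations(range(values.size), k))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    from math import comb

    return count / comb(values.size, k)


def rmse_bootstrap(human, model, n_boot: int = 1000,
                   seed: int = 0, ci: float = 0.95):
    """RMSE between two condition-wise vectors with a percentile bootstrap CI.

    Conditions are resampled with replacement ``n_boot`` times; the CI is
    the central ``ci`` interval of the resampled RMSEs.
    """
    human = np.asarray(human, dtype=np.float64)
    model = np.asarray(model, dtype=np.float64)
    if human.shape != model.shape:
        raise ValueError("vectors must have equal length")
    err = human - model
    rmse = float(np.sqrt(np.mean(err**2)))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, err.size, size=(n_boot, err.size))
    boot = np.sqrt(np.mean(err[idx] ** 2, axis=1))
    lo, hi = np.quantile(boot, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return rmse, (float(lo), float(hi))


def sample_size_extrapolation(pilot: np.ndarray, criterion: float,
                              n_grid, n_resamples: int = 100,
                              percentile: float = 20.0, seed: int = 0,
                              correlation: str = "spearman") -> int:
    """Project the sample size needed to reach a reliability criterion.

    For each subsample size in ``n_grid``, participants are resampled
    ``n_resamples`` times from the (participants x conditions) pilot
    matrix; split-half reliability (Spearman-Brown corrected to the full
    subsample) is computed per resample and summarized at ``percentile``
    (the pessimistic 20th by default, so the criterion is met most of the
    time). A Spearman-Brown-form curve r(n) = n r1 / (1 + (n-1) r1) is fit
    to these points and solved for ``criterion``.
    """
    pilot = np.asarray(pilot, dtype=np.float64)
    n_grid = sorted(int(n) for n in n_grid)
    if len(n_grid) < 2:
        raise ValueError("grid must span at least 2 sizes")
    if not 0 < criterion < 1:
        raise ValueError("criterion must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    points = []
    for n in n_grid:
        if n > pilot.shape[0] or n < 4:
            raise ValueError(f"subsample size {n} infeasible for pilot data")
        rels = []
        for _ in range(n_resamples):
            rows = rng.choice(pilot.shape[0], size=n, replace=False)
            r = split_half_reliability(pilot[rows], split_rule="random",
                                       correlation=correlation,
                                       seed=int(rng.integers(2**31)))
            rels.append(spearman_brown(max(r, -0.99), 2.0))
        points.append((n, float(np.percentile(rels, percentile))))

    # Fit r1 (the implied single-unit reliability) by least squares on the
    # Spearman-Brown curve, searching a fine log-spaced grid.
    ns = np.array([p[0] for p in points], dtype=np.float64)
    rs = np.array([p[1] for p in points], dtype=np.float64)
    r1_grid = 1.0 / (1.0 + np.geomspace(1e-2, 1e4, 2000))
    curves = ns[None, :] * r1_grid[:, None] / (1 + (ns[None, :] - 1) * r1_grid[:, None])
    r1 = float(r1_grid[np.argmin(((curves - rs[None, :]) ** 2).sum(axis=1))])

    if rs[0] >= criterion:
        return n_grid[0]
    n_star = criterion * (1 - r1) / (r1 * (1 - criterion))
    if n_star <= 0 or not np.isfinite(n_star):
        raise ValueError("criterion unreachable within the fitted curve")
    return max(n_grid[0], int(np.ceil(n_star)))
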