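"""Voxelwise encoding models and representational similarity analysis.

Each voxel's time-averaged response to a sound set is modeled as a ridge
(L2-regularized) linear combination of a model stage's time-averaged unit
activations:

    w = (X'X + n * lambda * I)^-1 X'y

with X and y demeaned using training-set statistics only, and columns of X
deliberately *not* norm-scaled (a non-isotropic prior: large-norm units are
expected a priori to contribute more). The regularization parameter is
selected per voxel by leave-one-out cross-validation over the training
sounds on a grid of 100 powers of ten (1e-50 ... 1e49).

Prediction quality on held-out sounds (Pearson r, zeroed when negative or
when the prediction is constant) is corrected for attenuation by the
measurement reliabilities of both the voxel response and the prediction:

    r2* = r^2 / (max(rel_v, k_v) * max(rel_vhat, k_vhat))

where each reliability is the Spearman-Brown-corrected median pairwise
scan correlation, and the floors k are the one-tailed p < .05 critical
Pearson correlations for the train/test sample sizes (0.182 and 0.183 for
83 and 82 sounds). Corrected values above 1 are clipped to 1.

Model-level aggregation selects each voxel's best-predicting stage on half
of the cross-validation splits and scores it on the other half; RSA
compares model and voxel representational dissimilarity matrices with the
same train/test split discipline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .psychometrics import spearman_brown

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "ridge_fit",
    "loo_errors",
    "loo_select_lambda",
    "reliability_from_scans",
    "corrected_r2",
    "critical_r",
    "EncodingResult",
    "encode_voxels",
    "aggregate_best_stage",
    "rdm",
    "rsa_score",
]

# 100 logarithmically spaced regularization values: 1e-50, 1e-49, ..., 1e49.
DEFAULT_LAMBDA_GRID = tuple(10.0**k for k in range(-50, 50))
K_VOXEL = 0.182  # critical r for n = 83 training sounds
K_PRED = 0.183  # critical r for n = 82 test sounds


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge solution w = (X'X + n*lam*I)^-1 X'y (inputs pre-demeaned).

    ``y`` may be a vector or an (n, k) matrix of targets sharing ``X``.
    The regularizer scales with the number of training stimuli n, making
    lambda comparable across training-set sizes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n, d = X.shape
    A = X.T @ X + n * lam * np.eye(d)
    try:
        return np.linalg.solve(A, X.T @ y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular ridge system (lam={lam}, n={n}, d={d})") from err


def _svd(X: np.ndarray):
    return np.linalg.svd(np.asarray(X, dtype=np.float64), full_matrices=False)


def loo_errors(X: np.ndarray, Y: np.ndarray, lam: float,
               svd=None) -> np.ndarray:
    """Mean squared leave-one-out ridge prediction error.

    Uses the hat-matrix identity e_i / (1 - h_ii): exactly the residual of
    refitting with stimulus i held out while keeping the penalty term
    n*lam*I fixed at the full training size (so lambda retains one meaning
    throughout selection). ``Y`` may be (n,) or (n, voxels); returns the
    per-column mean squared LOO error.
    """
    U, s, _ = _svd(X) if svd is None else svd
    Y = np.asarray(Y, dtype=np.float64)
    y2d = Y[:, None] if Y.ndim == 1 else Y
    n = y2d.shape[0]
    f = s**2 / (s**2 + n * lam)
    UtY = U.T @ y2d
    resid = y2d - U @ (f[:, None] * UtY)
    h = np.einsum("ij,j,ij->i", U, f, U)
    loo = resid / np.maximum(1.0 - h, 1e-12)[:, None]
    mse = np.mean(loo**2, axis=0)
    return mse[0] if Y.ndim == 1 else mse


def loo_select_lambda(X: np.ndarray, Y: np.ndarray,
                      grid=DEFAULT_LAMBDA_GRID):
    """Select lambda minimizing mean squared LOO error over ``grid``.

    Returns the winning lambda for a vector target, or an array of winners
    (one per column) for a matrix target.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    svd = _svd(X)
    errs = np.stack([np.atleast_1d(loo_errors(X, Y, lam, svd=svd))
                     for lam in grid])
    winners = np.asarray(grid, dtype=np.float64)[np.argmin(errs, axis=0)]
    return float(winners[0]) if np.ndim(Y) == 1 else winners


def reliability_from_scans(per_scan: np.ndarray) -> float:
    """Spearman-Brown-corrected median pairwise scan correlation.

    ``per_scan`` is (sounds, scans). The median Pearson correlation over
    all scan pairs is corrected by the scan count (factor 3 for 3 scans),
    estimating the reliability of the scan-averaged response.
    """
    per_scan = np.asarray(per_scan, dtype=np.float64)
    n_scans = per_scan.shape[1]
    if n_scans < 2:
        raise ValueError("need at least two scans")
    if np.any(per_scan.std(axis=0) == 0):
        raise ValueError("constant responses: reliability undefined")
    corr = np.corrcoef(per_scan.T)
    pairs = corr[np.triu_indices(n_scans, k=1)]
    return spearman_brown(float(np.median(pairs)), factor=n_scans)


def corrected_r2(r_test: float, rel_voxel: float, rel_pred: float,
                 k_voxel: float = K_VOXEL, k_pred: float = K_PRED) -> float:
    """Attenuation-corrected variance explained, floored and clipped.

    r2* = r_test^2 / (max(rel_voxel, k_voxel) * max(rel_pred, k_pred)),
    clipped to at most 1.
    """
    denom = max(rel_voxel, k_voxel) * max(rel_pred, k_pred)
    return float(min(r_test**2 / denom, 1.0))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest Pearson r reaching one-tailed significance ``alpha``.

    Uses the t transform r*sqrt((n-2)/(1-r^2)) ~ t(n-2) under the
    zero-correlation null. n=83 gives 0.182 and n=82 gives 0.183 at
    alpha=0.05 (the reliability floors above).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    t_crit = stats.t.ppf(1.0 - alpha, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r between matching columns of A and B."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A**2).sum(axis=0))
    sb = np.sqrt((B**2).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=0) / denom
    r[~np.isfinite(r)] = 0.0
    return r


@dataclass
class EncodingResult:
    """Per-voxel, per-stage, per-split encoding outcomes."""

    stages: list
    r_test: np.ndarray  # (stages, voxels, splits)
    r2_uncorrected: np.ndarray
    r2_corrected: np.ndarray
    rel_voxel: np.ndarray  # (voxels, splits)
    rel_pred: np.ndarray  # (stages, voxels, splits)
    lambda_star: np.ndarray  # (stages, voxels, splits)

    def median_r2(self) -> np.ndarray:
        """Median corrected R^2 over splits: (stages, voxels)."""
        return np.median(self.r2_corrected, axis=2)


def _fit_predict_grouped(U, s, Vt, y_train, X_test_c, lams):
    """Ridge predictions for many voxels with per-voxel lambdas (shared SVD)."""
    n = y_train.shape[0]
    preds = np.empty((X_test_c.shape[0], y_train.shape[1]))
    UtY = U.T @ y_train
    XtV = X_test_c @ Vt.T
    for lam in np.unique(lams):
        cols = np.nonzero(lams == lam)[0]
        factor = s / (s**2 + n * lam)
        preds[:, cols] = XtV @ (factor[:, None] * UtY[:, cols])
    return preds


def encode_voxels(stage_features: dict, voxel_responses: np.ndarray,
                  n_splits: int = 10, seed: int = 0,
                  grid=DEFAULT_LAMBDA_GRID,
                  k_voxel: float | None = None,
                  k_pred: float | None = None) -> EncodingResult:
    """Cross-validated, noise-corrected encoding analysis.

    Parameters
    ----------
    stage_features
        Mapping stage name -> (sounds, units) time-averaged activations.
    voxel_responses
        (sounds, voxels, scans) response array (e.g. from
        :class:`~audscene.synthetic_data.SyntheticVoxelSet`).
    n_splits
        Random train/test splits of the sounds; each uses ceil(n/2)
        training sounds (83 of 165) and the rest for testing.
    k_voxel, k_pred
        Reliability floors. Default: the one-tailed p < .05 critical r for
        the realized train/test sizes (0.182/0.183 at 83/82).

    Per split and stage: demean on train, select lambda per voxel by LOO,
    fit on the scan-averaged train responses, predict the test sounds, and
    correct the squared test correlation by the voxel and prediction
    reliabilities (prediction reliability from models fit on single-scan
    responses).
    """
    responses = np.asarray(voxel_responses, dtype=np.float64)
    if responses.ndim != 3:
        raise ValueError("voxel_responses must be (sounds, voxels, scans)")
    n_sounds, n_voxels, n_scans = responses.shape
    if n_sounds < 3:
        raise ValueError("need at least three sounds")
    stages = list(stage_features)
    n_train = int(np.ceil(n_sounds / 2))
    kv = critical_r(n_train) if k_voxel is None else k_voxel
    kp = critical_r(n_sounds - n_train) if k_pred is None else k_pred

    rng = np.random.default_rng(seed)
    shape = (len(stages), n_voxels, n_splits)
    r_test = np.zeros(shape)
    r2_unc = np.zeros(shape)
    r2_cor = np.zeros(shape)
    rel_pred_all = np.zeros(shape)
    lam_star = np.zeros(shape)
    rel_voxel_all = np.zeros((n_voxels, n_splits))

    mean_resp = responses.mean(axis=2)
    for split in range(n_splits):
        order = rng.permutation(n_sounds)
        tr, te = order[:n_train], order[n_train:]
        y_tr = mean_resp[tr]
        y_te = mean_resp[te]
        y_tr_c = y_tr - y_tr.mean(axis=0)

        for v in range(n_voxels):
            rel_voxel_all[v, split] = reliability_from_scans(responses[te, v, :])

        for si, stage in enumerate(stages):
            X = np.asarray(stage_features[stage], dtype=np.float64)
            X_tr = X[tr]
            mu = X_tr.mean(axis=0)
            X_tr_c = X_tr - mu
            X_te_c = X[te] - mu
            U, s, Vt = _svd(X_tr_c)
            svd = (U, s, Vt)
            errs = np.stack([loo_errors(X_tr_c, y_tr_c, lam, svd=svd)
                             for lam in grid])
            lams = np.asarray(grid)[np.argmin(errs, axis=0)]
            lam_star[si, :, split] = lams

            preds = _fit_predict_grouped(U, s, Vt, y_tr_c, X_te_c, lams)
            r = _pearson_rows(preds, y_te)
            r = np.maximum(r, 0.0)
            r_test[si, :, split] = r
            r2_unc[si, :, split] = r**2

            # Reliability of the prediction: one model per scan, fit on that
            # scan's training responses with the selected lambda.
            scan_preds = np.empty((te.size, n_voxels, n_scans))
            for scan in range(n_scans):
                y_scan = responses[tr, :, scan]
                y_scan_c = y_scan - y_scan.mean(axis=0)
                scan_preds[:, :, scan] = _fit_predict_grouped(
                    U, s, Vt, y_scan_c, X_te_c, lams)
            for v in range(n_voxels):
                sp = scan_preds[:, v, :]
                if np.any(sp.std(axis=0) == 0):
                    rel_pred_all[si, v, split] = 0.0
                else:
                    rel_pred_all[si, v, split] = reliability_from_scans(sp)
                r2_cor[si, v, split] = corrected_r2(
                    r_test[si, v, split], rel_voxel_all[v, split],
                    rel_pred_all[si, v, split], kv, kp)

    return EncodingResult(stages=stages, r_test=r_test,
                          r2_uncorrected=r2_unc, r2_corrected=r2_cor,
                          rel_voxel=rel_voxel_all, rel_pred=rel_pred_all,
                          lambda_star=lam_star)


def aggregate_best_stage(per_split_scores, n_repeats: int = 10,
                         seed: int = 0) -> float:
    """Model score via held-out best-stage selection.

    ``per_split_scores`` is a (voxels, stages, splits) array, or a list of
    such arrays (one per participant). Per voxel and repeat, a random half
    of the splits selects the best stage (highest median score) and the
    remaining half scores it (median); repeats are averaged. The voxel
    scores are medianed within participant and averaged across
    participants.
    """
    arrays = per_split_scores if isinstance(per_split_scores, (list, tuple)) \
        else [per_split_scores]
    rng = np.random.default_rng(seed)
    participant_scores = []
    for arr in arrays:
        arr = np.asarray(arr, dtype=np.float64)
        n_vox, n_stages, n_splits = arr.shape
        if n_splits < 2:
            raise ValueError("need at least two splits")
        half = n_splits // 2
        voxel_scores = np.zeros(n_vox)
        for _ in range(n_repeats):
            sel = rng.permutation(n_splits)
            pick, hold = sel[:half], sel[half:]
            best = np.argmax(np.median(arr[:, :, pick], axis=2), axis=1)
            voxel_scores += np.median(
                arr[np.arange(n_vox), best][:, hold], axis=1)
        participant_scores.append(np.median(voxel_scores / n_repeats))
    return float(np.mean(participant_scores))


def rdm(responses: np.ndarray, metric: str = "correlation") -> np.ndarray:
    """Representational dissimilarity matrix over sounds.

    ``responses`` is (sounds, units); dissimilarity is 1 - Pearson r
    between the unit-response patterns of each sound pair ('euclidean'
    gives pairwise Euclidean distance instead).
    """
    responses = np.asarray(responses, dtype=np.float64)
    if metric == "correlation":
        if np.any(responses.std(axis=1) == 0):
            raise ValueError("constant response pattern: RDM undefined")
        return 1.0 - np.corrcoef(responses)
    if metric == "euclidean":
        diff = responses[:, None, :] - responses[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    raise ValueError(f"unknown metric {metric!r}")


def _rdm_spearman(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate RDM (all-equal dissimilarities)")
    return float(stats.spearmanr(x, y).statistic)


def rsa_score(stage_features: dict, voxel_responses, n_splits: int = 10,
              seed: int = 0, metric: str = "correlation") -> float:
    """Representational similarity between model stages and voxel data.

    ``voxel_responses`` is a (sounds, voxels) matrix or a list of such
    matrices (one per participant). Per split: RDMs on the training sounds
    choose the stage with the highest Spearman rho against the
    participant's RDM; the test-sound RDMs of that stage provide the test
    rho. The median over splits is taken per participant and the mean over
    participants returned.
    """
    mats = voxel_responses if isinstance(voxel_responses, (list, tuple)) \
        else [voxel_responses]
    stages = list(stage_features)
    n_sounds = np.asarray(mats[0]).shape[0]
    n_train = int(np.ceil(n_sounds / 2))
    rng = np.random.default_rng(seed)
    per_participant = []
    for resp in mats:
        resp = np.asarray(resp, dtype=np.float64)
        rhos = []
        for _ in range(n_splits):
            order = rng.permutation(n_sounds)
            tr, te = order[:n_train], order[n_train:]
            brain_tr = rdm(resp[tr], metric)
            scores = [_rdm_spearman(rdm(np.asarray(stage_features[s])[tr], metric),
                                    brain_tr) for s in stages]
            best = stages[int(np.argmax(scores))]
            rhos.append(_rdm_spearman(
                rdm(np.asarray(stage_features[best])[te], metric),
                rdm(resp[te], metric)))
        per_participant.append(np.median(rhos))
    return float(np.mean(per_participant))
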