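"""Ridge encoding, noise-ceiling correction, aggregation, and RSA."""

import numpy as np
import pytest
from scipy import stats

from audscene import brain_alignment as ba
from audscene.synthetic_data import synth_voxel_dataset


class TestRidgeFit:
    def test_identity_design_unregularized_returns_target(self, rng):
        y = rng.normal(size=6)
        w = ba.ridge_fit(np.eye(6), y, lam=0.0)
        assert np.allclose(w, y)

    def test_heavy_regularization_shrinks_to_zero(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        w = ba.ridge_fit(X, y, lam=1e12)
        assert np.linalg.norm(w) < 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        lam = 0.1
        w = ba.ridge_fit(X, y, lam)
        oracle = np.linalg.inv(X.T @ X + 10 * lam * np.eye(5)) @ X.T @ y
        assert np.allclose(w, oracle, atol=1e-8)

    def test_lam_zero_equals_ols_on_overdetermined_problems(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        w = ba.ridge_fit(X, y, 0.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(w, ols, atol=1e-8)


class TestLooSelection:
    def test_default_grid_has_100_log_spaced_values(self):
        grid = np.asarray(ba.DEFAULT_LAMBDA_GRID)
        assert grid.size == 100
        assert grid[0] == pytest.approx(1e-50)
        assert grid[-1] == pytest.approx(1e49)
        assert np.allclose(np.diff(np.log10(grid)), 1.0)

    def test_noiseless_overdetermined_prefers_minimal_lambda(self, rng):
        X = rng.normal(size=(40, 5))
        w = rng.normal(size=5)
        y = X @ w
        Xc, yc = X - X.mean(0), y - y.mean()
        lam_star = ba.loo_select_lambda(Xc, yc)
        assert lam_star <= 1e-10
        upper = [ba.loo_errors(Xc, yc, lam) for lam in (1e0, 1e3, 1e6)]
        assert upper[0] < upper[1] < upper[2]

    def test_matches_naive_refit_oracle(self, rng):
        n, d, lam = 12, 4, 0.5
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        Xc, yc = X - X.mean(0), y - y.mean()
        fast = ba.loo_errors(Xc, yc, lam)
        errs = []
        for i in range(n):
            keep = np.arange(n) != i
            wi = np.linalg.solve(Xc[keep].T @ Xc[keep] + n * lam * np.eye(d),
                                 Xc[keep].T @ yc[keep])
            errs.append((yc[i] - Xc[i] @ wi) ** 2)
        assert fast == pytest.approx(np.mean(errs), abs=1e-8)


class TestReliability:
    def test_identical_scans_are_perfectly_reliable(self, rng):
        scan = rng.normal(size=30)
        scans = np.tile(scan[:, None], (1, 3))
        assert ba.reliability_from_scans(scans) == pytest.approx(1.0)

    def test_median_pairwise_correlation_is_spearman_brown_corrected(self):
        # Build 3 scans whose sample correlations are exactly (0.4, 0.5, 0.6):
        # median 0.5, corrected 3*0.5 / (1 + 2*0.5) = 0.75.
        target = np.array([[1.0, 0.4, 0.5], [0.4, 1.0, 0.6], [0.5, 0.6, 1.0]])
        gen = np.random.default_rng(0)
        Z = gen.normal(size=(50, 3))
        Z -= Z.mean(0)
        Q, _ = np.linalg.qr(Z)
        scans = Q @ np.linalg.cholesky(target).T
        corr = np.corrcoef(scans.T)
        assert np.allclose(corr, target, atol=1e-10)
        assert ba.reliability_from_scans(scans) == pytest.approx(0.75)

    def test_recovers_analytic_three_scan_reliability(self):
        # Signal variance 1, noise sd 0.8: single-scan-pair correlation
        # rho1 = 1/(1+0.64); three-scan reliability = SB(rho1, 3).
        gen = np.random.default_rng(5)
        rho1 = 1 / 1.64
        expected = 3 * rho1 / (1 + 2 * rho1)
        reps = 400
        vals = []
        for _ in range(reps):
            signal = gen.normal(size=(40, 1))
            scans = signal + 0.8 * gen.normal(size=(40, 3))
            vals.append(ba.reliability_from_scans(scans))
        se = np.std(vals) / np.sqrt(reps)
        assert abs(np.mean(vals) - expected) < 3 * se + 0.01


class TestCorrectedR2:
    def test_arithmetic(self):
        assert ba.corrected_r2(0.6, 0.8, 0.9) == pytest.approx(0.5)

    def test_reliability_floor_applies(self):
        low = ba.corrected_r2(0.1, 0.05, 0.9)
        assert low == pytest.approx(0.01 / (0.182 * 0.9))

    def test_clipped_at_one(self):
        assert ba.corrected_r2(0.95, 0.8, 0.8) == 1.0

    def test_exceeds_uncorrected_when_reliabilities_below_one(self):
        r = 0.5
        assert ba.corrected_r2(r, 0.7, 0.8) > r**2


class TestCriticalR:
    def test_printed_floors(self):
        assert round(ba.critical_r(83), 3) == 0.182
        assert round(ba.critical_r(82), 3) == 0.183

    def test_large_sample_normal_limit(self):
        n = 100_000
        assert ba.critical_r(n) == pytest.approx(1.645 / np.sqrt(n), rel=0.01)

    def test_strictly_decreasing_in_n(self):
        ks = [ba.critical_r(n) for n in (10, 30, 83, 200, 1000)]
        assert all(a > b for a, b in zip(ks, ks[1:]))


@pytest.fixture(scope="module")
def encoding_setup():
    gen = np.random.default_rng(42)
    features = gen.standard_normal((120, 40))
    sig_sd = 1.0
    return features, sig_sd


class TestEncodeVoxels:
    def test_noiseless_recovery_is_exact(self, encoding_setup):
        features, _ = encoding_setup
        vox = synth_voxel_dataset(features, n_voxels=12, noise_sd=0.0,
                                  n_scans=3, seed=1)
        res = ba.encode_voxels({"gen": features}, vox.responses,
                               n_splits=3, seed=2)
        assert np.median(res.r2_corrected) == pytest.approx(1.0, abs=1e-6)

    def test_noise_corrected_r2_recovers_ground_truth(self, encoding_setup):
        features, _ = encoding_setup
        signal_sd = float(np.std(features @ np.random.default_rng(1)
                                 .standard_normal((features.shape[1], 1))))
        vox = synth_voxel_dataset(features, n_voxels=20,
                                  noise_sd=0.8 * signal_sd, n_scans=3, seed=1)
        res = ba.encode_voxels({"gen": features}, vox.responses,
                               n_splits=5, seed=3)
        corrected = res.median_r2().mean()
        uncorrected = np.median(res.r2_uncorrected, axis=2).mean()
        assert corrected == pytest.approx(1.0, abs=0.1)
        assert corrected > uncorrected

    def test_permuted_features_explain_nothing(self, encoding_setup):
        features, _ = encoding_setup
        gen = np.random.default_rng(9)
        vox = synth_voxel_dataset(features, n_voxels=12, noise_sd=0.5,
                                  n_scans=3, seed=1)
        permuted = features[gen.permutation(features.shape[0])]
        res = ba.encode_voxels({"perm": permuted}, vox.responses,
                               n_splits=3, seed=4)
        assert res.median_r2().mean() <= 0.05

    def test_noise_monotonically_degrades_uncorrected_fit(self, encoding_setup):
        features, _ = encoding_setup
        med = []
        for noise in (0.0, 1.0, 4.0):
            vox = synth_voxel_dataset(features, n_voxels=8, noise_sd=noise,
                                      n_scans=3, seed=1)
            res = ba.encode_voxels({"gen": features}, vox.responses,
                                   n_splits=3, seed=5)
            med.append(np.median(res.r2_uncorrected))
        assert med[0] > med[1] > med[2]


class TestAggregateBestStage:
    def test_single_stage_reduces_to_held_out_median(self):
        gen = np.random.default_rng(0)
        scores = gen.uniform(size=(5, 1, 10))
        agg = ba.aggregate_best_stage(scores, n_repeats=1, seed=1)
        sel = np.random.default_rng(1).permutation(10)
        hold = sel[5:]
        expected = np.median(np.median(scores[:, 0, hold], axis=1))
        assert agg == pytest.approx(expected)

    def test_dominant_stage_always_selected(self):
        gen = np.random.default_rng(2)
        weak = gen.uniform(0.0, 0.2, size=(6, 1, 8))
        strong = gen.uniform(0.8, 1.0, size=(6, 1, 8))
        scores = np.concatenate([weak, strong], axis=1)
        agg = ba.aggregate_best_stage(scores, n_repeats=5, seed=3)
        assert agg > 0.75

    def test_split_selection_is_unbiased_for_equal_stages(self):
        # Two statistically identical stages: held-out stage selection
        # should estimate a single stage's score without winner's-curse
        # inflation, unlike a naive max over all-splits medians.
        gen = np.random.default_rng(4)
        reps = 200
        diffs, naive_diffs = [], []
        for _ in range(reps):
            scores = 0.5 + 0.1 * gen.standard_normal((8, 2, 10))
            agg = ba.aggregate_best_stage(scores, n_repeats=4,
                                          seed=int(gen.integers(2**31)))
            truth = np.median(np.median(scores, axis=2).mean(axis=1))
            naive = np.median(np.median(scores, axis=2).max(axis=1))
            diffs.append(agg - truth)
            naive_diffs.append(naive - truth)
        se = np.std(diffs) / np.sqrt(reps)
        assert abs(np.mean(diffs)) < max(2 * se, 0.01)
        assert np.mean(naive_diffs) > 3 * se  # the bias the procedure avoids

    def test_participant_averaging(self):
        a = np.full((4, 1, 4), 0.2)
        b = np.full((4, 1, 4), 0.6)
        assert ba.aggregate_best_stage([a, b], n_repeats=2, seed=0) == \
            pytest.approx(0.4)


class TestRsa:
    def test_identical_representations_give_unit_rho(self, rng):
        feats = rng.normal(size=(40, 12))
        assert ba.rsa_score({"s": feats}, feats, n_splits=3, seed=0) == \
            pytest.approx(1.0)

    def test_unrelated_representations_average_to_chance(self):
        gen = np.random.default_rng(6)
        vals = []
        for _ in range(60):
            feats = gen.normal(size=(60, 10))
            voxels = gen.normal(size=(60, 10))
            vals.append(ba.rsa_score({"s": feats}, voxels, n_splits=2,
                                     seed=int(gen.integers(2**31))))
        assert abs(np.mean(vals)) < 0.05

    def test_matched_noise_attenuates_rho_monotonically(self):
        gen = np.random.default_rng(7)
        feats = gen.normal(size=(50, 15))
        rhos = []
        for noise in (0.0, 1.0, 3.0):
            noisy_a = feats + noise * gen.normal(size=feats.shape)
            noisy_b = feats + noise * gen.normal(size=feats.shape)
            rhos.append(ba.rsa_score({"s": noisy_a}, noisy_b, n_splits=3,
                                     seed=8))
        assert rhos[0] > rhos[1] > rhos[2]

    def test_degenerate_rdm_raises(self):
        const = np.ones((10, 5))
        with pytest.raises(ValueError):
            ba.rsa_score({"s": const}, const, n_splits=2, seed=0)
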