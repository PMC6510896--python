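import dataclasses

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import bloodspec as bs
from bloodspec.exceptions import CVDesignError, ParameterError


def covariance_eigen_oracle(M, k):
    """Brute-force PCA oracle: eigendecomposition of the sample covariance."""
    Mc = M - M.mean(axis=0)
    C = Mc.T @ Mc / (M.shape[0] - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:k]
    return vals[order], vecs[:, order].T


class TestPCA:
    def test_rank_one_data(self):
        base = np.linspace(0, 1, 12)
        M = np.outer([1.0, 2.0, 3.0, 4.0], base)
        model = bs.pca_fit(M, 1)
        assert np.isclose(model.explained_fraction[0], 1.0)

    def test_score_covariance_diagonal(self):
        M = np.random.default_rng(0).normal(size=(15, 9))
        model = bs.pca_fit(M)
        C = np.cov(model.scores, rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 1e-10

    def test_matches_covariance_eigen_oracle(self):
        M = np.random.default_rng(1).normal(size=(10, 8))
        model = bs.pca_fit(M, 5)
        vals, vecs = covariance_eigen_oracle(M, 5)
        assert np.allclose(model.explained_fraction * vals.sum() / vals.sum(),
                           model.explained_fraction)
        total = np.trace(np.cov(M, rowvar=False))
        assert np.allclose(model.explained_fraction, vals / total, atol=1e-8)
        for got, want in zip(model.loadings, vecs):
            assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)

    def test_loadings_orthonormal_and_reconstruction(self):
        M = np.random.default_rng(2).normal(size=(12, 7))
        model = bs.pca_fit(M)
        G = model.loadings @ model.loadings.T
        assert np.allclose(G, np.eye(model.n_pcs), atol=1e-8)
        recon = model.scores @ model.loadings + model.mean_spectrum
        assert np.allclose(recon, M, atol=1e-8)

    def test_reconstruction_error_monotone_in_n_pcs(self):
        M = np.random.default_rng(3).normal(size=(10, 6))
        errs = []
        for k in range(1, 6):
            m = bs.pca_fit(M, k)
            recon = m.scores @ m.loadings + m.mean_spectrum
            errs.append(np.linalg.norm(recon - M))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_n_pcs_too_large(self):
        with pytest.raises(ParameterError):
            bs.pca_fit(np.random.default_rng(0).normal(size=(5, 8)), 7)

    def test_deterministic_sign_convention(self):
        M = np.random.default_rng(4).normal(size=(9, 5))
        a = bs.pca_fit(M)
        b = bs.pca_fit(M.copy())
        assert np.array_equal(a.loadings, b.loadings)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestPCALDA:
    def _toy(self, seed=0, n=16):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(n, 2)) + [0.0, 0.0],
            rng.normal(0.0, 1.0, size=(n, 2)) + [2.5, 1.0],
        ])
        y = np.array(["a"] * n + ["b"] * n)
        subjects = np.array([f"s{i}" for i in range(2 * n)])
        return X, y, subjects

    def test_full_rank_matches_direct_fisher_lda(self):
        """With all PCs retained, LD1 sample ordering equals Fisher LDA on
        the raw features (sklearn as independent oracle)."""
        X, y, subjects = self._toy()
        model = bs.pca_lda_fit(X, y, subjects=subjects, n_pcs=2, cv=None)
        oracle = LinearDiscriminantAnalysis(solver="eigen").fit(X, y).transform(X)[:, 0]
        rho = np.corrcoef(np.argsort(np.argsort(model.ld1_scores)),
                          np.argsort(np.argsort(oracle)))[0, 1]
        assert abs(rho) > 0.9999

    def test_ld1_is_projection_of_centred_scores(self):
        X, y, subjects = self._toy(seed=1)
        m = bs.pca_lda_fit(X, y, subjects=subjects, n_pcs=2, cv=None)
        assert np.allclose(m.ld1_scores, m.pca.scores @ m.lda_weights, atol=1e-10)

    def test_strong_effect_separates_with_small_p(self, default_study):
        """Implanted class effects far above noise give cross-validated LD1
        distributions separated at p < 1e-6."""
        ds, _ = default_study
        pre = bs.select_region(
            bs.apply_recipe(bs.average_replicates(ds), bs.PreprocessRecipe(variant="B")),
            "fingerprint",
        )
        m = bs.pca_lda_fit(pre, None)
        assert m.cv_p_value < 1e-6
        hc = m.cv_ld1_scores[m.labels == "HC"]
        cv = m.cv_ld1_scores[m.labels == "CVID"]
        assert abs(hc.mean() - cv.mean()) > 2 * (hc.std() + cv.std()) / 2

    def test_single_subject_class_raises(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array(["a", "a", "a", "a", "b", "b"])
        subjects = np.array(["s1", "s2", "s3", "s4", "s5", "s5"])
        with pytest.raises(CVDesignError):
            bs.pca_lda_fit(X, y, subjects=subjects, cv="leave_one_subject_out")

    def test_invariant_to_replicate_order_and_scaling(self, small_sim):
        _, ds, _ = small_sim
        pre = bs.select_region(bs.apply_recipe(ds, bs.PreprocessRecipe(variant="B")),
                               "fingerprint")
        m1 = bs.pca_lda_fit(pre, None, cv=None)
        perm = np.random.default_rng(0).permutation(pre.n_spectra)
        shuffled = pre.subset(perm)
        m2 = bs.pca_lda_fit(shuffled, None, cv=None)
        # compare per-subject mean LD1 (order-free)
        def by_subject(m, dsx):
            subs = np.array([r.subject_id for r in dsx.records])
            return {s: m.ld1_scores[subs == s].mean() for s in set(subs)}
        d1, d2 = by_subject(m1, pre), by_subject(m2, shuffled)
        assert all(np.isclose(d1[s], d2[s], atol=1e-8) for s in d1)
        scaled = pre.with_matrix(pre.matrix * 3.7)
        m3 = bs.pca_lda_fit(scaled, None, cv=None)
        rho = np.corrcoef(m1.ld1_scores, m3.ld1_scores)[0, 1]
        assert abs(rho) > 1 - 1e-9

    def test_cv_fold_excludes_held_out_subject(self, small_sim):
        """Recompute one LOSO fold from scratch and match cv_ld1_scores."""
        _, ds, _ = small_sim
        pre = bs.select_region(
            bs.apply_recipe(bs.average_replicates(ds), bs.PreprocessRecipe(variant="B")),
            "fingerprint",
        )
        m = bs.pca_lda_fit(pre, None, n_pcs=4)
        subs = np.array([r.subject_id for r in pre.records])
        held = subs == subs[0]
        # manual fold: fit on everything except subject 0
        fold = bs.pca_lda_fit(pre.subset(~held), None, n_pcs=4, cv=None)
        manual = fold.pca.transform(pre.matrix[held]) @ fold.lda_weights
        got = m.cv_ld1_scores[held]
        assert np.allclose(np.abs(manual), np.abs(got), atol=1e-8)


class TestClusterVectors:
    def test_track_shape_and_one_pseudo_spectrum_per_class(self):
        X, y = np.random.default_rng(5).normal(size=(20, 12)), None
        labels = np.array(["a"] * 10 + ["b"] * 10)
        m = bs.pca_lda_fit(X, labels, subjects=np.arange(20).astype(str), cv=None)
        cv = bs.cluster_vectors(m)
        assert cv.discriminant_track.size == 12
        assert set(cv.pseudo_spectra) == {"a", "b"}

    def test_single_informative_wavenumber_localised(self, fingerprint_axis):
        """An effect implanted at one axis point dominates the track there."""
        rng = np.random.default_rng(6)
        n = 30
        X = rng.normal(0, 1.0, size=(2 * n, fingerprint_axis.size))
        j_star = 80  # 1220 cm^-1
        X[n:, j_star] += 8.0
        labels = np.array(["HC"] * n + ["CVID"] * n)
        m = bs.pca_lda_fit(X, labels, subjects=np.arange(2 * n).astype(str), cv=None)
        track = bs.cluster_vectors(m).discriminant_track
        assert abs(int(np.argmax(track)) - j_star) <= 1

    def test_null_track_has_no_dominant_peak(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 100))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        m = bs.pca_lda_fit(X, labels, subjects=np.arange(40).astype(str), cv=None)
        track = bs.cluster_vectors(m).discriminant_track
        assert track.max() < 5 * np.median(track)
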