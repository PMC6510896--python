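"""PCA and cross-validated PCA-LDA with cluster-vector back-projection.

The discriminant model follows the classical biospectroscopy construction:
spectra are reduced by a centred singular-value decomposition to a handful
of principal-component scores, and a Fisher linear discriminant is fitted on
those scores.  The LD1 direction can be back-projected through the PCA
loadings into wavenumber space ("cluster vectors"), which localises the
wavenumbers driving class separation and is one of the three biomarker
extraction routes.

Cross-validation is leave-one-subject-out: all spectra of the held-out
subject are excluded from both the PCA and the LDA fit of that fold, so
replicate structure cannot leak into the held-out scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .exceptions import CVDesignError, ParameterError
from .io import SpectralDataset

_RIDGE = 1e-8  # fraction of trace added to the pooled covariance


@dataclass
class PCAModel:
    """Centred PCA of a spectral matrix.

    ``loadings`` rows are orthonormal; the sign convention is that the
    largest-magnitude element of each loading is positive, which makes the
    decomposition deterministic.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray          # (n_pcs, n_wavenumbers)
    scores: np.ndarray            # (n_samples, n_pcs)
    explained_fraction: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_spectrum) @ self.loadings.T


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectralDataset):
        return X.matrix
    return np.asarray(X, float)


def pca_fit(X, n_pcs: int | float | None = None) -> PCAModel:
    """Fit a centred PCA by singular-value decomposition.

    ``n_pcs`` may be an integer count, a variance-fraction target in (0, 1)
    (smallest count whose cumulative explained variance reaches it), or
    ``None`` for the full rank.
    """
    M = _as_matrix(X)
    n, p = M.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 samples")
    rank_cap = min(n - 1, p)
    mean = M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M - mean, full_matrices=False)
    s = s[:rank_cap]
    U = U[:, :rank_cap]
    Vt = Vt[:rank_cap]
    var = s**2 / (n - 1)
    total = ((M - mean) ** 2).sum() / (n - 1)
    explained = var / total if total > 0 else np.zeros_like(var)
    if n_pcs is None:
        k = rank_cap
    elif isinstance(n_pcs, float) and 0 < n_pcs < 1:
        k = int(np.searchsorted(np.cumsum(explained), n_pcs) + 1)
        k = min(k, rank_cap)
    else:
        k = int(n_pcs)
        if k < 1 or k > rank_cap:
            raise ParameterError(
                f"n_pcs={k} outside [1, min(n_samples-1, n_wavenumbers)]={rank_cap}"
            )
    loadings = Vt[:k].copy()
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|.| loading element positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return PCAModel(mean, loadings, scores, explained[:k])


# ----------------------------------------------------------------------
# Fisher LDA on PC scores
# ----------------------------------------------------------------------

def _fisher_ld1(T: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """First discriminant direction on score matrix T (ridge-regularised)."""
    k = T.shape[1]
    means = np.vstack([T[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((k, k))
    for c, m in zip(classes, means):
        D = T[y == c] - m
        Sw += D.T @ D
    Sw /= max(T.shape[0] - len(classes), 1)
    Sw += (_RIDGE * np.trace(Sw) / k + 1e-300) * np.eye(k)
    if len(classes) == 2:
        w = linalg.solve(Sw, means[1] - means[0], assume_a="pos")
    else:
        grand = T.mean(axis=0)
        Sb = np.zeros((k, k))
        for c, m in zip(classes, means):
            n_c = int((y == c).sum())
            d = (m - grand)[:, None]
            Sb += n_c * (d @ d.T)
        vals, vecs = linalg.eigh(Sb, Sw)
        w = vecs[:, -1]
    return w / np.linalg.norm(w)


def _default_n_pcs(explained: np.ndarray, n_subjects: int, target: float = 0.99) -> int:
    # smallest count reaching the variance target, capped both at
    # n_subjects - 2 and at one PC per five subjects: Fisher LDA on more
    # dimensions than ~n/5 overfits noise directions at these sample sizes
    k = int(np.searchsorted(np.cumsum(explained), target) + 1)
    cap = max(min(n_subjects - 2, n_subjects // 5), 1)
    return max(min(k, explained.size, cap), 1)


@dataclass
class PCALDAModel:
    """PCA-LDA fit with per-sample LD1 scores and held-out CV scores."""

    pca: PCAModel
    lda_weights: np.ndarray
    classes: np.ndarray
    class_means_ld1: dict
    ld1_scores: np.ndarray
    cv_ld1_scores: np.ndarray | None = None
    cv_p_value: float | None = None
    labels: np.ndarray = field(default_factory=lambda: np.array([]))
    subjects: np.ndarray = field(default_factory=lambda: np.array([]))


def _orient(ld1: np.ndarray, y: np.ndarray, classes: np.ndarray) -> float:
    """Sign making the last (sorted) class the high-LD1 class."""
    m0 = ld1[y == classes[0]].mean()
    m1 = ld1[y == classes[-1]].mean()
    return 1.0 if m1 >= m0 else -1.0


def pca_lda_fit(
    X,
    labels,
    subjects=None,
    n_pcs: int | float | None = None,
    cv: str | None = "leave_one_subject_out",
) -> PCALDAModel:
    """Fit PCA-LDA and, optionally, leave-one-subject-out CV LD1 scores.

    Parameters
    ----------
    X
        Preprocessed :class:`SpectralDataset` or plain matrix.
    labels
        Class label per row; if None and X is a dataset, the record group.
    subjects
        Subject id per row (taken from dataset records when omitted);
        required for cross-validation.
    n_pcs
        Retained components; default = smallest count explaining >= 99% of
        variance, capped at (number of training subjects - 2).
    cv
        ``"leave_one_subject_out"`` or None to skip cross-validation.
    """
    M = _as_matrix(X)
    if labels is None and isinstance(X, SpectralDataset):
        labels = X.groups()
    y = np.asarray(labels)
    if subjects is None and isinstance(X, SpectralDataset):
        subjects = np.array([r.subject_id for r in X.records])
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("PCA-LDA needs at least 2 classes")

    def _fit(Mtr: np.ndarray, ytr: np.ndarray, subs: np.ndarray):
        n_subj = len(set(subs.tolist()))
        full = pca_fit(Mtr)
        if n_pcs is None:
            k = _default_n_pcs(full.explained_fraction, n_subj)
        elif isinstance(n_pcs, float) and 0 < n_pcs < 1:
            k = _default_n_pcs(full.explained_fraction, n_subj, target=n_pcs)
        else:
            k = min(int(n_pcs), full.n_pcs)
        pca = PCAModel(
            full.mean_spectrum,
            full.loadings[:k],
            full.scores[:, :k],
            full.explained_fraction[:k],
        )
        w = _fisher_ld1(pca.scores, ytr, classes)
        return pca, w

    subs = np.asarray(subjects) if subjects is not None else np.arange(len(y)).astype(str)
    pca, w = _fit(M, y, subs)
    ld1 = pca.scores @ w
    sgn = _orient(ld1, y, classes)
    w = w * sgn
    ld1 = ld1 * sgn
    class_means = {c: float(ld1[y == c].mean()) for c in classes}

    cv_scores = None
    cv_p = None
    if cv == "leave_one_subject_out":
        uniq = list(dict.fromkeys(subs.tolist()))
        for c in classes:
            n_c = len(set(subs[y == c].tolist()))
            if n_c < 2:
                raise CVDesignError(f"class {c!r} has {n_c} subject(s); CV needs >= 2")
        cv_scores = np.empty(len(y))
        for s in uniq:
            held = subs == s
            pca_f, w_f = _fit(M[~held], y[~held], subs[~held])
            ld1_tr = pca_f.scores @ w_f
            sgn_f = _orient(ld1_tr, y[~held], classes)
            cv_scores[held] = (pca_f.transform(M[held]) @ w_f) * sgn_f
        if classes.size == 2:
            a = cv_scores[y == classes[0]]
            b = cv_scores[y == classes[1]]
            cv_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            cv_p = float(stats.f_oneway(*(cv_scores[y == c] for c in classes)).pvalue)

    return PCALDAModel(
        pca=pca,
        lda_weights=w,
        classes=classes,
        class_means_ld1=class_means,
        ld1_scores=ld1,
        cv_ld1_scores=cv_scores,
        cv_p_value=cv_p,
        labels=y,
        subjects=subs,
    )


@dataclass
class ClusterVectorSet:
    """Back-projection of LD1 through the PCA loadings into wavenumber space."""

    discriminant_track: np.ndarray           # |w^T L| per wavenumber
    pseudo_spectra: dict                     # class -> class_mean_ld1 * (w^T L)
    signed_track: np.ndarray                 # w^T L (signed)


def cluster_vectors(model: PCALDAModel) -> ClusterVectorSet:
    """Cluster-vector analysis of a fitted PCA-LDA model.

    The discriminant track ``|w^T loadings|`` localises the wavenumbers
    driving LD1; its peaks are candidate biomarkers.  Each class's pseudo-
    spectrum is the track scaled by the class-mean LD1 score.
    """
    signed = model.lda_weights @ model.pca.loadings
    pseudo = {c: model.class_means_ld1[c] * signed for c in model.classes}
    return ClusterVectorSet(np.abs(signed), pseudo, signed)
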