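"""Spectral biomarker extraction, peak panels and subject-level statistics.

Three per-wavenumber score tracks are computed on the training data:

* ``ttest`` — Welch two-sample t-test per wavenumber on subject-averaged
  spectra; score = -log10(p);
* ``cluster_vector`` — |LD1 back-projected through the PCA loadings|;
* ``ffs`` — forward feature selection: over bootstrap resamples of the
  subjects, wavenumbers are ranked by variance-weighted |PCA loading| and
  greedily retained while they improve the Welch p-value of the class
  contrast on a running difference-of-means projection (at most 6 per
  round); score = how many rounds selected each wavenumber.

From each track the six highest well-separated local maxima are retained
(candidates within 10 cm^-1 of an already-retained peak are omitted), and
the per-method panels are merged with the same proximity rule.  Retained
biomarkers are then read back on intensity-preserving (rubber-band +
vector-normalised) spectra: per-subject means of the replicates, Welch
t-tests with 95% confidence intervals for each group contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from .chemometrics import PCALDAModel, PCAModel, cluster_vectors
from .exceptions import DesignError, ParameterError
from .io import SpectralDataset, average_replicates

GROUP_LABELS = ("HC", "CVID", "CVID_non", "CVID_comp")

DEFAULT_CONTRASTS = (
    ("HC", "CVID"),
    ("HC", "CVID_non"),
    ("HC", "CVID_comp"),
    ("CVID_non", "CVID_comp"),
)


@dataclass
class FeatureScoreTrack:
    """Per-wavenumber non-negative score for one extraction method."""

    method: str
    axis: np.ndarray
    score: np.ndarray
    signs: np.ndarray | None = None  # sign of (CVID - HC) mean difference

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, float)
        self.score = np.asarray(self.score, float)
        if self.score.shape != self.axis.shape:
            raise DesignError("score track and axis lengths differ")
        if not np.all(np.isfinite(self.score)) or np.any(self.score < 0):
            raise DesignError("scores must be finite and non-negative")


@dataclass
class BiomarkerPeak:
    wavenumber: float
    method: str
    score: float
    p_value: float | None = None
    direction: str | None = None          # up_in_CVID / down_in_CVID
    methods: tuple = ()                   # corroborating methods (merged panels)

    @property
    def corroborated(self) -> bool:
        return len(set(self.methods)) >= 2


@dataclass
class BiomarkerPanel:
    peaks: list
    omitted: list = field(default_factory=list)   # (peak, rule) pairs
    min_separation: float = 10.0

    def wavenumbers(self) -> np.ndarray:
        return np.array([p.wavenumber for p in self.peaks])


# ----------------------------------------------------------------------
# score tracks
# ----------------------------------------------------------------------

def _two_class_arrays(ds: SpectralDataset, labels, subject_level: bool):
    if subject_level:
        if labels is not None and len(labels) == ds.n_spectra:
            by_subject = {}
            for rec, lab in zip(ds.records, np.asarray(labels)):
                prev = by_subject.setdefault((rec.subject_id, rec.biofluid), lab)
                if prev != lab:
                    raise DesignError(f"subject {rec.subject_id!r} has mixed labels")
            ds = average_replicates(ds)
            labels = np.array([by_subject[(r.subject_id, r.biofluid)] for r in ds.records])
        else:
            ds = average_replicates(ds)
    y = np.asarray(labels) if labels is not None else ds.groups()
    classes = np.unique(y)
    if classes.size != 2:
        raise DesignError(f"expected 2 classes, got {classes.tolist()}")
    return ds, y, classes


def ttest_track(
    train: SpectralDataset, labels=None, subject_level: bool = True
) -> FeatureScoreTrack:
    """Per-wavenumber Welch t-test track; score = -log10(p).

    By default the test runs on subject-averaged spectra (n = subjects);
    ``subject_level=False`` tests the individual spectra instead.
    """
    ds, y, classes = _two_class_arrays(train, labels, subject_level)
    for c in classes:
        if (y == c).sum() < 2:
            raise DesignError(f"class {c!r} has fewer than 2 samples")
    A = ds.matrix[y == classes[0]]
    B = ds.matrix[y == classes[1]]
    res = stats.ttest_ind(A, B, axis=0, equal_var=False)
    p = np.clip(res.pvalue, 1e-300, 1.0)
    # sign of CVID-minus-HC difference when the classes are the standard pair
    diff = B.mean(axis=0) - A.mean(axis=0)
    if "CVID" in classes and "HC" in classes and classes[0] != "HC":
        diff = -diff
    return FeatureScoreTrack("ttest", ds.axis, -np.log10(p), signs=np.sign(diff))


def cluster_vector_track(model: PCALDAModel, axis: np.ndarray) -> FeatureScoreTrack:
    """Cluster-vector discriminant track of a fitted PCA-LDA model."""
    cv = cluster_vectors(model)
    signs = None
    if model.classes.size == 2:
        # signed pseudo-spectrum difference oriented as CVID - HC when present
        lo, hi = model.classes[0], model.classes[-1]
        diff = cv.pseudo_spectra[hi] - cv.pseudo_spectra[lo]
        if "HC" in model.classes and hi == "HC":
            diff = -diff
        signs = np.sign(diff)
    return FeatureScoreTrack("cluster_vector", np.asarray(axis, float), cv.discriminant_track, signs=signs)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def ffs_track(
    train: SpectralDataset,
    labels=None,
    pca: PCAModel | None = None,
    rounds: int = 100,
    seed: int = 0,
    max_features: int = 6,
    alpha_enter: float = 0.05,
    subject_level: bool = True,
) -> FeatureScoreTrack:
    """Forward-feature-selection track; score = selection count per wavenumber.

    Each round bootstraps subjects within class, ranks wavenumbers by
    variance-weighted aggregate |PCA loading| (the PCA is refit on each
    bootstrap resample unless a fixed ``pca`` is supplied), and greedily
    retains wavenumbers that reduce the Welch p-value of the class contrast
    on the running difference-of-means projection (with a standard
    alpha-to-enter gate: a feature must reach ``alpha_enter`` to be
    retained at all), stopping at ``max_features`` retained features or at
    the end of the candidate list.
    """
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    ds, y, classes = _two_class_arrays(train, labels, subject_level)
    from .chemometrics import pca_fit

    fixed_rank = None
    if pca is not None:
        weight = pca.explained_fraction @ np.abs(pca.loadings)
        fixed_rank = np.argsort(-weight, kind="stable")
    rng = np.random.default_rng(seed)
    counts = np.zeros(ds.axis.size)
    idx_a = np.flatnonzero(y == classes[0])
    idx_b = np.flatnonzero(y == classes[1])
    for _ in range(rounds):
        boot_a = rng.choice(idx_a, size=idx_a.size, replace=True)
        boot_b = rng.choice(idx_b, size=idx_b.size, replace=True)
        A = ds.matrix[boot_a]
        B = ds.matrix[boot_b]
        if fixed_rank is None:
            boot_pca = pca_fit(np.vstack([A, B]))
            weight = boot_pca.explained_fraction @ np.abs(boot_pca.loadings)
            rank = np.argsort(-weight, kind="stable")
        else:
            rank = fixed_rank
        selected: list[int] = []
        proj_a = np.zeros(A.shape[0])
        proj_b = np.zeros(B.shape[0])
        best_p = alpha_enter
        for j in rank:
            sgn = np.sign(B[:, j].mean() - A[:, j].mean()) or 1.0
            cand_a = proj_a + sgn * A[:, j]
            cand_b = proj_b + sgn * B[:, j]
            p = _welch_p(cand_a, cand_b)
            if p < best_p:
                selected.append(int(j))
                proj_a, proj_b = cand_a, cand_b
                best_p = p
                if len(selected) >= max_features:
                    break
        counts[selected] += 1
    return FeatureScoreTrack("ffs", ds.axis, counts)


# ----------------------------------------------------------------------
# peak detection and panel merging
# ----------------------------------------------------------------------

def _local_maxima(score: np.ndarray) -> list[int]:
    """Strict local maxima; plateaus contribute their lowest index;
    endpoints are eligible against their single neighbour."""
    n = score.size
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and score[j + 1] == score[i]:
            j += 1
        left_ok = i == 0 or score[i - 1] < score[i]
        right_ok = j == n - 1 or score[j + 1] < score[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i)
        i = j + 1
    return maxima


def detect_peaks(
    track: FeatureScoreTrack,
    k: int = 6,
    min_separation: float = 10.0,
) -> BiomarkerPanel:
    """Retain the ``k`` highest well-separated local maxima of a track.

    Candidates are ranked by height (ties toward the lower wavenumber) and
    retained greedily; a candidate within ``min_separation`` cm^-1 of an
    already-retained peak is omitted and recorded as such.
    """
    idxs = _local_maxima(track.score)
    idxs.sort(key=lambda i: (-track.score[i], track.axis[i]))
    peaks: list[BiomarkerPeak] = []
    omitted: list[tuple] = []
    for i in idxs:
        if len(peaks) >= k:
            break
        w = float(track.axis[i])
        direction = None
        if track.signs is not None and track.signs[i] != 0:
            direction = "up_in_CVID" if track.signs[i] > 0 else "down_in_CVID"
        p_value = 10.0 ** (-track.score[i]) if track.method == "ttest" else None
        peak = BiomarkerPeak(
            w, track.method, float(track.score[i]), p_value, direction, (track.method,)
        )
        near = [q for q in peaks if abs(q.wavenumber - w) <= min_separation]
        if near:
            omitted.append((peak, f"within {min_separation} cm^-1 of {near[0].wavenumber}"))
        else:
            peaks.append(peak)
    return BiomarkerPanel(peaks, omitted, min_separation)


def merge_panels(panels: list, min_separation: float = 10.0) -> BiomarkerPanel:
    """Merge per-method panels into one proximity-filtered consensus panel.

    Scores from different methods are incommensurable, so candidates are
    ordered by their within-method max-normalised score.  When a candidate
    falls within ``min_separation`` of a retained peak, it is omitted and
    its method recorded as corroborating the retained peak.
    """
    if not panels:
        return BiomarkerPanel([], [], min_separation)
    cands: list[tuple[float, BiomarkerPeak]] = []
    for panel in panels:
        if panel.peaks:
            top = max(p.score for p in panel.peaks) or 1.0
            for p in panel.peaks:
                cands.append((p.score / top, p))
    cands.sort(key=lambda t: (-t[0], t[1].wavenumber, t[1].method))
    merged: list[BiomarkerPeak] = []
    omitted: list[tuple] = []
    for norm_score, p in cands:
        hit = None
        for q in merged:
            if abs(q.wavenumber - p.wavenumber) <= min_separation:
                hit = q
                break
        if hit is None:
            merged.append(replace(p, methods=(p.method,)))
        else:
            hit.methods = tuple(dict.fromkeys((*hit.methods, p.method)))
            if abs(hit.wavenumber - p.wavenumber) > 0:
                omitted.append((p, f"within {min_separation} cm^-1 of {hit.wavenumber}"))
            if hit.direction is None and p.direction is not None:
                hit.direction = p.direction
    merged.sort(key=lambda q: q.wavenumber)
    return BiomarkerPanel(merged, omitted, min_separation)


# ----------------------------------------------------------------------
# subject-level intensity analysis
# ----------------------------------------------------------------------

@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    wavenumber: float
    mean_a: float
    mean_b: float
    ci95: tuple
    p_value: float
    direction: str | None = None
    n_a: int = 0
    n_b: int = 0


def _membership(rec, label: str) -> bool:
    if label == "HC":
        return rec.group == "HC"
    if label == "CVID":
        return rec.group == "CVID"
    if label == "CVID_non":
        return rec.group == "CVID" and rec.subgroup == "complication_free"
    if label == "CVID_comp":
        return rec.group == "CVID" and rec.subgroup == "complications"
    raise DesignError(f"unknown group label {label!r}")


def subject_intensity_analysis(
    ds: SpectralDataset,
    panel: BiomarkerPanel,
    contrasts=DEFAULT_CONTRASTS,
) -> list:
    """Per-biomarker, per-contrast Welch comparisons of subject means.

    ``ds`` should be intensity-preserving (variant A) preprocessed data with
    the full replicate structure; the statistic for each subject is the mean
    of its replicates at the biomarker wavenumber, so p-values are computed
    on n = subjects, never n = spectra.
    """
    averaged = average_replicates(ds)
    axis = averaged.axis
    step = float(np.diff(axis).mean()) if axis.size >= 2 else 1.0
    results: list[GroupComparison] = []
    for peak in panel.peaks:
        j = int(np.argmin(np.abs(axis - peak.wavenumber)))
        # band labels (e.g. 1034 cm^-1) snap to the nearest axis point
        if abs(axis[j] - peak.wavenumber) > step / 2 + 1e-9:
            raise DesignError(f"biomarker {peak.wavenumber} cm^-1 is not on the axis")
        col = averaged.matrix[:, j]
        for ga, gb in contrasts:
            a = np.array([v for v, r in zip(col, averaged.records) if _membership(r, ga)])
            b = np.array([v for v, r in zip(col, averaged.records) if _membership(r, gb)])
            if a.size < 2 or b.size < 2:
                raise DesignError(f"contrast {ga} vs {gb} has a group with < 2 subjects")
            res = stats.ttest_ind(a, b, equal_var=False)
            diff = a.mean() - b.mean()
            se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
            df = res.df
            half = stats.t.ppf(0.975, df) * se if se > 0 else 0.0
            direction = None
            cvid_like = {"CVID", "CVID_non", "CVID_comp"}
            if ga == "HC" and gb in cvid_like:
                direction = "up_in_CVID" if b.mean() > a.mean() else "down_in_CVID"
            elif gb == "HC" and ga in cvid_like:
                direction = "up_in_CVID" if a.mean() > b.mean() else "down_in_CVID"
            results.append(
                GroupComparison(
                    ga, gb, float(axis[j]), float(a.mean()), float(b.mean()),
                    (float(diff - half), float(diff + half)), float(res.pvalue),
                    direction, a.size, b.size,
                )
            )
    return results


# ----------------------------------------------------------------------
# power analysis
# ----------------------------------------------------------------------

@dataclass
class PowerResult:
    n_a: int
    n_b: int
    alpha: float
    power_target: float
    achieved_power: float
    effect_size: float
    effect_inputs: dict


def power_min_n(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    alpha: float = 0.05,
    power_target: float = 0.80,
    ratio: float = 1.0,
) -> PowerResult:
    """Smallest group sizes reaching the target power for a two-tailed
    two-sample t-test under the noncentral-t model.

    ``ratio = n_a / n_b`` is held (up to integer rounding) while the sizes
    grow; minimality is verified by checking that one step smaller falls
    below the target.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ParameterError("standard deviations must be positive")
    if mean_a == mean_b:
        raise ParameterError("means are equal: no finite sample size reaches the target")
    if not 0 < alpha < 1 or not 0 < power_target < 1:
        raise ParameterError("alpha and power_target must lie in (0, 1)")
    d = abs(mean_a - mean_b) / np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    solver = TTestIndPower()

    def achieved(n_b: int) -> tuple[float, int]:
        n_a = max(int(round(ratio * n_b)), 2)
        return (
            float(solver.power(effect_size=d, nobs1=n_a, ratio=n_b / n_a, alpha=alpha)),
            n_a,
        )

    n_b = 2
    power, n_a = achieved(n_b)
    while power < power_target:
        n_b += 1
        power, n_a = achieved(n_b)
        if n_b > 10_000_000:  # pragma: no cover - defensive
            raise ParameterError("no attainable sample size below 1e7")
    return PowerResult(
        n_a, n_b, alpha, power_target, power, float(d),
        {"mean_a": mean_a, "sd_a": sd_a, "mean_b": mean_b, "sd_b": sd_b, "ratio": ratio},
    )
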