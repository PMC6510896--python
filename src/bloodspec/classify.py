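"""Patient-level splitting and RBF-SVM classification.

The train/test split is the Kennard-Stone max-min-distance selection run
per class on subject-mean preprocessed spectra, so no subject contributes
spectra to both sides.  SVM hyperparameters (c, gamma) come from a grid
search scored by subject-grouped stratified k-fold cross-validation on the
training spectra; sensitivity and specificity are computed from the pooled
("accumulated hits") per-spectrum counts of the test predictions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.svm import SVC

from .exceptions import CVDesignError, DesignError, LeakageError, ParameterError
from .io import SpectralDataset, average_replicates, select_region
from .preprocess import PreprocessRecipe, apply_recipe

log = logging.getLogger("bloodspec.classify")

#: libsvm-style default grids (powers of 4)
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 4))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 4))


def label_three_class(records) -> np.ndarray:
    """HC / CVID_non / CVID_comp labelling from group + subgroup."""
    out = []
    for r in records:
        if r.group == "HC":
            out.append("HC")
        elif r.subgroup == "complication_free":
            out.append("CVID_non")
        elif r.subgroup == "complications":
            out.append("CVID_comp")
        else:
            raise DesignError(
                f"CVID subject {r.subject_id!r} has no subgroup; "
                "three-class labelling needs one"
            )
    return np.array(out)


def make_labels(records, labelling: str) -> np.ndarray:
    if labelling == "two_class":
        return np.array([r.group for r in records])
    if labelling == "three_class":
        return label_three_class(records)
    raise DesignError(f"unknown labelling {labelling!r}")


# ----------------------------------------------------------------------
# Kennard-Stone
# ----------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Patient-level train/test assignment."""

    train_subjects: frozenset
    test_subjects: frozenset
    fraction: float
    selection_order: dict = field(default_factory=dict)  # class -> [subject ids]

    def mask(self, subjects: Sequence[str], train: bool = True) -> np.ndarray:
        pool = self.train_subjects if train else self.test_subjects
        return np.array([s in pool for s in subjects])


def _kennard_stone_order(X: np.ndarray, n_select: int) -> list[int]:
    """Max-min selection sequence of ``n_select`` row indices of X."""
    D = cdist(X, X)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    first = sorted((int(i), int(j)))
    selected = list(first[:n_select])
    if n_select <= 1:
        return selected[:n_select]
    mind = np.minimum(D[selected[0]], D[selected[1]])
    mind[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(mind))
        selected.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    return selected


def kennard_stone_split(
    ds: SpectralDataset,
    fraction: float = 2.0 / 3.0,
    labels=None,
    per_class: bool = True,
) -> SplitPlan:
    """Kennard-Stone train/test split on subject-mean spectra.

    ``ds`` must contain one row per subject (average replicates first).
    Within each class the training set is grown by max-min Euclidean
    distance, seeded with the two most mutually distant subjects, until
    ``round(fraction * n_class)`` subjects are chosen; the rest are test.
    Deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ParameterError("fraction must lie in (0, 1)")
    subjects = np.array([r.subject_id for r in ds.records])
    if len(set(subjects.tolist())) != len(subjects):
        raise DesignError("Kennard-Stone expects one (averaged) row per subject")
    y = np.asarray(labels) if labels is not None else ds.groups()
    train: list[str] = []
    order: dict = {}
    class_iter = np.unique(y) if per_class else np.array(["__all__"])
    for c in class_iter:
        idx = np.flatnonzero(y == c) if per_class else np.arange(len(y))
        if idx.size < 2:
            raise CVDesignError(f"class {c!r} has fewer than 2 subjects")
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        sel = _kennard_stone_order(ds.matrix[idx], n_train)
        chosen = [subjects[idx[s]] for s in sel]
        order[str(c)] = chosen
        train.extend(chosen)
    train_set = frozenset(train)
    test_set = frozenset(subjects.tolist()) - train_set
    return SplitPlan(train_set, test_set, fraction, order)


# ----------------------------------------------------------------------
# SVM
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM grid-search settings."""

    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ParameterError("c and gamma grids must be non-empty")
        if any(v <= 0 for v in self.c_grid) or any(v <= 0 for v in self.gamma_grid):
            raise ParameterError("grid values must be positive")
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")


def svm_grid_search(X, labels, subjects, cfg: SVMConfig) -> tuple[float, float, float]:
    """Grid search (c, gamma) by subject-grouped stratified k-fold CV.

    Accuracy per grid point is the pooled per-spectrum accuracy over all
    folds.  Ties break toward the smallest c, then the smallest gamma.
    Returns ``(c, gamma, cv_accuracy)``.
    """
    M = X.matrix if isinstance(X, SpectralDataset) else np.asarray(X, float)
    y = np.asarray(labels)
    subs = np.asarray(subjects)
    min_subjects = min(len(set(subs[y == c].tolist())) for c in np.unique(y))
    if min_subjects < 2:
        raise CVDesignError("grid-search CV needs >= 2 subjects per class")
    folds = min(cfg.folds, min_subjects)
    if folds < cfg.folds:
        log.warning(
            "clamping grid-search folds from %d to %d (smallest class has "
            "%d subjects)", cfg.folds, folds, min_subjects,
        )
    splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    # subject-level stratified folds: one representative row per subject
    folds = list(splitter.split(M, y, groups=subs))
    best = (-1.0, None, None)
    for c in sorted(cfg.c_grid):
        for g in sorted(cfg.gamma_grid):
            hits = 0
            for tr, te in folds:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(M[tr], y[tr])
                hits += int((clf.predict(M[te]) == y[te]).sum())
            acc = hits / len(y)
            if acc > best[0]:
                best = (acc, c, g)
    return best[1], best[2], best[0]


@dataclass
class ConfusionReport:
    """Spectrum-level confusion counts with accumulated-hit rates.

    ``per_class_rate``, ``sensitivity`` and ``specificity`` are percentages
    in [0, 100]; a class absent from the test set has its entries set to
    NaN and is listed in ``undefined``.
    """

    counts: pd.DataFrame
    per_class_rate: dict
    sensitivity: dict
    specificity: dict
    undefined: list = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        return 100.0 * np.trace(self.counts.to_numpy()) / total if total else float("nan")


def confusion_report(y_true, y_pred, classes=None) -> ConfusionReport:
    """Assemble a :class:`ConfusionReport` from true/predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = list(classes)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    ci = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[ci[t], ci[p]] += 1
    counts = pd.DataFrame(cm, index=classes, columns=classes)
    rate, sens, spec, undef = {}, {}, {}, []
    total = cm.sum()
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            rate[c] = sens[c] = float("nan")
            undef.append(c)
        else:
            rate[c] = 100.0 * tp / (tp + fn)
            sens[c] = 100.0 * tp / (tp + fn)
        spec[c] = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return ConfusionReport(counts, rate, sens, spec, undef)


def svm_train_predict(
    train: SpectralDataset | np.ndarray,
    test: SpectralDataset | np.ndarray,
    c: float,
    gamma: float,
    train_labels=None,
    test_labels=None,
) -> ConfusionReport:
    """Fit an RBF-SVM on training spectra and report test-set confusion."""
    if isinstance(train, SpectralDataset) and isinstance(test, SpectralDataset):
        tr_subj = {r.subject_id for r in train.records}
        te_subj = {r.subject_id for r in test.records}
        overlap = tr_subj & te_subj
        if overlap:
            raise LeakageError(f"subjects in both train and test: {sorted(overlap)}")
        if train_labels is None:
            train_labels = train.groups()
        if test_labels is None:
            test_labels = test.groups()
        Mtr, Mte = train.matrix, test.matrix
    else:
        Mtr = np.asarray(train, float)
        Mte = np.asarray(test, float)
    y_tr = np.asarray(train_labels)
    y_te = np.asarray(test_labels)
    clf = SVC(C=c, gamma=gamma, kernel="rbf")
    clf.fit(Mtr, y_tr)
    pred = clf.predict(Mte)
    return confusion_report(y_te, pred, classes=np.unique(y_tr))


# ----------------------------------------------------------------------
# end-to-end classification
# ----------------------------------------------------------------------

@dataclass
class ClassificationResultBundle:
    split: SplitPlan
    c: float
    gamma: float
    cv_accuracy: float
    report: ConfusionReport
    provenance: dict


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_classification(
    ds: SpectralDataset,
    recipe: PreprocessRecipe,
    region,
    labelling: str = "two_class",
    cfg: SVMConfig | None = None,
    fraction: float = 2.0 / 3.0,
) -> ClassificationResultBundle:
    """Full classification pipeline on one dataset.

    preprocess -> select region -> Kennard-Stone patient split (on subject
    averages) -> grid-searched RBF-SVM on the training spectra -> confusion
    report on the held-out test spectra.
    """
    cfg = cfg or SVMConfig()
    pre = select_region(apply_recipe(ds, recipe), region)
    averaged = average_replicates(pre)
    split = kennard_stone_split(
        averaged, fraction=fraction, labels=make_labels(averaged.records, labelling)
    )
    subjects = np.array([r.subject_id for r in pre.records])
    tr_mask = split.mask(subjects, train=True)
    train_ds = pre.subset(tr_mask)
    test_ds = pre.subset(~tr_mask)
    y_tr = make_labels(train_ds.records, labelling)
    y_te = make_labels(test_ds.records, labelling)
    tr_subjects = np.array([r.subject_id for r in train_ds.records])
    c, g, cv_acc = svm_grid_search(train_ds, y_tr, tr_subjects, cfg)
    report = svm_train_predict(train_ds, test_ds, c, g, y_tr, y_te)
    prov = {
        "seed": cfg.seed,
        "config_hash": _config_hash(
            {
                "recipe": recipe.variant,
                "region": str(region),
                "labelling": labelling,
                "fraction": fraction,
                "c_grid": list(cfg.c_grid),
                "gamma_grid": list(cfg.gamma_grid),
                "folds": cfg.folds,
                "seed": cfg.seed,
            }
        ),
    }
    return ClassificationResultBundle(split, c, g, cv_acc, report, prov)
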