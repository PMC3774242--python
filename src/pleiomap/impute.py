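"""Impute focal-locus functionality from SNPs around the locus.

A radial-basis-function support vector classifier is trained on the 0/1
haploid alleles of all SNPs within a window (default ±100 kb) of the
focal locus, with the kernel width and regularization chosen by grid
search on inner cross-validation accuracy.  Two evaluation protocols are
provided: stratified k-fold cross-validation (:func:`kfold_cv`, default
fourfold) and repeated leave-one-out cross-validation on random
accession subsets of size n (:func:`subset_loocv`), which measures how
quickly the SNP–functionality association becomes learnable as the
labeled sample grows.

Grid search and any preprocessing happen strictly inside training splits,
so a label-permutation control recovers the majority-class baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import (
    CVReport,
    FeatureWindow,
    LABEL_UNKNOWN,
    PleiomapError,
    SNPPanel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "extract_window",
    "train_classifier",
    "kfold_cv",
    "subset_loocv",
    "impute_labels",
]


@dataclass
class ClassifierSpec:
    """RBF-SVC hyperparameter grid and inner-CV layout.

    ``widths`` are RBF gamma values (similarity decays as
    exp(-gamma * ||x - x'||²)); ``regularizations`` are SVC C values.
    Ties in inner-CV accuracy resolve to the smallest regularization,
    then the smallest width.
    """

    widths: tuple[float, ...] = tuple(2.0 ** k for k in range(-6, 3, 2))
    regularizations: tuple[float, ...] = tuple(2.0 ** k for k in range(-2, 7, 2))
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.widths or not self.regularizations:
            raise PleiomapError("hyperparameter grids must be non-empty")
        if min(self.widths) <= 0 or min(self.regularizations) <= 0:
            raise PleiomapError("hyperparameters must be positive")


@dataclass
class TrainedClassifier:
    model: SVC
    width: float
    regularization: float
    inner_cv_accuracy: float
    spec: ClassifierSpec = field(repr=False, default=None)


def extract_window(panel: SNPPanel, focal_chrom: str, focal_pos: int,
                   half_span_bp: int = 100_000) -> FeatureWindow:
    """SNP features in the closed interval focal ± half_span.

    Missing calls are filled with the SNP's major allele (count logged).
    """
    sel = np.flatnonzero(
        (panel.chrom == focal_chrom) &
        (panel.pos >= focal_pos - half_span_bp) &
        (panel.pos <= focal_pos + half_span_bp))
    if sel.size == 0:
        raise PleiomapError(
            f"no SNPs within ±{half_span_bp} bp of {focal_chrom}:{focal_pos}")
    X = panel.genotypes[:, sel].copy()
    all_missing = np.flatnonzero(np.isnan(X).all(axis=1))
    n_filled = int(np.isnan(X).sum())
    if n_filled:
        with np.errstate(invalid="ignore"):
            major = (np.nanmean(X, axis=0) >= 0.5).astype(float)
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(major, X.shape)[miss]
        logger.info("filled %d missing window calls with the major allele",
                    n_filled)
    return FeatureWindow(
        focal_chrom=focal_chrom, focal_pos=focal_pos,
        half_span_bp=half_span_bp,
        snp_ids=panel.snp_ids[sel], snp_pos=panel.pos[sel],
        X=X, accession_ids=list(panel.accession_ids),
        n_missing_filled=n_filled, all_missing_rows=all_missing)


def _fold_accuracy(X, y, tr, te, gamma, C) -> float:
    clf = SVC(kernel="rbf", gamma=gamma, C=C)
    clf.fit(X[tr], y[tr])
    return float(np.mean(clf.predict(X[te]) == y[te]))


def _precompute_kernels(X: np.ndarray, widths) -> dict:
    """RBF Gram matrices exp(-gamma ||x - x'||²) for every grid width.

    Precomputing once per dataset turns the CV protocols' many small SVC
    fits into cheap precomputed-kernel fits.
    """
    sq = np.sum(X ** 2, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    return {g: np.exp(-g * D2) for g in widths}


def _kfold_accuracy_k(Ks, y, idx_tr, idx_te, gamma, C) -> float:
    K = Ks[gamma]
    clf = SVC(kernel="precomputed", C=C)
    clf.fit(K[np.ix_(idx_tr, idx_tr)], y[idx_tr])
    pred = clf.predict(K[np.ix_(idx_te, idx_tr)])
    return float(np.mean(pred == y[idx_te]))


def _grid_search_k(Ks, y, idx, spec: ClassifierSpec) -> tuple[float, float, float]:
    """Grid search on precomputed kernels restricted to accessions ``idx``."""
    splits = _inner_splits(y[idx], spec.inner_folds, spec.seed)
    if splits is None:
        w = spec.widths[len(spec.widths) // 2]
        c = spec.regularizations[len(spec.regularizations) // 2]
        return w, c, float("nan")
    best = (-1.0, None, None)
    for C in sorted(spec.regularizations):
        for gamma in sorted(spec.widths):
            acc = np.mean([
                _kfold_accuracy_k(Ks, y, idx[tr], idx[te], gamma, C)
                for tr, te in splits])
            if acc > best[0] + 1e-12:
                best = (acc, gamma, C)
    return best[1], best[2], best[0]


def _inner_splits(y: np.ndarray, folds: int, seed: int):
    """Stratified inner folds, degrading gracefully for tiny classes."""
    counts = np.bincount(y.astype(int), minlength=2)
    k = min(folds, int(counts[counts > 0].min()))
    if k < 2:
        return None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def _grid_search(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> tuple[float, float, float]:
    """(width, regularization, inner accuracy) maximizing inner-CV accuracy."""
    splits = _inner_splits(y, spec.inner_folds, spec.seed)
    if splits is None:
        # too few labeled examples per class for inner CV: use grid midpoints
        w = spec.widths[len(spec.widths) // 2]
        c = spec.regularizations[len(spec.regularizations) // 2]
        return w, c, float("nan")
    best = (-1.0, None, None)
    for C in sorted(spec.regularizations):
        for gamma in sorted(spec.widths):
            acc = np.mean([_fold_accuracy(X, y, tr, te, gamma, C)
                           for tr, te in splits])
            if acc > best[0] + 1e-12:     # strict: first best = smallest C, width
                best = (acc, gamma, C)
    return best[1], best[2], best[0]


def train_classifier(window: FeatureWindow, labels: np.ndarray,
                     spec: ClassifierSpec | None = None) -> TrainedClassifier:
    """Grid-searched RBF-SVC refit on all labeled accessions."""
    spec = spec or ClassifierSpec()
    labels = np.asarray(labels)
    labeled = np.flatnonzero((labels == 0) | (labels == 1))
    y = labels[labeled].astype(int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise PleiomapError("need >= 2 labeled accessions per class")
    X = window.X[labeled]
    gamma, C, inner_acc = _grid_search(X, y, spec)
    model = SVC(kernel="rbf", gamma=gamma, C=C)
    model.fit(X, y)
    return TrainedClassifier(model=model, width=gamma, regularization=C,
                             inner_cv_accuracy=inner_acc, spec=spec)


def kfold_cv(window: FeatureWindow, labels: np.ndarray, k: int = 4,
             spec: ClassifierSpec | None = None, seed: int = 0) -> CVReport:
    """Stratified k-fold accuracy with grid search inside each training split."""
    spec = spec or ClassifierSpec()
    labels = np.asarray(labels)
    labeled = np.flatnonzero((labels == 0) | (labels == 1))
    X = window.X[labeled]
    y = labels[labeled].astype(int)
    if k < 2:
        raise PleiomapError("k must be >= 2")
    if min(np.bincount(y, minlength=2)) < k:
        raise PleiomapError("stratified folds infeasible: a class has < k members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    Ks = _precompute_kernels(X, spec.widths)
    accs = []
    for tr, te in skf.split(X, y):
        gamma, C, _ = _grid_search_k(Ks, y, tr, spec)
        accs.append(_kfold_accuracy_k(Ks, y, tr, te, gamma, C))
    return CVReport(protocol=f"{k}fold", fold_accuracies=accs,
                    mean_accuracy=float(np.mean(accs)),
                    n=y.size, repeats=1, seed=seed)


def subset_loocv(window: FeatureWindow, labels: np.ndarray, n: int,
                 repeats: int = 20, spec: ClassifierSpec | None = None,
                 seed: int = 0) -> CVReport:
    """Leave-one-out accuracy on random accession subsets of size n.

    Each repeat samples n labeled accessions without replacement
    (single-class draws are redrawn, up to 100 attempts) and runs n-fold
    (leave-one-out) cross-validation within the subset; the report
    averages accuracy over repeats.
    """
    spec = spec or ClassifierSpec()
    labels = np.asarray(labels)
    labeled = np.flatnonzero((labels == 0) | (labels == 1))
    if n > labeled.size:
        raise PleiomapError(f"n = {n} exceeds {labeled.size} labeled accessions")
    if n < 3:
        raise PleiomapError("n must be >= 3")
    X = window.X[labeled]
    y = labels[labeled].astype(int)
    rng = np.random.default_rng(seed)
    Ks = _precompute_kernels(X, spec.widths)
    accs = []
    for _ in range(repeats):
        for attempt in range(100):
            sub = rng.choice(labeled.size, size=n, replace=False)
            if len(np.unique(y[sub])) == 2:
                break
        else:
            raise PleiomapError("could not draw a two-class subset in 100 tries")
        if attempt:
            logger.info("redrew a single-class subset %d time(s)", attempt)
        hits = 0.0
        for i in range(n):
            tr = np.delete(sub, i)
            if len(np.unique(y[tr])) < 2:
                # training split lost a class: predict its only label
                hits += int(y[tr][0]) == y[sub[i]]
                continue
            gamma, C, _ = _grid_search_k(Ks, y, tr, spec)
            # 0/1 accuracy on the single held-out accession
            hits += _kfold_accuracy_k(Ks, y, tr, sub[i:i + 1], gamma, C)
        accs.append(hits / n)
    return CVReport(protocol="subset_loocv", fold_accuracies=accs,
                    mean_accuracy=float(np.mean(accs)),
                    n=n, repeats=repeats, seed=seed)


def impute_labels(trained: TrainedClassifier, window: FeatureWindow,
                  labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict functionality for unlabeled accessions.

    Returns (labels_out, margins): labeled accessions keep their observed
    labels (margin = nan); unlabeled ones get the model's binary
    prediction and decision-function margin.  Accessions whose window
    features were entirely missing before filling keep LABEL_UNKNOWN.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    margins = np.full(labels.size, np.nan)
    unlabeled = np.flatnonzero((labels != 0) & (labels != 1))
    # accessions with no window data at all stay unknown
    unlabeled = np.setdiff1d(unlabeled, window.all_missing_rows)
    out[np.intersect1d(window.all_missing_rows,
                       np.flatnonzero((labels != 0) & (labels != 1)))] = LABEL_UNKNOWN
    if unlabeled.size:
        X = window.X[unlabeled]
        pred = trained.model.predict(X).astype(int)
        marg = trained.model.decision_function(X)
        out[unlabeled] = pred
        margins[unlabeled] = marg
    return out, margins
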