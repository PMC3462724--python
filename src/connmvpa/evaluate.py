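"""Leave-one-out cross-validation, hyperparameter sweeps, permutation test.

Every fold re-ranks features on the N-1 training subjects only, selects
the top-k by |tau|, fits PCA (d components) and a linear SVM (cost C) on
the training rows, and scores the held-out subject — so feature
selection never sees the test subject. Per-fold classifier weights are
back-projected to the edge space and stored so the reconstruction stage
can average them.

Confusion-count convention: TP = patients correctly predicted,
TN = controls correctly predicted, FP = controls called patients,
FN = patients called controls. GR = (TP+TN)/N is overall accuracy,
SS = TP/(TP+FN) sensitivity, SC = TN/(TN+FP) specificity.

The permutation test permutes the full label vector and re-runs the
entire LOOCV — including per-fold feature selection — once per
permutation; p = (1 + #{GR* >= GR0}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from connmvpa.connectivity import FeatureDataset
from connmvpa.model import PcaModel, SvmModel, decision_score, fit_pca, fit_svm, project
from connmvpa.ranking import SelectionResult, rank_order, select_top_k, tau_vector
from connmvpa.reconstruct import fold_feature_weights


@dataclass
class Metrics:
    gr: float | None
    ss: float | None
    sc: float | None


@dataclass
class FoldRecord:
    subject_id: str
    selection: SelectionResult
    pca: PcaModel
    svm: SvmModel
    weights: np.ndarray          # length D, zeros off the selected features
    score: float
    predicted: int
    true: int


@dataclass
class CvResult:
    folds: list[FoldRecord]
    tp: int
    tn: int
    fp: int
    fn: int
    metrics: Metrics
    consensus: np.ndarray        # features selected in every fold
    union: np.ndarray            # features selected in at least one fold
    k: int
    d: int
    C: float

    @property
    def n_subjects(self) -> int:
        return len(self.folds)


@dataclass
class PermutationResult:
    gr_observed: float
    gr_permuted: np.ndarray
    n_perm: int
    p_value: float
    seed: int


def metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """GR/SS/SC from confusion counts; undefined denominators give None."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty confusion table")
    gr = (tp + tn) / n
    ss = tp / (tp + fn) if (tp + fn) > 0 else None
    sc = tn / (tn + fp) if (tn + fp) > 0 else None
    return Metrics(gr, ss, sc)


def _fit_fold(X_train: np.ndarray, y_train: np.ndarray, k: int, d: int,
              C: float) -> tuple[SelectionResult, PcaModel, SvmModel]:
    taus = tau_vector(X_train, y_train)
    selection = select_top_k(rank_order(taus.tau), k)
    X_sel = X_train[:, selection.indices]
    pca = fit_pca(X_sel, d)
    svm = fit_svm(project(pca, X_sel), y_train, C)
    return selection, pca, svm


def loocv(dataset: FeatureDataset, k: int, d: int, C: float,
          y_override: np.ndarray | None = None) -> CvResult:
    """Leave-one-out CV with training-only feature selection.

    ``y_override`` substitutes a (possibly permuted) label vector for
    both training and scoring; used by the permutation test.
    """
    y = dataset.y if y_override is None else np.asarray(y_override, dtype=int)
    X = dataset.X
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    folds: list[FoldRecord] = []
    tp = tn = fp = fn = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {i}: training set lost a class")
        selection, pca, svm = _fit_fold(X[mask], y_train, k, d, C)
        score, predicted = decision_score(pca, svm, X[i, selection.indices])
        weights = fold_feature_weights(pca, svm, selection, dataset.n_features)
        folds.append(FoldRecord(dataset.subject_ids[i], selection, pca, svm,
                                weights, score, predicted, int(y[i])))
        if y[i] == -1:
            tp += predicted == -1
            fn += predicted != -1
        else:
            tn += predicted == +1
            fp += predicted != +1
    sets = [set(f.selection.indices.tolist()) for f in folds]
    consensus = np.array(sorted(set.intersection(*sets)), dtype=int)
    union = np.array(sorted(set.union(*sets)), dtype=int)
    return CvResult(folds, tp, tn, fp, fn, metrics(tp, tn, fp, fn),
                    consensus, union, k, d, C)


def consensus_features(cv: CvResult) -> np.ndarray:
    """Features selected in every fold."""
    return cv.consensus.copy()


def union_features(cv: CvResult) -> np.ndarray:
    """Features selected in at least one fold."""
    return cv.union.copy()


def sweep_feature_number(dataset: FeatureDataset, k_grid: list[int],
                         d: int, C: float) -> pd.DataFrame:
    """One LOOCV per feature count k; returns (k, gr, ss, sc) rows.

    The best row is the highest GR, ties broken toward the smallest k.
    """
    rows = []
    for k in k_grid:
        cv = loocv(dataset, k, d, C)
        rows.append({"k": k, "gr": cv.metrics.gr, "ss": cv.metrics.ss,
                     "sc": cv.metrics.sc})
    table = pd.DataFrame(rows)
    best = table.sort_values(["gr", "k"], ascending=[False, True],
                             kind="mergesort").iloc[0]
    table.attrs["best_k"] = int(best["k"])
    table.attrs["best_gr"] = float(best["gr"])
    return table


def grid_select(dataset: FeatureDataset, k_grid: list[int], d_grid: list[int],
                c_grid: list[float]) -> tuple[tuple[int, int, float], float, pd.DataFrame]:
    """Exhaustive LOOCV over (k, d, C); best by GR, ties toward smallest."""
    rows = []
    for k in k_grid:
        for d in d_grid:
            for C in c_grid:
                cv = loocv(dataset, k, d, C)
                rows.append({"k": k, "d": d, "C": C, "gr": cv.metrics.gr})
    table = pd.DataFrame(rows)
    best = table.sort_values(["gr", "k", "d", "C"],
                             ascending=[False, True, True, True],
                             kind="mergesort").iloc[0]
    return (int(best["k"]), int(best["d"]), float(best["C"])), float(best["gr"]), table


def permutation_test(dataset: FeatureDataset, k: int, d: int, C: float,
                     n_perm: int, seed: int) -> PermutationResult:
    """Label-permutation null for the LOOCV generalization rate.

    Each permutation reshuffles the full label vector and re-runs the
    complete pipeline (feature selection, PCA, SVM, all folds).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gr0 = loocv(dataset, k, d, C).metrics.gr
    rng = np.random.default_rng(seed)
    gr_perm = np.empty(n_perm)
    for p in range(n_perm):
        y_perm = rng.permutation(dataset.y)
        gr_perm[p] = loocv(dataset, k, d, C, y_override=y_perm).metrics.gr
    p_value = (1 + int(np.sum(gr_perm >= gr0))) / (n_perm + 1)
    return PermutationResult(gr0, gr_perm, n_perm, p_value, seed)
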