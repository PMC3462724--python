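"""Cross-group Kendall-tau feature ranking.

For one feature, every patient-control sample pair (m x n pairs; within-
group pairs are not considered) is classified as concordant when the
sign of the feature difference matches the sign of the label difference,
discordant when opposite. With labels -1 = patient, +1 = control,

    tau = (n_c - n_d) / (m * n)

so tau > 0 means the feature tends to be *lower* in patients. Tied
feature values count in the denominator but as neither concordant nor
discordant. Features are ranked by |tau| descending (ties broken by
ascending edge index, for reproducible consensus sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from connmvpa.connectivity import FeatureDataset


@dataclass
class TauVector:
    """Per-feature cross-group tau with the group sizes used."""

    tau: np.ndarray
    n_patients: int
    n_controls: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.tau) > 1.0 + 1e-12):
            raise ValueError("tau out of [-1, 1]")


@dataclass
class SelectionResult:
    """Top-k feature indices, ordered by descending |tau|."""

    indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) != self.k:
            raise ValueError("selection length does not match k")
        if len(np.unique(self.indices)) != self.k:
            raise ValueError("selected indices are not unique")


def _split_groups(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    patients = X[y == -1]
    controls = X[y == +1]
    if len(patients) == 0 or len(controls) == 0:
        raise ValueError("both groups (-1 and +1) must be present")
    return patients, controls


def tau_vector(X: np.ndarray, y: np.ndarray) -> TauVector:
    """Cross-group tau for every column of X (vectorized over features)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    patients, controls = _split_groups(X, y)
    m, n = len(patients), len(controls)
    # pairwise differences control - patient: (n*m) x D
    diff = controls[:, None, :] - patients[None, :, :]
    # concordant: patient below control (sgn(x_p - x_c) = sgn(y_p - y_c) = -1)
    n_c = (diff > 0).sum(axis=(0, 1))
    n_d = (diff < 0).sum(axis=(0, 1))
    tau = (n_c - n_d) / float(m * n)
    return TauVector(tau, m, n)


def kendall_tau_cross_group(values: np.ndarray, labels: np.ndarray) -> float:
    """Cross-group tau of a single feature."""
    values = np.asarray(values, dtype=float)
    return float(tau_vector(values[:, None], labels).tau[0])


def rank_order(tau: np.ndarray) -> np.ndarray:
    """Feature ordering: |tau| descending, ties by ascending index."""
    tau = np.asarray(tau, dtype=float)
    return np.lexsort((np.arange(len(tau)), -np.abs(tau)))


def rank_features(dataset: FeatureDataset | None = None, *,
                  X: np.ndarray | None = None,
                  y: np.ndarray | None = None) -> tuple[TauVector, np.ndarray]:
    """Tau per feature plus the ranking order, from a dataset or raw arrays."""
    if dataset is not None:
        X, y = dataset.X, dataset.y
    if X is None or y is None:
        raise ValueError("provide either a dataset or both X and y")
    taus = tau_vector(X, y)
    return taus, rank_order(taus.tau)


def select_top_k(order: np.ndarray, k: int) -> SelectionResult:
    """First k features of a ranking order."""
    order = np.asarray(order, dtype=int)
    if not 1 <= k <= len(order):
        raise ValueError(f"k={k} out of range [1, {len(order)}]")
    return SelectionResult(order[:k].copy(), k)
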