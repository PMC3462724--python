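"""Edge-feature construction: correlation, Fisher z, upper-triangle vectorization.

Each subject's cleaned T x R series becomes an R x R Pearson correlation
matrix; the strictly-upper triangle (row-major, 0-based) is Fisher
z-transformed and flattened into a length R(R-1)/2 feature vector. For
the standard 90-region parcellation this gives 4005 edge features. The
edge ordering is fixed package-wide so feature indices are comparable
across folds, files and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from connmvpa.preprocess import ConfoundSet, PreprocessConfig, preprocess_series
from connmvpa.synth import Cohort

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between edge index k and region pair (i, j), i < j.

    Ordering is row-major over the strictly upper triangle:
    (0,1), (0,2), ..., (0,R-1), (1,2), ... — the canonical serialization
    used everywhere in this package.
    """

    n_regions: int

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def rows(self) -> np.ndarray:
        return np.triu_indices(self.n_regions, k=1)[0]

    @property
    def cols(self) -> np.ndarray:
        return np.triu_indices(self.n_regions, k=1)[1]

    def edge_index(self, i: int, j: int) -> int:
        if not 0 <= i < j < self.n_regions:
            raise ValueError(f"need 0 <= i < j < {self.n_regions}, got ({i}, {j})")
        # offset of row i plus position within the row
        r = self.n_regions
        return i * r - i * (i + 1) // 2 + (j - i - 1)

    def region_pair(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.n_edges:
            raise ValueError(f"edge index {k} out of range [0, {self.n_edges})")
        return int(self.rows[k]), int(self.cols[k])

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass
class ConnectivityProfile:
    """One subject's Fisher-z edge-feature vector."""

    subject_id: str
    group: int
    features: np.ndarray
    edge_map: EdgeIndexMap

    def __post_init__(self) -> None:
        if self.features.shape != (self.edge_map.n_edges,):
            raise ValueError("feature vector length does not match edge map")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"subject {self.subject_id}: non-finite features")


@dataclass
class FeatureDataset:
    """N x D feature matrix with labels, edge map and region names."""

    X: np.ndarray
    y: np.ndarray
    edge_map: EdgeIndexMap
    region_labels: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.y), self.edge_map.n_edges):
            raise ValueError("X shape does not match labels / edge map")
        if not self.subject_ids:
            self.subject_ids = [f"sub_{i:03d}" for i in range(len(self.y))]
        if set(np.unique(self.y)) - {-1, 1}:
            raise ValueError("labels must be -1 (patient) or +1 (control)")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def correlation_matrix(series: np.ndarray, region_labels: list[str] | None = None) -> np.ndarray:
    """Pearson correlation between all region pairs of a T x R series."""
    series = np.asarray(series, dtype=float)
    t, r = series.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    sd = series.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ([region_labels[i] for i in dead] if region_labels
                 else dead.tolist())
        raise ValueError(f"zero-variance region(s): {names}")
    corr = np.corrcoef(series, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing arctanh of a correlation, clipped near +/-1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(out) if np.isscalar(r) else out


def vectorize_upper(matrix: np.ndarray, edge_map: EdgeIndexMap) -> np.ndarray:
    """Flatten the strictly upper triangle in the map's canonical order."""
    matrix = np.asarray(matrix, dtype=float)
    r = edge_map.n_regions
    if matrix.shape != (r, r):
        raise ValueError(f"matrix is {matrix.shape}, edge map expects ({r}, {r})")
    return matrix[edge_map.rows, edge_map.cols].copy()


def devectorize_upper(vector: np.ndarray, edge_map: EdgeIndexMap,
                      diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; fills a symmetric matrix."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (edge_map.n_edges,):
        raise ValueError(f"vector length {vector.shape} does not match edge map")
    r = edge_map.n_regions
    out = np.full((r, r), diagonal, dtype=float)
    out[edge_map.rows, edge_map.cols] = vector
    out[edge_map.cols, edge_map.rows] = vector
    return out


def connectivity_profile(subject_series: np.ndarray, subject_id: str, group: int,
                         edge_map: EdgeIndexMap,
                         region_labels: list[str] | None = None) -> ConnectivityProfile:
    corr = correlation_matrix(subject_series, region_labels)
    feats = fisher_z(vectorize_upper(corr, edge_map))
    return ConnectivityProfile(subject_id, group, feats, edge_map)


def build_dataset(cohort: Cohort, config: PreprocessConfig | None = None,
                  confounds: dict[str, ConfoundSet] | None = None) -> FeatureDataset:
    """Preprocess every subject and assemble the N x D feature dataset."""
    edge_map = EdgeIndexMap(cohort.n_regions)
    rows, labels, ids = [], [], []
    for subject in cohort.subjects:
        conf = (confounds or {}).get(subject.subject_id)
        clean = preprocess_series(subject.series, cohort.tr_seconds, config, conf)
        profile = connectivity_profile(clean, subject.subject_id, subject.group,
                                       edge_map, cohort.region_labels)
        rows.append(profile.features)
        labels.append(subject.group)
        ids.append(subject.subject_id)
    return FeatureDataset(np.vstack(rows), np.array(labels), edge_map,
                          list(cohort.region_labels), ids)
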