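"""Back-projection of classifier weights to edges and regions.

Because the trained classifier is linear end-to-end, its discriminant
can be rewritten directly on the selected edge features:

    Y = w^T U^T (x - x_bar) - b = (U w)^T (x - x_bar) - b,

so Lambda = U w assigns each selected feature a signed weight whose
magnitude is its contribution to the discriminative score. Per-fold
Lambda vectors are embedded into the full D-length edge space (zeros at
unselected features), their absolute values averaged over folds, and
each edge's averaged weight split half-and-half between its two incident
regions — so the region weights conserve the total feature weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from connmvpa.connectivity import EdgeIndexMap, FeatureDataset
from connmvpa.model import PcaModel, SvmModel
from connmvpa.ranking import SelectionResult, tau_vector


def fold_feature_weights(pca: PcaModel, svm: SvmModel,
                         selection: SelectionResult | np.ndarray,
                         n_features: int) -> np.ndarray:
    """Lambda = U w scattered to the fold's selected positions, zeros elsewhere."""
    indices = selection.indices if isinstance(selection, SelectionResult) else np.asarray(selection, dtype=int)
    if svm.w.shape[0] != pca.n_components:
        raise ValueError("SVM weight length does not match PCA dimension")
    lam = pca.components @ svm.w
    if lam.shape[0] != len(indices):
        raise ValueError(f"{lam.shape[0]} selected-space weights for "
                         f"{len(indices)} selected features")
    out = np.zeros(n_features)
    out[indices] = lam
    return out


def average_weights(fold_vectors: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Elementwise mean of |Lambda_i| over all folds."""
    arr = np.asarray(fold_vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValueError("no fold weight vectors to average")
    return np.abs(arr).mean(axis=0)


def region_weights(lambda_bar: np.ndarray, edge_map: EdgeIndexMap,
                   region_labels: list[str]) -> pd.DataFrame:
    """Half of each incident edge's weight, summed per region.

    The returned table (region, weight, rank) conserves the total:
    sum of region weights == sum of lambda_bar.
    """
    lambda_bar = np.asarray(lambda_bar, dtype=float)
    if lambda_bar.shape != (edge_map.n_edges,):
        raise ValueError("weight vector length does not match edge map")
    if len(region_labels) != edge_map.n_regions:
        raise ValueError("region label count does not match edge map")
    weights = np.zeros(edge_map.n_regions)
    np.add.at(weights, edge_map.rows, 0.5 * lambda_bar)
    np.add.at(weights, edge_map.cols, 0.5 * lambda_bar)
    table = pd.DataFrame({"region": region_labels, "weight": weights})
    table["rank"] = table["weight"].rank(ascending=False, method="min").astype(int)
    return table.sort_values(["weight", "region"], ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)


def edge_report(dataset: FeatureDataset, lambda_bar: np.ndarray,
                feature_set: np.ndarray | list[int]) -> pd.DataFrame:
    """Per-edge table: region pair, full-data tau, weight, direction.

    Tau is recomputed on all subjects; direction is "decreased" for
    tau > 0 (feature lower in patients under the -1/+1 label convention)
    and "increased" otherwise. Rows are the requested feature set
    (typically the consensus set), sorted by weight descending with ties
    by edge index.
    """
    feats = np.asarray(sorted(set(int(f) for f in feature_set)), dtype=int)
    lambda_bar = np.asarray(lambda_bar, dtype=float)
    taus = tau_vector(dataset.X[:, feats], dataset.y).tau
    emap = dataset.edge_map
    rows = []
    for f, tau in zip(feats, taus):
        i, j = emap.region_pair(int(f))
        rows.append({
            "edge_index": int(f),
            "region_a": dataset.region_labels[i],
            "region_b": dataset.region_labels[j],
            "tau": float(tau),
            "weight": float(lambda_bar[f]),
            "direction": "decreased" if tau > 0 else "increased",
        })
    table = pd.DataFrame(rows, columns=["edge_index", "region_a", "region_b",
                                        "tau", "weight", "direction"])
    return table.sort_values(["weight", "edge_index"], ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)
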