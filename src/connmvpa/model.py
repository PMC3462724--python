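"""PCA subspace + soft-margin linear SVM classifier.

The feature vector (after selection) is centered on the training mean
and projected onto the top-d eigenvectors of the training covariance,

    x_tilde = U^T (x - x_bar),

then scored by a linear SVM decision function Y = w^T x_tilde - b;
Y > 0 predicts control (+1), otherwise patient (-1). The composition
collapses to a single linear functional on the original features,
Y = (U w)^T (x - x_bar) - b, which is the identity the reconstruction
module relies on.

The SVM is scikit-learn's libsvm-based solver (deterministic, exact
convex optimum), wrapped so the stored (w, b) follow the Y = w.x - b
sign convention. PCA is an explicit eigendecomposition with a fixed
component-sign convention so back-projected weights are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class PcaModel:
    mean: np.ndarray          # training column means, length k
    components: np.ndarray    # k x d, orthonormal columns
    eigenvalues: np.ndarray   # length d, descending

    def __post_init__(self) -> None:
        k, d = self.components.shape
        if self.mean.shape != (k,) or self.eigenvalues.shape != (d,):
            raise ValueError("inconsistent PCA model shapes")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class SvmModel:
    w: np.ndarray
    b: float
    C: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.b)):
            raise ValueError("non-finite SVM parameters")


def fit_pca(X: np.ndarray, d: int) -> PcaModel:
    """Top-d principal components of the training matrix (rows = samples).

    Eigenvalues are those of the sample covariance (1/(n-1)). d is capped
    at min(n_features, n_samples - 1) with a warning. Each component's
    sign is fixed so its largest-magnitude entry is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if d < 1:
        raise ValueError("d must be >= 1")
    cap = min(k, n - 1)
    if d > cap:
        logger.warning("requested d=%d exceeds rank bound %d; capping", d, cap)
        d = cap
    mean = X.mean(axis=0)
    centered = X - mean
    if not centered.any():
        raise ValueError("degenerate training matrix: zero variance everywhere")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = (s ** 2) / (n - 1)
    components = vt[:d].T.copy()
    # sign convention: largest-|entry| of each component is positive
    for c in range(d):
        col = components[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            components[:, c] = -col
    return PcaModel(mean, components, eigenvalues[:d].copy())


def project(pca: PcaModel, x: np.ndarray) -> np.ndarray:
    """U^T (x - x_bar); accepts a vector or a matrix of row vectors."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != pca.mean.shape[0]:
        raise ValueError(f"input length {x.shape[-1]} does not match model "
                         f"({pca.mean.shape[0]})")
    return (x - pca.mean) @ pca.components


def fit_svm(X_reduced: np.ndarray, y: np.ndarray, C: float) -> SvmModel:
    """Soft-margin linear SVM on reduced coordinates; convention Y = w.x - b."""
    X_reduced = np.atleast_2d(np.asarray(X_reduced, dtype=float))
    y = np.asarray(y, dtype=int)
    if C <= 0:
        raise ValueError("C must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="linear", C=C, tol=1e-8)  # tight tol: symmetric, reproducible optimum
    clf.fit(X_reduced, y)
    w = clf.coef_[0].copy()
    b = -float(clf.intercept_[0])  # decision_function = w.x + intercept = w.x - b
    return SvmModel(w, b, float(C))


def decision_score(pca: PcaModel, svm: SvmModel, x: np.ndarray) -> tuple[float, int]:
    """Discriminant Y = w^T U^T (x - x_bar) - b and the predicted label.

    Y > 0 -> control (+1); Y <= 0 -> patient (-1). Exactly Y = 0 is
    assigned to the patient class for determinism.
    """
    if svm.w.shape[0] != pca.n_components:
        raise ValueError("SVM weight length does not match PCA dimension")
    y_score = float(svm.w @ project(pca, np.asarray(x, dtype=float))) - svm.b
    return y_score, (1 if y_score > 0 else -1)


def to_json(pca: PcaModel, svm: SvmModel,
            selected: np.ndarray | None = None) -> str:
    """Serialize a fold's models (and selected feature indices) to JSON."""
    payload = {
        "mean": pca.mean.tolist(),
        "components": pca.components.tolist(),
        "eigenvalues": pca.eigenvalues.tolist(),
        "w": svm.w.tolist(),
        "b": svm.b,
        "C": svm.C,
        "selected_features": None if selected is None else np.asarray(selected).tolist(),
    }
    return json.dumps(payload)


def from_json(text: str) -> tuple[PcaModel, SvmModel, np.ndarray | None]:
    obj = json.loads(text)
    pca = PcaModel(np.array(obj["mean"]), np.array(obj["components"]),
                   np.array(obj["eigenvalues"]))
    svm = SvmModel(np.array(obj["w"]), float(obj["b"]), float(obj["C"]))
    sel = None if obj["selected_features"] is None else np.array(obj["selected_features"], dtype=int)
    return pca, svm, sel
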