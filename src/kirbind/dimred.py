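"""PCA and MCA projections of the one-hot panel matrix.

Both methods are exposed through a single :class:`ProjectionModel` whose
``project`` maps new rows to K coordinates: PCA centers the raw indicator
matrix, MCA converts rows to profiles and uses the correspondence-analysis
column geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ProjectionModel:
    method: str  # "pca" | "mca"
    K: int
    center: np.ndarray  # per-feature offsets (PCA: means; MCA: column masses)
    components: np.ndarray  # K x n_features direction vectors
    explained: np.ndarray  # per-component variance / inertia shares
    feature_labels: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.components.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "K": self.K,
                "center": self.center.tolist(),
                "components": self.components.tolist(),
                "explained": self.explained.tolist(),
                "feature_labels": [[int(p), r] for p, r in self.feature_labels],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProjectionModel":
        d = json.loads(text)
        return cls(
            method=d["method"],
            K=int(d["K"]),
            center=np.asarray(d["center"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained=np.asarray(d["explained"], dtype=float),
            feature_labels=[(int(p), r) for p, r in d["feature_labels"]],
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def fit_pca(X: np.ndarray, K: int = 7, feature_labels=None) -> ProjectionModel:
    """Mean-centered PCA via SVD; keeps the top-K components.

    K above the rank of the centered matrix is clipped with a warning.
    Indicator columns are centered but not scaled.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if K < 1:
        raise ValueError("K must be >= 1")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if K > rank:
        warnings.warn(f"K={K} exceeds rank {rank}; clipping", stacklevel=2)
        K = max(rank, 1)
    eigvals = s**2 / (X.shape[0] - 1)
    total = eigvals.sum()
    explained = eigvals[:K] / total if total > 0 else np.zeros(K)
    components = _fix_signs(Vt[:K])
    return ProjectionModel(
        method="pca",
        K=K,
        center=center,
        components=components,
        explained=explained,
        feature_labels=list(feature_labels or []),
    )


def fit_mca(X: np.ndarray, K: int = 7, feature_labels=None) -> ProjectionModel:
    """Correspondence analysis of the indicator matrix.

    SVD of the standardized residuals with row/column mass weighting; the
    stored geometry maps a new row's profile to principal coordinates.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if np.any(X.sum(axis=0) == 0):
        raise ValueError("empty categories (all-zero columns) are not allowed")
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("all-zero rows cannot be given a profile")
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if K > rank:
        warnings.warn(f"K={K} exceeds CA rank {rank}; clipping", stacklevel=2)
        K = max(rank, 1)
    inertia = s**2
    explained = inertia[:K] / inertia.sum() if inertia.sum() > 0 else np.zeros(K)
    # rows of `components`: D_c^{-1/2} V, so that a centered row profile
    # mapped through them lands on principal coordinates
    components = _fix_signs((Vt[:K] / np.sqrt(c)))
    return ProjectionModel(
        method="mca",
        K=K,
        center=c.copy(),
        components=components,
        explained=explained,
        feature_labels=list(feature_labels or []),
    )


def project(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the model's K axes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: {X.shape[1]} columns vs model's {model.n_features}"
        )
    if model.method == "mca":
        sums = X.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("cannot project an all-zero row with MCA")
        X = X / sums
    return (X - model.center) @ model.components.T
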