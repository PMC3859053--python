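"""Kernel discriminant analysis for position-invariant activity features.

The same activity produces very different accelerometer output depending on
where the phone is carried (front pocket, back pocket, jacket pocket ...),
inflating within-class variance of the AR-coefficient features. KDA seeks
nonlinear discriminant directions in the RBF-kernel-induced feature space:
with kernel matrix K (K_ij = exp(-gamma ||x_i - x_j||^2)) and the
class-indicator matrix W (W_ij = 1/m_k when samples i, j share class k),
the discriminant coefficients alpha maximize

    J(alpha) = (alpha^T K W K alpha) / (alpha^T K K alpha)

and are the leading eigenvectors of the generalized eigenproblem

    K W K alpha = lambda (K K + eps I) alpha,

where the small ridge eps handles the rank deficiency of K K. The kernel
matrix is double-centered first (K <- H K H with H = I - 11^T/m), the
standard kernel-Fisher practice: without centering the criterion's leading
direction degenerates onto the constant component of feature space (all
RBF kernel entries are positive, so phi has a large mean) instead of the
separating one. A query x is projected onto a discriminant direction as
alpha^T k_c(x), where k_c is the consistently centered kernel column
[K(x_1,x)..K(x_m,x)]^T. At most C - 1 informative directions exist for C
classes.

Each alpha is scaled so the corresponding direction has unit norm in
feature space (alpha^T K alpha = 1); this makes projections invariant to
duplicating the training set, which Euclidean normalization of alpha is
not. Signs are fixed by making the first non-negligible entry positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist, pdist

from .ar_model import FeatureVector
from .exceptions import NumericalError, ParameterError


@dataclass
class KDAModel:
    """Fitted KDA projection.

    ``training_vectors`` are stored standardized (``feature_mean`` /
    ``feature_scale`` hold the z-score statistics applied before kernel
    evaluation); ``alpha`` is m x d with columns ordered by descending
    eigenvalue.
    """

    training_vectors: np.ndarray
    labels: np.ndarray
    gamma: float
    alpha: np.ndarray
    eigenvalues: np.ndarray
    n_components: int
    eps: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    #: per-training-point kernel row means and grand mean, used to center
    #: query kernel columns consistently with the training kernel
    kernel_row_mean: np.ndarray | None = None
    kernel_grand_mean: float = 0.0


def rbf_kernel(xi, xj, gamma: float) -> float:
    """Radial basis function kernel ``exp(-gamma * ||xi - xj||^2)``."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ParameterError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    if not gamma > 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    diff = xi - xj
    return float(np.exp(-gamma * np.dot(diff, diff)))


def _rbf_matrix(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(a, b, metric="sqeuclidean"))


def class_indicator_matrix(labels) -> np.ndarray:
    """W with W_ij = 1/m_k when samples i and j share class k, else 0."""
    labels = np.asarray(labels)
    m = labels.shape[0]
    if m == 0:
        raise ParameterError("label list is empty")
    w = np.zeros((m, m))
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        w[np.ix_(idx, idx)] = 1.0 / idx.size
    return w


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        x = features
    else:
        rows = [
            f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=float)
            for f in features
        ]
        x = np.vstack(rows)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"feature matrix must be 2-D, got shape {x.shape}")
    return x


def median_heuristic_gamma(x: np.ndarray) -> float:
    """``gamma = 1 / (2 * median^2)`` of pairwise training distances."""
    med = float(np.median(pdist(x)))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med * med)


def fit_kda(
    features,
    labels,
    gamma: float | None = None,
    n_components: int | None = None,
    eps: float | None = None,
    standardize: bool = True,
) -> KDAModel:
    """Fit the KDA projection on labeled feature vectors.

    ``gamma=None`` applies the median heuristic on the (standardized)
    training vectors; ``n_components=None`` retains C - 1 directions;
    ``eps=None`` sets the ridge to ``1e-6 * trace(KK) / m``.
    """
    x = _as_matrix(features)
    labels = np.asarray(labels)
    m = x.shape[0]
    if labels.shape[0] != m:
        raise ParameterError(f"{m} feature vectors but {labels.shape[0]} labels")
    classes = np.unique(labels)
    n_classes = classes.shape[0]
    if n_classes < 2:
        raise ParameterError(f"need at least 2 classes, got {n_classes}")
    if m < n_classes:
        raise ParameterError("fewer samples than classes")

    if standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0.0] = 1.0
    else:
        mean = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    xs = (x - mean) / scale

    if gamma is None:
        gamma = median_heuristic_gamma(xs)
    if not gamma > 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")

    k_raw = _rbf_matrix(xs, xs, gamma)
    row_mean = k_raw.mean(axis=1)
    grand_mean = float(k_raw.mean())
    # double centering: K <- H K H removes the feature-space mean component
    k = k_raw - row_mean[:, None] - row_mean[None, :] + grand_mean
    w = class_indicator_matrix(labels)
    kwk = k @ w @ k
    kk = k @ k
    if eps is None:
        eps = 1e-6 * float(np.trace(kk)) / m
    b = kk + eps * np.eye(m)

    try:
        eigvals, eigvecs = scipy.linalg.eigh(kwk, b)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"generalized eigensolve failed: {exc}") from exc

    order = np.argsort(eigvals)[::-1]
    d_max = n_classes - 1
    d = d_max if n_components is None else min(int(n_components), d_max)
    if d < 1:
        raise ParameterError(f"n_components must be >= 1, got {n_components}")
    idx = order[:d]
    vals = eigvals[idx]
    vecs = eigvecs[:, idx].copy()

    # feature-space unit norm (alpha^T K alpha = 1) + deterministic sign
    for j in range(d):
        a = vecs[:, j]
        norm2 = float(a @ k @ a)
        if norm2 > 0:
            a = a / np.sqrt(norm2)
        else:  # numerically null direction: fall back to Euclidean norm
            a = a / np.linalg.norm(a)
        nz = np.flatnonzero(np.abs(a) > 1e-10 * np.abs(a).max())
        if nz.size and a[nz[0]] < 0:
            a = -a
        vecs[:, j] = a

    return KDAModel(
        training_vectors=xs,
        labels=labels,
        gamma=float(gamma),
        alpha=vecs,
        eigenvalues=vals,
        n_components=d,
        eps=float(eps),
        feature_mean=mean,
        feature_scale=scale,
        kernel_row_mean=row_mean,
        kernel_grand_mean=grand_mean,
    )


def project(model: KDAModel, x) -> np.ndarray:
    """Project one vector (1-D) or a batch (2-D) onto the KDA directions.

    Component j of a query's projection is ``alpha_j^T k_c(x)`` with the
    query kernel column centered by the training statistics.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.training_vectors.shape[1]:
        raise ParameterError(
            f"query dimension {x.shape[1]} != training dimension "
            f"{model.training_vectors.shape[1]}"
        )
    xs = (x - model.feature_mean) / model.feature_scale
    kvec = _rbf_matrix(xs, model.training_vectors, model.gamma)
    if model.kernel_row_mean is not None:
        kvec = (
            kvec
            - kvec.mean(axis=1, keepdims=True)
            - model.kernel_row_mean[None, :]
            + model.kernel_grand_mean
        )
    out = kvec @ model.alpha
    return out[0] if single else out
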