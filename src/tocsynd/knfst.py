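"""Kernel Null Foley–Sammon Transform (KNFST) for open-set classification.

The null-space Foley–Sammon discriminant seeks projection directions
``w`` in the kernel feature space that satisfy

    w' Sw w = 0   and   w' Sb w > 0,

where ``Sw`` and ``Sb`` are the within-class and between-class scatter
operators of the training data.  In such a direction every training
class collapses to a single point — its *target* — while different
classes map to different targets.  A test point is projected into the
null space and classified by the Euclidean distance to the nearest
target; that minimum distance doubles as a novelty score: a sample from
a class never seen in training has no target to be close to, so a large
minimum distance flags it as novel.

Everything is computed through the kernel matrix:

1. center the training kernel matrix and eigendecompose it, keeping
   eigenvalues above a relative cutoff — an orthonormal basis of the
   span of the (centered) training features;
2. inside that basis, form the within- and between-class scatters and
   solve the Foley–Sammon ratio problem ``Sb v = lambda (Sw + eps I) v``
   with a small ridge ``eps``, keeping the top C - 1 directions.

When the within-class scatter has a genuine null space that carries
between-class variance (always the case for small exact-rank problems),
the ratio problem returns exactly that null space — the two defining
conditions hold to machine precision.  For large training sets whose
kernel spectrum decays below double precision the exact null space is
not numerically representable; the ridge then yields the best
Fisher-discriminant approximation, and the realized (small, nonzero)
within-class spread is recorded on the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.linalg
from sklearn.metrics.pairwise import euclidean_distances

from .synthetic_data import Dataset

__all__ = [
    "KernelConfig",
    "KNFSTModel",
    "kernel_matrix",
    "fit_knfst",
    "knfst_distances",
]

#: relative eigenvalue cutoff used when building the kernel span basis
BASIS_EIGENVALUE_CUTOFF = 1e-10

#: relative ridge added to the within-class scatter in the ratio problem
NULL_SPACE_RIDGE = 1e-6

#: relative cutoff below which a between-class eigenvalue counts as zero
BETWEEN_CUTOFF = 1e-12


@dataclass
class KernelConfig:
    """Kernel family and parameters.

    bandwidth
        RBF width sigma in feature units (Hz);
        ``k(x, y) = exp(-||x - y||^2 / (2 sigma^2))``.  Two heuristics
        are accepted: ``"median-within"`` (default) resolves to the
        median pairwise distance *within* training classes — the scale
        the projection has to resolve — and ``"median"`` to the global
        median pairwise distance.
    degree, coef0
        Polynomial kernel parameters, ``k(x, y) = (x.y + coef0)^degree``.
    standardize
        Standardize features to zero mean / unit variance before the
        kernel.  Off by default: both axes are already in Hz.
    ridge
        Relative ridge ``eps`` on the within-class scatter (times
        ``tr(Sw)/r``); the null-space tolerance of the fit.
    """

    family: str = "rbf"
    bandwidth: Union[str, float] = "median-within"
    degree: int = 3
    coef0: float = 1.0
    standardize: bool = False
    ridge: float = NULL_SPACE_RIDGE

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "polynomial", "linear"):
            raise ValueError("kernel family must be rbf, polynomial or linear")
        if isinstance(self.bandwidth, str):
            if self.bandwidth not in ("median", "median-within"):
                raise ValueError(
                    "bandwidth must be a number, 'median' or 'median-within'"
                )
        elif self.bandwidth <= 0:
            raise ValueError("rbf bandwidth must be positive")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.ridge <= 0:
            raise ValueError("ridge must be positive")


def _median_pairwise(X: np.ndarray) -> np.ndarray:
    d = euclidean_distances(X)
    return d[np.triu_indices_from(d, k=1)]


def _resolve_bandwidth(X: np.ndarray, labels: np.ndarray, rule: str) -> float:
    if rule == "median":
        off = _median_pairwise(X)
    else:  # median-within
        chunks = [
            _median_pairwise(X[labels == c]) for c in np.unique(labels)
        ]
        off = np.concatenate([c for c in chunks if c.size]) if chunks else np.array([])
        if off.size == 0:  # all-singleton classes: fall back to global
            off = _median_pairwise(X)
    med = float(np.median(off)) if off.size else 1.0
    return med if med > 0 else 1.0


def kernel_matrix(
    X: np.ndarray,
    Y: np.ndarray,
    config: KernelConfig,
    bandwidth: Optional[float] = None,
) -> np.ndarray:
    """Evaluate the kernel between the rows of ``X`` and ``Y``.

    ``bandwidth`` overrides the config (fitted models pass the resolved
    heuristic value).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature dimensionality mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    if config.family == "linear":
        return X @ Y.T
    if config.family == "polynomial":
        return (X @ Y.T + config.coef0) ** config.degree
    sigma = bandwidth
    if sigma is None:
        if isinstance(config.bandwidth, str):
            raise ValueError(
                "rbf bandwidth is unresolved; fitting resolves the heuristic"
            )
        sigma = float(config.bandwidth)
    sq = euclidean_distances(X, Y, squared=True)
    return np.exp(-sq / (2.0 * sigma**2))


@dataclass
class KNFSTModel:
    """Fitted KNFST state.

    ``projection`` maps a centered kernel vector (against the training
    set) to null-space coordinates; ``targets[c]`` is the collapsed
    image of class ``classes[c]``.  ``train_spread`` records the largest
    distance of a projected training instance to its class target,
    relative scale being ``target_scale`` (the median inter-target
    distance): for an exactly collapsible problem
    ``train_spread / target_scale`` is at machine-noise level.
    """

    X_train: np.ndarray
    classes: list[str]
    config: KernelConfig
    bandwidth: Optional[float]
    projection: np.ndarray  # (n_train, n_dims)
    targets: np.ndarray  # (C, n_dims)
    k_row_means: np.ndarray
    k_total_mean: float
    scale_mean: np.ndarray
    scale_std: np.ndarray
    train_spread: float = 0.0
    target_scale: float = 1.0

    @property
    def n_dims(self) -> int:
        return self.projection.shape[1]

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.scale_mean) / self.scale_std

    def project(self, X: np.ndarray) -> np.ndarray:
        """Null-space coordinates of the rows of ``X``."""
        k = kernel_matrix(
            self._scale(X), self._scale(self.X_train), self.config,
            bandwidth=self.bandwidth,
        )
        kc = (
            k
            - k.mean(axis=1, keepdims=True)
            - self.k_row_means[None, :]
            + self.k_total_mean
        )
        return kc @ self.projection

    def distances(self, X: np.ndarray) -> np.ndarray:
        """(n, C) matrix of Euclidean distances to the class targets."""
        return euclidean_distances(self.project(X), self.targets)

    def score_samples(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(novelty scores, predicted labels) for the rows of ``X``.

        The novelty score is the minimum distance to a class target
        (larger = more novel); prediction is the nearest target, ties
        broken toward the lowest class index (``argmin`` returns the
        first minimum).
        """
        d = self.distances(X)
        idx = np.argmin(d, axis=1)
        scores = d[np.arange(len(d)), idx]
        labels = np.array([self.classes[i] for i in idx], dtype=object)
        return scores, labels


def fit_knfst(train: Dataset, config: KernelConfig = KernelConfig()) -> KNFSTModel:
    """Fit the null-space projection and class targets.

    Raises
    ------
    ValueError
        For a single-class training set (the null-space conditions need
        at least two classes), or when classes are degenerate: two
        targets coincide because no direction separates them.
    """
    X = np.asarray(train.features, dtype=float)
    labels = np.asarray(train.labels, dtype=object)
    classes = sorted(set(labels))
    C = len(classes)
    if C < 2:
        raise ValueError(
            "KNFST requires at least 2 training classes: the null-space "
            "conditions (zero within-class, positive between-class scatter) "
            "are unsatisfiable for a single class"
        )
    if config.standardize:
        mean, std = X.mean(axis=0), X.std(axis=0)
        std[std == 0] = 1.0
    else:
        mean, std = np.zeros(X.shape[1]), np.ones(X.shape[1])
    Xs = (X - mean) / std

    bandwidth: Optional[float] = None
    if config.family == "rbf":
        bandwidth = (
            _resolve_bandwidth(Xs, labels, config.bandwidth)
            if isinstance(config.bandwidth, str)
            else float(config.bandwidth)
        )

    K = kernel_matrix(Xs, Xs, config, bandwidth=bandwidth)
    row_means = K.mean(axis=1)
    total_mean = float(K.mean())
    Kc = K - row_means[:, None] - row_means[None, :] + total_mean

    # orthonormal basis of the span of the centered training features
    lam, V = scipy.linalg.eigh(Kc)
    keep = lam > BASIS_EIGENVALUE_CUTOFF * max(lam[-1], 0.0)
    if not np.any(keep):
        raise ValueError("kernel matrix has no significant spectrum; degenerate data")
    lam, V = lam[keep], V[:, keep]
    Z = V * np.sqrt(lam)  # (n, r) basis coordinates of the training points
    r = Z.shape[1]

    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in labels])
    means = np.stack([Z[y == i].mean(axis=0) for i in range(C)])
    D = Z - means[y]
    Sw = D.T @ D
    mu_c = means - means.mean(axis=0)
    Sb = mu_c.T @ mu_c

    # Foley–Sammon ratio problem; the ridge sets the null-space tolerance
    tr_sw = float(np.trace(Sw))
    eps = config.ridge * (tr_sw / r if tr_sw > 0 else 1.0)
    b_lam, b_V = scipy.linalg.eigh(Sb, Sw + eps * np.eye(r))
    pos = b_lam > BETWEEN_CUTOFF * max(b_lam[-1], 1e-300)
    n_dims = min(C - 1, int(np.sum(pos)))
    if n_dims == 0:
        raise ValueError("no direction carries between-class scatter")
    W = b_V[:, -n_dims:]

    projection = (V / np.sqrt(lam)) @ W  # maps centered kernel vectors
    targets = means @ W

    t_dist = euclidean_distances(targets)
    np.fill_diagonal(t_dist, np.inf)
    finite = t_dist[np.isfinite(t_dist)]
    target_scale = float(np.median(finite)) if finite.size else 1.0
    close = np.argwhere(np.triu(t_dist <= 1e-8 * target_scale, k=1))
    if len(close):
        pairs = ", ".join(f"{classes[i]}/{classes[j]}" for i, j in close[:5])
        raise ValueError(
            f"degenerate classes collapse to the same target: {pairs}"
        )

    proj_train = Z @ W
    spread = float(np.max(np.linalg.norm(proj_train - targets[y], axis=1)))

    return KNFSTModel(
        X_train=X,
        classes=classes,
        config=config,
        bandwidth=bandwidth,
        projection=projection,
        targets=targets,
        k_row_means=row_means,
        k_total_mean=total_mean,
        scale_mean=mean,
        scale_std=std,
        train_spread=spread,
        target_scale=target_scale,
    )


def knfst_distances(model: KNFSTModel, x: np.ndarray) -> np.ndarray:
    """Per-class distance vector for a single point (or (n, 2) batch).

    The novelty score is ``min`` of the vector; the predicted label is
    the ``argmin`` (ties toward the lowest class index).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = model.distances(x)
    return d[0] if d.shape[0] == 1 else d
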