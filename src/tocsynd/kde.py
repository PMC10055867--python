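"""Parzen-window (kernel density) classification with novelty rejection.

Each metabolite class keeps its training points and the class-conditional
density at a query ``x`` is the Parzen estimator

    p(x) = (1/N) sum_i (1/h^d) k((x - x_i) / h),

with ``d = 2`` (the two frequency axes) and the standard bivariate
Gaussian profile ``k(u) = exp(-||u||^2 / 2) / (2 pi)``.  Classification
takes the class of highest density; the maximum density doubles as the
novelty score — a query in a region none of the training classes
populates has uniformly low density and is rejected as novel.

The bandwidth ``h`` (in Hz, shared by both axes and all classes by
default) controls the smoothness of the estimate.  When not given it is
selected by maximizing the leave-one-out log-density of the training
points under their own class over a logarithmic grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics.pairwise import euclidean_distances

from .synthetic_data import Dataset

__all__ = [
    "ParzenConfig",
    "KDEModel",
    "parzen_density",
    "fit_kde",
    "kde_scores",
    "loo_bandwidth",
]

#: default bandwidth grid for leave-one-out selection, Hz
DEFAULT_BANDWIDTH_GRID = np.logspace(0.0, 2.5, 40)


@dataclass
class ParzenConfig:
    """Parzen estimator settings.

    h
        Bandwidth in Hz; ``"loo"`` (default) selects it by leave-one-out
        likelihood on the training set.
    per_class
        Select a separate bandwidth per class instead of one global h.
    """

    h: Union[str, float] = "loo"
    per_class: bool = False

    d: int = 2  # feature dimension: (F2, F1)

    def __post_init__(self) -> None:
        if isinstance(self.h, (int, float)) and self.h <= 0:
            raise ValueError("bandwidth h must be positive")


def parzen_density(
    points: np.ndarray, x: np.ndarray, config: ParzenConfig
) -> Union[float, np.ndarray]:
    """Parzen density of ``x`` under the cloud ``points``.

    Implements ``(1/N) sum_i (1/h^d) k((x - x_i)/h)`` with the Gaussian
    profile; for a single stored point the density at that point is
    ``1 / (2 pi h^2)``.  ``x`` may be one point or an (m, 2) batch.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("empty point set")
    if not isinstance(config.h, (int, float)):
        raise ValueError("parzen_density needs a numeric bandwidth")
    single = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    h = float(config.h)
    sq = euclidean_distances(x, points, squared=True)
    dens = np.exp(-sq / (2.0 * h**2)).sum(axis=1) / (
        len(points) * (2.0 * np.pi) ** (config.d / 2.0) * h**config.d
    )
    return float(dens[0]) if single else dens


def _log_density(points: np.ndarray, x: np.ndarray, h: float, d: int = 2) -> np.ndarray:
    """log Parzen density, stable for far-away queries."""
    sq = euclidean_distances(np.atleast_2d(x), np.atleast_2d(points), squared=True)
    return (
        logsumexp(-sq / (2.0 * h**2), axis=1)
        - np.log(len(np.atleast_2d(points)))
        - (d / 2.0) * np.log(2.0 * np.pi)
        - d * np.log(h)
    )


def loo_bandwidth(
    by_class: dict[str, np.ndarray],
    grid: np.ndarray = DEFAULT_BANDWIDTH_GRID,
    d: int = 2,
) -> float:
    """Global bandwidth maximizing the leave-one-out log-density.

    For each candidate h, every training point is scored under the
    Parzen density of its own class with itself left out; the h with the
    largest summed log-density wins (ties toward the smaller h).
    """
    sq_by_class = {}
    for c, pts in by_class.items():
        sq = euclidean_distances(pts, squared=True)
        np.fill_diagonal(sq, np.inf)  # leave-one-out: drop the self term
        sq_by_class[c] = sq
    best_h, best_ll = None, -np.inf
    for h in grid:
        ll = 0.0
        for c, sq in sq_by_class.items():
            n = sq.shape[0]
            if n < 2:
                continue  # a singleton class has no LOO term
            logp = (
                logsumexp(-sq / (2.0 * h**2), axis=1)
                - np.log(n - 1)
                - (d / 2.0) * np.log(2.0 * np.pi)
                - d * np.log(h)
            )
            ll += float(logp.sum())
        if ll > best_ll:
            best_h, best_ll = float(h), ll
    if best_h is None or not np.isfinite(best_ll):
        best_h = float(np.median(grid))
    return best_h


@dataclass
class KDEModel:
    """Fitted Parzen classifier: per-class point clouds + bandwidths."""

    by_class: dict[str, np.ndarray]
    classes: list[str]
    config: ParzenConfig
    bandwidths: dict[str, float]

    def score_samples(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(novelty scores, predicted labels) for the rows of ``X``.

        The novelty score is the maximum class-conditional density
        (smaller = more novel); prediction is the densest class, ties
        broken toward the lowest class index.
        """
        dens = self.class_densities(X)
        idx = np.argmax(dens, axis=1)  # first maximum: lowest class index
        scores = dens[np.arange(len(dens)), idx]
        labels = np.array([self.classes[i] for i in idx], dtype=object)
        return scores, labels

    def class_densities(self, X: np.ndarray) -> np.ndarray:
        """(n, C) matrix of class-conditional Parzen densities."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.classes)))
        for j, c in enumerate(self.classes):
            cfg = ParzenConfig(h=self.bandwidths[c], d=self.config.d)
            out[:, j] = parzen_density(self.by_class[c], X, cfg)
        return out


def fit_kde(train: Dataset, config: ParzenConfig = ParzenConfig()) -> KDEModel:
    """Partition the training set by label and resolve the bandwidth.

    Unlike KNFST, a single-class training set is valid (pure novelty
    detection against one known class).
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    labels = np.asarray(train.labels, dtype=object)
    classes = sorted(set(labels))
    by_class = {
        c: np.asarray(train.features[labels == c], dtype=float) for c in classes
    }
    if isinstance(config.h, (int, float)):
        bandwidths = {c: float(config.h) for c in classes}
    elif config.per_class:
        bandwidths = {
            c: loo_bandwidth({c: pts}, d=config.d) for c, pts in by_class.items()
        }
    else:
        h = loo_bandwidth(by_class, d=config.d)
        bandwidths = {c: h for c in classes}
    return KDEModel(
        by_class=by_class, classes=classes, config=config, bandwidths=bandwidths
    )


def kde_scores(model: KDEModel, x: np.ndarray) -> np.ndarray:
    """Per-class density vector for one point (or (n, 2) batch).

    Predicted label = argmax; novelty score = max; a sample is novel
    when its maximum density falls below the selected threshold.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dens = model.class_densities(x)
    return dens[0] if dens.shape[0] == 1 else dens
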