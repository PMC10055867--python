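"""Novelty-threshold selection, open-set prediction and error metrics.

The two classifiers emit scalar novelty scores with opposite polarity:
KNFST distances grow with novelty (``direction="above"``: novel when the
score exceeds the threshold), Parzen densities shrink with novelty
(``direction="below"``).  A single global threshold per classifier turns
the scores into an open-set decision: reject as NOVEL, or assign the
classifier's label.

Error accounting follows the usual novelty-detection triple:

* ``Fn`` — novel instances accepted as some known class,
* ``Fp`` — known instances rejected as novel,
* ``Fe`` — known instances assigned the wrong known label,

with ``fnr = 100 Fn / Nn``, ``fpr = 100 Fp / (N - Nn)`` and
``total_error = 100 (Fn + Fe + Fp) / N`` over ``N`` test instances of
which ``Nn`` are novel.  Instances are individual cross peaks: a
metabolite with three multiplets contributes three instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .peak_tables import LabeledPeakSet

__all__ = [
    "NOVEL",
    "NoveltyThreshold",
    "OpenSetPrediction",
    "NoveltyMetrics",
    "select_threshold",
    "predict_open_set",
    "compute_metrics",
    "confusion_matrix",
    "plot_novelty_scores",
    "round_half_away",
]

#: sentinel predicted label for rejected instances
NOVEL = "NOVEL"


@dataclass
class NoveltyThreshold:
    """A score cutoff plus the side on which scores count as novel."""

    value: float
    direction: str  # "above": novel if score > value; "below": score < value
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")
        if not np.isfinite(self.value):
            raise ValueError("threshold must be finite")

    def is_novel(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return scores > self.value if self.direction == "above" else scores < self.value


def _candidate_thresholds(pooled: np.ndarray) -> np.ndarray:
    """Midpoints of the sorted pooled scores, plus outer candidates."""
    s = np.unique(pooled)
    mids = (s[:-1] + s[1:]) / 2.0 if len(s) > 1 else np.array([])
    lo = s[0] - max(1.0, abs(s[0])) * 1e-3
    hi = s[-1] + max(1.0, abs(s[-1])) * 1e-3
    return np.concatenate([[lo], mids, [hi]])


def select_threshold(
    known_scores: Sequence[float],
    pseudo_novel_scores: Optional[Sequence[float]] = None,
    direction: str = "above",
    strategy: str = "min-error",
    q: Optional[float] = None,
) -> NoveltyThreshold:
    """Pick the novelty threshold on validation scores.

    ``min-error`` scans the midpoints of the pooled sorted scores and
    returns the candidate minimizing (known flagged novel) + (pseudo-novel
    accepted as known); among zero-gradient ties the candidate sitting in
    the widest score gap wins, then the smallest value — fully
    deterministic.  ``quantile`` ignores the pseudo-novel scores and
    returns the q-th percentile of the known scores (default q=99 for
    distances / ``direction="above"``, q=1 for densities); it is the
    fallback when no pseudo-novel scores exist.
    """
    known = np.asarray(list(known_scores), dtype=float)
    if known.size == 0:
        raise ValueError("known_scores must be non-empty")
    pseudo = (
        np.asarray(list(pseudo_novel_scores), dtype=float)
        if pseudo_novel_scores is not None
        else np.array([])
    )
    if strategy == "quantile" or pseudo.size == 0:
        if q is None:
            q = 99.0 if direction == "above" else 1.0
        value = float(np.percentile(known, q))
        return NoveltyThreshold(
            value=value,
            direction=direction,
            provenance={"strategy": "quantile", "q": q, "n_known": int(known.size)},
        )
    if strategy != "min-error":
        raise ValueError("strategy must be 'min-error' or 'quantile'")

    pooled = np.concatenate([known, pseudo])
    candidates = _candidate_thresholds(pooled)
    best = None  # (error, -gap, value)
    for t in candidates:
        if direction == "above":
            err = int(np.sum(known > t)) + int(np.sum(pseudo <= t))
        else:
            err = int(np.sum(known < t)) + int(np.sum(pseudo >= t))
        sorted_pool = np.sort(np.unique(pooled))
        below = sorted_pool[sorted_pool < t]
        above = sorted_pool[sorted_pool > t]
        gap = (above[0] - below[-1]) if (below.size and above.size) else np.inf
        key = (err, -gap, t)
        if best is None or key < best:
            best = key
    err, neg_gap, value = best
    return NoveltyThreshold(
        value=float(value),
        direction=direction,
        provenance={
            "strategy": "min-error",
            "validation_error": int(err),
            "n_known": int(known.size),
            "n_pseudo_novel": int(pseudo.size),
        },
    )


@dataclass
class OpenSetPrediction:
    """Per-instance open-set outcome on one test set."""

    true_labels: np.ndarray
    predicted_labels: np.ndarray  # class label or NOVEL
    scores: np.ndarray
    threshold: NoveltyThreshold
    sample: str = ""

    def __len__(self) -> int:
        return len(self.true_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true": self.true_labels,
                "predicted": self.predicted_labels,
                "score": self.scores,
            }
        )


def predict_open_set(
    model, threshold: NoveltyThreshold, test: LabeledPeakSet
) -> OpenSetPrediction:
    """Score every test peak and reject or classify it.

    ``model`` is any fitted classifier exposing
    ``score_samples(X) -> (scores, labels)`` (KNFST or KDE here); the
    threshold's direction must match the model's score polarity.
    """
    X = test.features()
    scores, labels = model.score_samples(X)
    novel = threshold.is_novel(scores)
    predicted = labels.copy()
    predicted[novel] = NOVEL
    true = np.array([p.metabolite for p in test.peaks], dtype=object)
    return OpenSetPrediction(
        true_labels=true,
        predicted_labels=predicted,
        scores=np.asarray(scores, dtype=float),
        threshold=threshold,
        sample=test.sample,
    )


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (reporting convention)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class NoveltyMetrics:
    """Open-set error counts and rates for one test set."""

    Fn: int  # novel accepted as known
    Fp: int  # known rejected as novel
    Fe: int  # known assigned the wrong known label
    Nn: int  # novel instances in the test set
    N: int  # total test instances
    fnr: float = field(init=False)
    fpr: float = field(init=False)
    total_error: float = field(init=False)
    fnr_undefined: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not 0 <= self.Fn <= max(self.Nn, 0):
            raise ValueError("Fn must lie in [0, Nn]")
        if self.Fp + self.Fe > self.N - self.Nn:
            raise ValueError("Fp + Fe cannot exceed the known instance count")
        if self.Nn == 0:
            self.fnr = 0.0
            self.fnr_undefined = True
        else:
            self.fnr = 100.0 * self.Fn / self.Nn
        self.fpr = 100.0 * self.Fp / (self.N - self.Nn) if self.N > self.Nn else 0.0
        self.total_error = 100.0 * (self.Fn + self.Fe + self.Fp) / self.N

    def rounded(self) -> dict[str, float]:
        """Rates rounded to one decimal (reporting convention)."""
        return {
            "fnr": round_half_away(self.fnr),
            "fpr": round_half_away(self.fpr),
            "total_error": round_half_away(self.total_error),
        }

    def to_dict(self) -> dict:
        return {
            "Fn": self.Fn,
            "Fp": self.Fp,
            "Fe": self.Fe,
            "Nn": self.Nn,
            "N": self.N,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "total_error": self.total_error,
        }


def compute_metrics(
    pred: OpenSetPrediction, known_label_set: Iterable[str]
) -> NoveltyMetrics:
    """Count Fn / Fp / Fe against the training label set."""
    known = set(known_label_set)
    true = pred.true_labels
    predicted = pred.predicted_labels
    is_novel_true = np.array([t not in known for t in true], dtype=bool)
    is_rejected = predicted == NOVEL
    Fn = int(np.sum(is_novel_true & ~is_rejected))
    Fp = int(np.sum(~is_novel_true & is_rejected))
    Fe = int(np.sum(~is_novel_true & ~is_rejected & (predicted != true)))
    return NoveltyMetrics(
        Fn=Fn, Fp=Fp, Fe=Fe, Nn=int(is_novel_true.sum()), N=len(true)
    )


def confusion_matrix(pred: OpenSetPrediction) -> pd.DataFrame:
    """Labeled confusion matrix: rows true labels, columns predicted
    labels plus NOVEL; row sums equal the true-label counts."""
    true = pd.Series(pred.true_labels, dtype=object)
    predicted = pd.Series(pred.predicted_labels, dtype=object)
    rows = sorted(set(true))
    cols = sorted(set(predicted) - {NOVEL}) + [NOVEL]
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for t, p in zip(true, predicted):
        mat.loc[t, p] += 1
    return mat


_GROUP_STYLE = {
    # group name -> (color, marker); colors follow the usual convention:
    # training known blue, test known green, misclassified known black,
    # detected novel red, missed novel pink
    "known-train": ("tab:blue", "."),
    "known-test correct": ("tab:green", "o"),
    "known-test misclassified": ("black", "s"),
    "novel detected": ("tab:red", "^"),
    "novel missed": ("#ff69b4", "v"),
}


def score_groups(
    pred: OpenSetPrediction, known_label_set: Iterable[str]
) -> dict[str, np.ndarray]:
    """Split the test scores into the five reporting groups."""
    known = set(known_label_set)
    true, predicted = pred.true_labels, pred.predicted_labels
    s = pred.scores
    is_novel_true = np.array([t not in known for t in true], dtype=bool)
    rejected = predicted == NOVEL
    return {
        "known-test correct": s[~is_novel_true & ~rejected & (predicted == true)],
        "known-test misclassified": s[~is_novel_true & ~rejected & (predicted != true)],
        "novel detected": s[is_novel_true & rejected],
        "novel missed": s[is_novel_true & ~rejected],
        "known-rejected": s[~is_novel_true & rejected],
    }


def plot_novelty_scores(
    pred: OpenSetPrediction,
    training_scores: Sequence[float],
    threshold: NoveltyThreshold,
    path: Union[str, Path],
    known_label_set: Optional[Iterable[str]] = None,
    title: str = "",
) -> Path:
    """Scatter the novelty scores by group with the threshold line.

    Groups: known-train, known-test correct, known-test misclassified,
    novel detected, novel missed (known peaks rejected as novel are
    folded into the misclassified group for display).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if known_label_set is None:
        known_label_set = set(pred.true_labels[pred.predicted_labels != NOVEL])
    groups = score_groups(pred, known_label_set)
    display = {
        "known-train": np.asarray(list(training_scores), dtype=float),
        "known-test correct": groups["known-test correct"],
        "known-test misclassified": np.concatenate(
            [groups["known-test misclassified"], groups["known-rejected"]]
        ),
        "novel detected": groups["novel detected"],
        "novel missed": groups["novel missed"],
    }
    fig, ax = plt.subplots(figsize=(7, 4))
    offset = 0
    for name, scores in display.items():
        color, marker = _GROUP_STYLE[name]
        if len(scores):
            ax.scatter(
                np.arange(offset, offset + len(scores)),
                scores,
                s=18,
                c=color,
                marker=marker,
                label=f"{name} (n={len(scores)})",
            )
        offset += len(scores)
    ax.axhline(threshold.value, color="gray", ls="--", lw=1, label="threshold")
    ax.set_xlabel("instance")
    ax.set_ylabel("novelty score")
    if threshold.direction == "below":
        ax.set_yscale("symlog", linthresh=max(threshold.value, 1e-300))
    ax.set_title(title or pred.sample)
    ax.legend(fontsize=7, loc="best")
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
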