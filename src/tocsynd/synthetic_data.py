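"""Training/validation set generation for cross-peak classification.

A single reference spectrum yields only one (F2, F1) point per multiplet,
far too little to train a classifier.  Chemical shifts, however, drift
between samples (pH, ionic strength, temperature), so realistic extra
instances of a peak can be produced by perturbing its frequencies:

* :func:`augment_shift` — training set: per-axis shifts drawn uniformly
  from [-max_shift, +max_shift] Hz (default bound 30 Hz), with
  under-sampling of metabolites that have many multiplets so classes end
  up balanced, up to a fixed total size (default 4000 instances).
* :func:`augment_noise` — validation set: i.i.d. Gaussian noise per axis.
* :func:`make_synthetic_table` — fully synthetic train/test peak tables
  with controllable class count, separation and novel classes, used to
  benchmark open-set behavior without any real spectrum.

All generators are deterministic given their seed, and never emit a
frequency outside the spectral window (out-of-window draws are
resampled, not clipped, to avoid density pile-up at the window edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .peak_tables import SPECTRAL_WIDTH_HZ, CrossPeak, LabeledPeakSet

__all__ = [
    "AugmentationConfig",
    "Dataset",
    "augment_shift",
    "augment_noise",
    "make_synthetic_table",
]


@dataclass
class AugmentationConfig:
    """Knobs of the augmentation generators.

    n_total
        Target training-set size (instances), default 4000.
    max_shift
        Per-axis bound of the uniform training shift, Hz, default 30.
    noise_sigma
        Standard deviation of the validation Gaussian noise, Hz.
    per_class_cap
        During training augmentation, metabolites with more than this
        many multiplets contribute only a random subset of that size per
        round (under-sampling against class imbalance); default 2.
    seed
        RNG seed; identical config + seed gives a bit-identical dataset.
    """

    n_total: int = 4000
    max_shift: float = 30.0
    noise_sigma: float = 10.0
    per_class_cap: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.max_shift < 0:
            raise ValueError("max_shift must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.per_class_cap < 1:
            raise ValueError("per_class_cap must be at least 1")


@dataclass
class Dataset:
    """Labeled feature matrix: n x 2 frequencies (Hz) + n labels."""

    features: np.ndarray
    labels: np.ndarray
    provenance: str = "train"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2 or self.features.shape[1] != 2:
            raise ValueError("features must be an (n, 2) array")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "metabolite": self.labels,
                "f2_hz": self.features[:, 0],
                "f1_hz": self.features[:, 1],
                "provenance": self.provenance,
            }
        )


def _draw_in_window(
    center: np.ndarray, draw, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Draw center + perturbation, resampling until inside the window."""
    for _ in range(max_tries):
        x = center + draw(rng)
        if np.all((x >= 0.0) & (x <= SPECTRAL_WIDTH_HZ)):
            return x
    raise RuntimeError("could not draw an in-window sample; peak too far outside?")


def augment_shift(peaks: LabeledPeakSet, config: AugmentationConfig) -> Dataset:
    """Build a balanced training set by uniform frequency shifts.

    Each output instance is one source multiplet shifted independently
    on each axis by at most ``config.max_shift`` Hz.  Classes are
    balanced: the ``config.n_total`` instances are split evenly over the
    metabolite labels (sorted order; the remainder goes to the first
    labels).  A class with more multiplets than ``per_class_cap``
    contributes, per round of ``per_class_cap`` draws, only a freshly
    drawn random subset of its multiplets, so no single class floods the
    set with its many multiplets while every multiplet still appears
    across rounds.
    """
    if len(peaks) == 0:
        raise ValueError("cannot augment an empty peak set")
    rng = np.random.default_rng(config.seed)
    by_class: dict[str, list[CrossPeak]] = {}
    for p in peaks.peaks:
        by_class.setdefault(p.metabolite, []).append(p)
    classes = sorted(by_class)
    base, extra = divmod(config.n_total, len(classes))

    def shift(r: np.random.Generator) -> np.ndarray:
        return r.uniform(-config.max_shift, config.max_shift, size=2)

    feats: list[np.ndarray] = []
    labels: list[str] = []
    for ci, label in enumerate(classes):
        quota = base + (1 if ci < extra else 0)
        multiplets = np.array([[p.f2, p.f1] for p in by_class[label]])
        m = len(multiplets)
        emitted = 0
        while emitted < quota:
            if m > config.per_class_cap:
                subset = rng.choice(m, size=config.per_class_cap, replace=False)
            else:
                subset = np.arange(m)
            for idx in subset:
                if emitted >= quota:
                    break
                feats.append(_draw_in_window(multiplets[idx], shift, rng))
                labels.append(label)
                emitted += 1
    return Dataset(features=np.array(feats), labels=np.array(labels, dtype=object),
                   provenance="train")


def augment_noise(
    peaks: LabeledPeakSet, n_per_peak: int, config: AugmentationConfig
) -> Dataset:
    """Build a validation set by Gaussian perturbation of each peak.

    Every source peak yields ``n_per_peak`` instances with independent
    N(0, noise_sigma^2) noise on each axis; labels are inherited.
    """
    if len(peaks) == 0:
        raise ValueError("cannot augment an empty peak set")
    if n_per_peak <= 0:
        raise ValueError("n_per_peak must be positive")
    rng = np.random.default_rng(config.seed)

    def noise(r: np.random.Generator) -> np.ndarray:
        return r.normal(0.0, config.noise_sigma, size=2)

    feats: list[np.ndarray] = []
    labels: list[str] = []
    for p in peaks.peaks:
        center = np.array([p.f2, p.f1])
        for _ in range(n_per_peak):
            feats.append(_draw_in_window(center, noise, rng))
            labels.append(p.metabolite)
    return Dataset(features=np.array(feats), labels=np.array(labels, dtype=object),
                   provenance="validation")


def make_synthetic_table(
    n_known_classes: int,
    n_novel_classes: int,
    peaks_per_class: int,
    min_separation: float = 0.0,
    seed: int = 0,
    jitter: float = 10.0,
    margin: float = 100.0,
) -> tuple[LabeledPeakSet, LabeledPeakSet]:
    """Generate a synthetic train/test pair of peak sets.

    Class centers are placed uniformly in the spectral window (inset by
    *margin* Hz) subject to a pairwise ``min_separation``.  Known
    classes appear in both sets; their test peaks are re-jittered around
    the same centers, emulating between-sample chemical-shift drift.
    Novel classes appear only in the test set.  Known classes are named
    ``class_01`` ..., novel ones ``novel_01`` ...

    Raises
    ------
    ValueError
        When the requested number of centers cannot be placed at the
        requested separation (geometric infeasibility).
    """
    if min_separation < 0:
        raise ValueError("min_separation must be nonnegative")
    if n_known_classes < 1 or n_novel_classes < 0 or peaks_per_class < 1:
        raise ValueError("class and peak counts must be positive")
    rng = np.random.default_rng(seed)
    n_classes = n_known_classes + n_novel_classes
    lo, hi = margin, SPECTRAL_WIDTH_HZ - margin
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_classes:
        c = rng.uniform(lo, hi, size=2)
        if all(np.linalg.norm(c - o) >= min_separation for o in centers):
            centers.append(c)
        tries += 1
        if tries > 10000 * n_classes:
            raise ValueError(
                f"cannot place {n_classes} class centers at pairwise "
                f"separation {min_separation} Hz inside the spectral window"
            )

    def jitter_draw(r: np.random.Generator) -> np.ndarray:
        return r.uniform(-jitter, jitter, size=2) if jitter > 0 else np.zeros(2)

    def peaks_around(center: np.ndarray, label: str, sample: str) -> list[CrossPeak]:
        return [
            CrossPeak(*(float(v) for v in _draw_in_window(center, jitter_draw, rng)),
                      metabolite=label, sample=sample)
            for _ in range(peaks_per_class)
        ]

    train_peaks: list[CrossPeak] = []
    test_peaks: list[CrossPeak] = []
    for i in range(n_known_classes):
        label = f"class_{i + 1:02d}"
        train_peaks.extend(peaks_around(centers[i], label, "synthetic-train"))
        test_peaks.extend(peaks_around(centers[i], label, "synthetic-test"))
    for j in range(n_novel_classes):
        label = f"novel_{j + 1:02d}"
        test_peaks.extend(
            peaks_around(centers[n_known_classes + j], label, "synthetic-test")
        )
    return (
        LabeledPeakSet(sample="synthetic-train", peaks=train_peaks),
        LabeledPeakSet(sample="synthetic-test", peaks=test_peaks),
    )
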