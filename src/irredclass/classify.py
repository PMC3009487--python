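"""Maximum-margin classification on precomputed score kernels, plus the
ranking metrics used for remote-homology benchmarks.

The classifier is consumed through a small interface contract: fit a
soft-margin SVM on a precomputed (possibly indefinite) kernel with an
iteration cap, and score test sequences by the standard kernel expansion

    score(t) = sum_i alpha_i * y_i * K(t, i) + b.

scikit-learn's libsvm backend fills the contract; the trained model is
reduced to the id-aligned weight vector ``alpha`` (zero off the support)
so footprinting and serialization do not depend on the optimizer.

Metrics on a ranking of test sequences:

- ROC: normalized area under true positives vs false positives, ties at
  half credit (trapezoidal).
- ROC50: the same area truncated at 50 false positives, normalized by
  ``#positives * min(50, #negatives)``.
- mRFP: fraction of negatives scoring at or above the median positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .scoring import ScoreMatrix

__all__ = [
    "ExperimentSplit",
    "TrainedModel",
    "RankingResult",
    "train",
    "decision_scores",
    "roc_score",
    "roc50_score",
    "mrfp_score",
]


@dataclass(frozen=True)
class ExperimentSplit:
    """One family-vs-rest experiment: disjoint train/test id lists."""

    family: str
    pos_train: tuple[str, ...]
    neg_train: tuple[str, ...]
    pos_test: tuple[str, ...]
    neg_test: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = (self.pos_train, self.neg_train, self.pos_test, self.neg_test)
        all_ids = [i for g in groups for i in g]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split id lists must be disjoint")

    @property
    def train_ids(self) -> tuple[str, ...]:
        return self.pos_train + self.neg_train

    @property
    def test_ids(self) -> tuple[str, ...]:
        return self.pos_test + self.neg_test

    def train_labels(self) -> np.ndarray:
        return np.array([1] * len(self.pos_train) + [-1] * len(self.neg_train))

    def test_labels(self) -> np.ndarray:
        return np.array([1] * len(self.pos_test) + [-1] * len(self.neg_test))


@dataclass(frozen=True)
class TrainedModel:
    """A trained kernel classifier: per-training-sequence weights and bias.

    ``alpha`` holds the nonnegative dual weights (zero for non-support
    training sequences), ``labels`` the +-1 training labels, both aligned
    with ``train_ids``.
    """

    train_ids: tuple[str, ...]
    alpha: np.ndarray
    labels: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.train_ids) or len(self.labels) != len(
            self.train_ids
        ):
            raise ValueError("weights must align with the training ids")

    @property
    def signed_alpha(self) -> np.ndarray:
        """alpha_i * y_i, the coefficients of the kernel expansion."""
        return self.alpha * self.labels


@dataclass(frozen=True)
class RankingResult:
    """Decision scores with ground-truth +-1 labels for a test set."""

    ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.ids) or len(self.labels) != len(self.ids):
            raise ValueError("one score and one label per test id")


def train(
    K: ScoreMatrix,
    labels: np.ndarray | list[int],
    *,
    max_iter: int = 1_000_000,
    C: float = 1.0,
) -> TrainedModel:
    """Fit a soft-margin SVM on a precomputed kernel.

    ``K`` must already be restricted to the training ids, in order.  The
    iteration cap keeps the optimizer from cycling on indefinite kernels;
    a cap hit is reported as a warning, not an error.
    """
    y = np.asarray(labels)
    if len(y) != len(K.ids):
        raise ValueError("one label per kernel row required")
    classes = set(np.unique(y).tolist())
    if classes != {-1, 1}:
        raise ValueError(f"labels must contain both classes (+1/-1), got {classes}")
    svc = SVC(kernel="precomputed", C=C, max_iter=max_iter)
    with warnings.catch_warnings():
        # An iteration-cap stop on a weakly non-PSD kernel is expected.
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(K.values, y)
    alpha = np.zeros(len(y))
    alpha[svc.support_] = np.abs(svc.dual_coef_[0])
    return TrainedModel(
        train_ids=K.ids,
        alpha=alpha,
        labels=y,
        bias=float(svc.intercept_[0]),
    )


def decision_scores(
    model: TrainedModel,
    K_test_train: np.ndarray,
    test_ids: tuple[str, ...] | list[str],
    test_labels: np.ndarray | list[int],
) -> RankingResult:
    """Kernel-expansion decision scores for test sequences.

    ``K_test_train`` has one row per test sequence and one column per
    training sequence, column order matching ``model.train_ids``.
    """
    K = np.asarray(K_test_train, dtype=float)
    if K.ndim != 2 or K.shape != (len(test_ids), len(model.train_ids)):
        raise ValueError(
            f"kernel block shape {K.shape} does not match "
            f"({len(test_ids)} test, {len(model.train_ids)} train)"
        )
    scores = K @ model.signed_alpha + model.bias
    return RankingResult(
        ids=tuple(test_ids), scores=scores, labels=np.asarray(test_labels)
    )


def _check_two_classes(r: RankingResult) -> tuple[np.ndarray, np.ndarray]:
    pos = r.scores[r.labels == 1]
    neg = r.scores[r.labels == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ranking metrics need both classes present")
    return pos, neg


def _roc_counts(r: RankingResult) -> tuple[np.ndarray, np.ndarray, int, int]:
    """ROC curve in raw counts: (false positives, true positives)."""
    pos, neg = _check_two_classes(r)
    fpr, tpr, _ = roc_curve(r.labels, r.scores, drop_intermediate=False)
    return fpr * len(neg), tpr * len(pos), len(pos), len(neg)


def roc_score(r: RankingResult) -> float:
    """Normalized area under the TP-vs-FP curve; ties at half credit."""
    fps, tps, n_pos, n_neg = _roc_counts(r)
    return float(np.trapezoid(tps, fps) / (n_pos * n_neg))


def roc50_score(r: RankingResult, *, n_fp: int = 50) -> float:
    """ROC area truncated at ``n_fp`` false positives, normalized.

    Normalization uses ``min(n_fp, #negatives)`` so the value stays in
    [0, 1] on small experiments; when there are at most ``n_fp`` negatives
    the truncation is inactive and the value equals :func:`roc_score`.
    """
    fps, tps, n_pos, n_neg = _roc_counts(r)
    fmax = min(n_fp, n_neg)
    # Clip curve segments at fmax; a vertical jump (true positives found at
    # exactly fmax false positives) lies past the truncation and adds
    # nothing, while a diagonal tie segment is interpolated (half credit).
    area = 0.0
    for (f0, t0), (f1, t1) in zip(zip(fps, tps), zip(fps[1:], tps[1:])):
        if f0 >= fmax:
            break
        if f1 <= fmax:
            area += (f1 - f0) * (t0 + t1) / 2
        else:
            t_cut = t0 + (t1 - t0) * (fmax - f0) / (f1 - f0)
            area += (fmax - f0) * (t0 + t_cut) / 2
            break
    return float(area / (n_pos * fmax))


def mrfp_score(r: RankingResult) -> float:
    """Median rate of false positives.

    Fraction of negatives scoring at or above the median positive score.
    """
    pos, neg = _check_two_classes(r)
    median_pos = np.median(pos)
    return float(np.mean(neg >= median_pos))
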