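"""QIF + CNN feature fusion, Random-Forest classification and evaluation.

The fused representation concatenates the 50 radiomic features with the
200 CNN penultimate-layer features (QIF first, 250 total) and feeds a
Random Forest of 1000 trees.  A single-covariate logistic model on the
square root of the largest cross-sectional area (a RECIST-like size
surrogate) serves as the baseline, and a low-data stress test retrains
the forest from one positive and one negative example over many repeats.

Evaluation reports AUC (rank-based Mann-Whitney with half credit for
ties) plus accuracy / sensitivity / specificity from the confusion matrix
at a probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .qif import QIF_FEATURE_NAMES, SIZE_FEATURE_NAMES

__all__ = [
    "FusedFeatureVector",
    "EvalResult",
    "CNN_FEATURE_NAMES",
    "combine_features",
    "combine_feature_tables",
    "train_random_forest",
    "rf_no_size_variant",
    "size_feature_mm",
    "size_baseline",
    "evaluate",
    "one_shot_experiment",
]

N_QIF = 50
N_CNN = 200
CNN_FEATURE_NAMES = tuple(f"cnn_{i:03d}" for i in range(N_CNN))


@dataclass(frozen=True)
class FusedFeatureVector:
    """50 QIF values concatenated with 200 CNN values (QIF first)."""

    qif: np.ndarray
    cnn: np.ndarray
    key: str
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "qif", np.asarray(self.qif, dtype=float))
        object.__setattr__(self, "cnn", np.asarray(self.cnn, dtype=float))
        if self.qif.shape != (N_QIF,):
            raise ValueError(f"expected {N_QIF} QIF values, got {self.qif.shape}")
        if self.cnn.shape != (N_CNN,):
            raise ValueError(f"expected {N_CNN} CNN values, got {self.cnn.shape}")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.qif, self.cnn])


def combine_features(qif, cnn, key: str = "", label: int = 0) -> FusedFeatureVector:
    """Concatenate one nodule's QIF and CNN feature vectors (250 values)."""
    return FusedFeatureVector(qif=qif, cnn=cnn, key=key, label=label)


def combine_feature_tables(qif: pd.DataFrame, cnn: pd.DataFrame) -> pd.DataFrame:
    """Join keyed QIF and CNN tables into one 250-column table, QIF first.

    Raises on any key present in one table but not the other.
    """
    missing_cnn = sorted(set(qif.index) - set(cnn.index))
    missing_qif = sorted(set(cnn.index) - set(qif.index))
    if missing_cnn:
        raise KeyError(f"keys missing a CNN feature row: {missing_cnn}")
    if missing_qif:
        raise KeyError(f"keys missing a QIF feature row: {missing_qif}")
    fused = pd.concat(
        [qif.loc[:, list(QIF_FEATURE_NAMES)], cnn.loc[qif.index]], axis=1
    )
    assert fused.shape[1] == N_QIF + N_CNN
    return fused


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _check_two_classes(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def train_random_forest(
    features, labels, n_trees: int = 1000, seed: int = 0
) -> RandomForestClassifier:
    """Random Forest with ``n_trees`` trees and library defaults otherwise."""
    labels = _check_two_classes(labels)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


@dataclass
class NoSizeForest:
    """A Random Forest trained with direct size measures excluded."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    excluded: tuple[str, ...]

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(
            table.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        )


def rf_no_size_variant(
    table: pd.DataFrame,
    labels,
    n_trees: int = 1000,
    seed: int = 0,
    excluded: tuple[str, ...] = SIZE_FEATURE_NAMES,
) -> NoSizeForest:
    """Train the forest with all direct measures of size omitted.

    The default exclusion set (pixel count, area, x/y spans, perimeter,
    summed surface distance) leaves 44 of the 50 radiomic features; it is
    a configuration value, not code.
    """
    kept = tuple(c for c in table.columns if c not in excluded)
    model = train_random_forest(
        table.loc[:, list(kept)].to_numpy(dtype=float), labels,
        n_trees=n_trees, seed=seed,
    )
    return NoSizeForest(model=model, feature_names=kept, excluded=tuple(excluded))


def size_feature_mm(mask: np.ndarray, spacing) -> float:
    """sqrt of the largest cross-sectional in-mask area (mm): RECIST analogue."""
    mask = np.asarray(mask, dtype=bool)
    pixel_area = float(spacing[0]) * float(spacing[1])
    largest = float(mask.sum(axis=(0, 1)).max()) * pixel_area
    return float(np.sqrt(largest))


def size_baseline(sizes, labels, seed: int = 0) -> LogisticRegression:
    """Single-covariate logistic model on the size feature."""
    labels = _check_two_classes(labels)
    sizes = np.asarray(sizes, dtype=float).reshape(-1, 1)
    if np.ptp(sizes) == 0:
        raise ValueError("size feature is constant; logistic fit is degenerate")
    clf = LogisticRegression(random_state=seed)
    clf.fit(sizes, labels)
    return clf


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score+ > score-) with ties counted half."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    last_score = None
    for i in order:
        if last_score is not None and scores[i] != last_score:
            points.append((fp / n_neg, tp / n_pos))
        tp += int(pos[i])
        fp += int(not pos[i])
        last_score = scores[i]
    points.append((1.0, 1.0))
    return points


def evaluate(scores, labels, threshold: float = 0.5) -> EvalResult:
    """AUC plus thresholded confusion-matrix metrics for binary scores."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    pos = labels == 1
    pred = scores >= threshold
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    return EvalResult(
        auc=_rank_auc(scores, labels),
        accuracy=(tp + tn) / labels.size,
        sensitivity=tp / int(pos.sum()),
        specificity=tn / int((~pos).sum()),
        threshold=threshold,
        roc_points=_roc_points(scores, labels),
    )


def youden_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(scores):
        r = evaluate(scores, labels, threshold=t)
        j = r.sensitivity + r.specificity - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


# ---------------------------------------------------------------------------
# low-data stress test
# ---------------------------------------------------------------------------

def one_shot_experiment(
    features,
    labels,
    n_repeats: int = 200,
    seed: int = 0,
    n_trees: int = 1000,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Train on one positive and one negative example, test on the rest.

    Repeated ``n_repeats`` times with fresh random picks; returns the mean
    AUC and mean accuracy over repeats.
    """
    features = np.asarray(features, dtype=float)
    labels = _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    aucs, accs = [], []
    for rep in range(n_repeats):
        i_pos = int(rng.choice(pos_idx))
        i_neg = int(rng.choice(neg_idx))
        train_idx = [i_neg, i_pos]
        test_mask = np.ones(labels.size, dtype=bool)
        test_mask[train_idx] = False
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1))
        )
        clf.fit(features[train_idx], labels[train_idx])
        scores = clf.predict_proba(features[test_mask])[:, 1]
        res = evaluate(scores, labels[test_mask], threshold=threshold)
        aucs.append(res.auc)
        accs.append(res.accuracy)
    return float(np.mean(aucs)), float(np.mean(accs))
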