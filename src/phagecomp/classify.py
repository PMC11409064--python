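"""Provenance discrimination with replicate shallow feed-forward networks.

Features are the 19 compositional metrics, standardized on the full dataset
before an 80:20 train:test split is drawn once and frozen; every replicate
model (and every feature-subset model in the selection module) trains and
tests on exactly the same genomes. The network is p -> 32 -> 16 -> 1 with
ReLU hidden activations and a sigmoid output, trained with binary
cross-entropy loss and the Adam optimizer for 10 epochs at batch size 32;
test predictions are thresholded at 0.5. Sensitivity is recall of the
generated class, specificity recall of the natural class.

Standardizing before splitting leaks test-set location/scale into training;
this ordering is preserved deliberately because it is the pipeline being
characterized, and is noted in the docs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .composition import METRIC_NAMES
from .sequence_io import GENERATED

logger = logging.getLogger(__name__)

DEFAULT_EPOCHS = 10
DEFAULT_BATCH_SIZE = 32
DEFAULT_HIDDEN = (32, 16)
DEFAULT_N_REPLICATES = 12


@dataclass
class SplitDataset:
    """Standardized features with one frozen train/test partition."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray
    feature_names: tuple[str, ...]
    train_index: np.ndarray
    test_index: np.ndarray

    def subset(self, features: list[str] | tuple[str, ...]) -> "SplitDataset":
        """Same rows and partition, restricted to ``features`` (canonical order)."""
        feats = [f for f in self.feature_names if f in set(features)]
        missing = set(features) - set(self.feature_names)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        cols = [self.feature_names.index(f) for f in feats]
        return SplitDataset(
            X=self.X[:, cols], y=self.y, ids=self.ids, feature_names=tuple(feats),
            train_index=self.train_index, test_index=self.test_index,
        )

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def make_split(
    frame: pd.DataFrame,
    feature_subset: list[str] | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitDataset:
    """Scale the full feature matrix, then draw one frozen random split.

    Labels: 0 = natural, 1 = generated. Raises if either class is absent
    from either partition or either class has fewer than 10 profiles.
    """
    features = tuple(feature_subset) if feature_subset else METRIC_NAMES
    features = tuple(f for f in METRIC_NAMES if f in set(features))  # canonical order
    y = (frame["provenance"] == GENERATED).to_numpy(dtype=int)
    for cls in (0, 1):
        if (y == cls).sum() < 10:
            raise ValueError("need >= 10 profiles per class")
    X = StandardScaler().fit_transform(frame[list(features)].to_numpy(dtype=float))
    n = len(frame)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_index, train_index = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    for part, name in ((train_index, "train"), (test_index, "test")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"class absent from {name} partition; reseed or rebalance")
    return SplitDataset(
        X=X, y=y, ids=frame.index.to_numpy(), feature_names=features,
        train_index=train_index, test_index=test_index,
    )


@dataclass
class ClassifierRun:
    replicate: int
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: pd.Series  # per-test-sequence predicted label, indexed by id

    @staticmethod
    def from_confusion(replicate: int, tp: int, tn: int, fp: int, fn: int,
                       predictions: pd.Series) -> "ClassifierRun":
        return ClassifierRun(
            replicate=replicate,
            accuracy=(tp + tn) / (tp + tn + fp + fn),
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
            predictions=predictions,
        )


def train_model(split: SplitDataset, seed: int = 0,
                epochs: int = DEFAULT_EPOCHS,
                batch_size: int = DEFAULT_BATCH_SIZE,
                hidden: tuple[int, ...] = DEFAULT_HIDDEN) -> ClassifierRun:
    """Train one network on the frozen split and score the test partition."""
    model = MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=batch_size,
        learning_rate_init=1e-3,
        max_iter=epochs,
        shuffle=True,
        random_state=int(seed) % (2**32 - 1),
        early_stopping=False,
        n_iter_no_change=epochs + 1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(split.X[split.train_index], split.y[split.train_index])
    if not np.isfinite(model.loss_):
        raise RuntimeError(f"non-finite training loss (replicate seed {seed})")
    proba = model.predict_proba(split.X[split.test_index])[:, 1]
    pred = (proba >= 0.5).astype(int)
    truth = split.y[split.test_index]
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    predictions = pd.Series(pred, index=split.ids[split.test_index], name=f"rep{seed}")
    return ClassifierRun.from_confusion(seed, tp, tn, fp, fn, predictions)


@dataclass
class ReplicateSummary:
    runs: list[ClassifierRun]
    median_accuracy: float
    median_sensitivity: float
    median_specificity: float
    misidentified: pd.Series = field(default=None)  # per test id: # replicates wrong

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"replicate": r.replicate, "accuracy": r.accuracy,
                 "sensitivity": r.sensitivity, "specificity": r.specificity}
                for r in self.runs
            ]
        )


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def replicate_models(split: SplitDataset, n_replicates: int = DEFAULT_N_REPLICATES,
                     base_seed: int = 0, **train_kwargs) -> ReplicateSummary:
    """Replicate networks on the identical split, differing only in the
    initialization/shuffling seed; report medians and per-sequence
    misidentification counts across replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    runs = [train_model(split, seed=int(s), **train_kwargs) for s in replicate_seeds(base_seed, n_replicates)]
    truth = pd.Series(split.y[split.test_index], index=split.ids[split.test_index])
    wrong = sum((r.predictions != truth).astype(int) for r in runs)
    return ReplicateSummary(
        runs=runs,
        median_accuracy=float(np.median([r.accuracy for r in runs])),
        median_sensitivity=float(np.median([r.sensitivity for r in runs])),
        median_specificity=float(np.median([r.specificity for r in runs])),
        misidentified=wrong,
    )


def zeror_benchmark(labels: np.ndarray | pd.Series) -> float:
    """Accuracy of always predicting the most common class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / labels.size)
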