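"""Feature-subset experiments on the frozen split: a random-subset sweep
and greedy forward selection of the most (or least) predictive metrics.

Greedy selection starts from the empty feature set; at each step every
remaining metric is evaluated by training ``reps`` replicate networks on
the current set plus that metric, and the metric with the highest
(maximal mode) or lowest (minimal mode) mean accuracy is added. Ties break
on canonical metric order. Being greedy, the resulting order is locally
optimal at each step but need not be the global optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SplitDataset, train_model

logger = logging.getLogger(__name__)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _mean_accuracy(split: SplitDataset, features: list[str], reps: int, seeds: list[int]) -> float:
    sub = split.subset(features)
    return float(np.mean([train_model(sub, seed=s).accuracy for s in seeds[:reps]]))


@dataclass
class SubsetSweepResult:
    """Accuracies of models trained on random feature subsets of each size."""

    results: pd.DataFrame  # columns: feature_count, replicate, subset, accuracy

    def median_by_count(self) -> pd.Series:
        return self.results.groupby("feature_count")["accuracy"].median()


def random_subset_sweep(
    split: SplitDataset,
    counts: range | list[int] | None = None,
    reps: int = 12,
    seed: int = 0,
) -> SubsetSweepResult:
    """For each feature count, ``reps`` models each on an independent random
    subset (drawn without replacement), scored on the fixed test set."""
    names = list(split.feature_names)
    if counts is None:
        counts = range(1, len(names))
    rows = []
    for count in counts:
        for rep in range(reps):
            rng = np.random.default_rng(_derived_seed(seed, count, rep))
            subset = sorted(rng.choice(len(names), size=count, replace=False))
            feats = [names[i] for i in subset]
            run = train_model(split.subset(feats), seed=_derived_seed(seed, count, rep, 1))
            rows.append(
                {"feature_count": count, "replicate": rep, "subset": ",".join(feats), "accuracy": run.accuracy}
            )
    return SubsetSweepResult(results=pd.DataFrame(rows))


@dataclass
class SelectionTrace:
    """Greedy feature ordering with per-step accuracies and the stored
    per-candidate evaluations that justify each choice."""

    mode: str  # "maximal" | "minimal"
    ordered_features: list[str]
    mean_accuracy_at_step: list[float]
    evaluations: list[dict[str, float]] = field(default_factory=list)  # per step: candidate -> mean acc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.ordered_features) + 1),
                "feature": self.ordered_features,
                "mean_accuracy": self.mean_accuracy_at_step,
            }
        )


def greedy_selection(
    split: SplitDataset,
    mode: str = "maximal",
    reps: int = 12,
    seed: int = 0,
    max_steps: int | None = None,
) -> SelectionTrace:
    """Greedy forward ordering of all features (or the first ``max_steps``).

    Per-candidate replicate seeds derive from (seed, step, candidate index)
    so the trace is reproducible and candidates at one step share nothing
    but the frozen split.
    """
    if mode not in ("maximal", "minimal"):
        raise ValueError("mode must be 'maximal' or 'minimal'")
    names = list(split.feature_names)
    chosen: list[str] = []
    acc_at_step: list[float] = []
    evaluations: list[dict[str, float]] = []
    n_steps = len(names) if max_steps is None else min(max_steps, len(names))
    for step in range(n_steps):
        candidates = [f for f in names if f not in chosen]
        scores: dict[str, float] = {}
        for cand in candidates:
            seeds = [_derived_seed(seed, step, names.index(cand), r) for r in range(reps)]
            scores[cand] = _mean_accuracy(split, chosen + [cand], reps, seeds)
        # max()/min() return the first of equal candidates, and `candidates`
        # is in canonical order, so ties break canonically
        pick = (max if mode == "maximal" else min)(candidates, key=lambda f: scores[f])
        if list(scores.values()).count(scores[pick]) > 1:
            logger.info("greedy step %d: tie at %.4f broken by canonical order -> %s", step + 1, scores[pick], pick)
        chosen.append(pick)
        acc_at_step.append(scores[pick])
        evaluations.append(scores)
    return SelectionTrace(mode=mode, ordered_features=chosen, mean_accuracy_at_step=acc_at_step, evaluations=evaluations)
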