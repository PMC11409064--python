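"""Assembly of the 19-metric compositional profile per genome and the
between-group statistics run on those profiles.

The 19 primary metrics, in canonical order, are GC content, the 16
dinucleotide odds ratios (ApA ... TpT), and the per-genome medians of
windowed MFE and MFED. Median Z, the standard deviation of window MFED
values, and the genome length travel alongside as auxiliary columns.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composition import METRIC_NAMES, DINUCLEOTIDES, dinucleotide_odds, gc_content
from .sequence_io import Cohort
from .structure import FoldingEngine, genome_structure

logger = logging.getLogger(__name__)

N_METRICS = len(METRIC_NAMES)  # 19
AUX_NAMES = ("sd_mfed", "median_z", "length", "n_windows_used")
QUALITY_BINS = ("low", "medium", "high")


@dataclass
class CompositionProfile:
    id: str
    provenance: str
    metrics: dict[str, float]
    aux: dict[str, float] = field(default_factory=dict)
    family: str | None = None
    quality_bin: str | None = None

    def __post_init__(self) -> None:
        if tuple(self.metrics) != METRIC_NAMES:
            raise ValueError("metrics must carry exactly the 19 canonical metrics in order")

    def is_complete(self) -> bool:
        return all(math.isfinite(v) for v in self.metrics.values())


def build_profiles(
    cohorts: list[Cohort],
    engine: FoldingEngine,
    k: int = 120,
    step: int = 10,
    n_controls: int = 105,
    seed: int = 0,
) -> list[CompositionProfile]:
    """One profile per record; records failing any metric are dropped with a
    logged reason (too short for a window, undefined odds ratio, ...)."""
    profiles: list[CompositionProfile] = []
    for cohort in cohorts:
        for rec in cohort:
            if rec.length < k:
                logger.warning("dropping %s: no windows (length %d < k=%d)", rec.id, rec.length, k)
                continue
            try:
                odds = dinucleotide_odds(rec.seq)
                gc = gc_content(rec.seq)
                _, summ = genome_structure(engine, rec, k=k, step=step, n_controls=n_controls, seed=seed)
            except ValueError as exc:
                logger.warning("dropping %s: %s", rec.id, exc)
                continue
            metrics = {"gc": gc}
            metrics.update({d: odds.ratios[d] for d in DINUCLEOTIDES})
            metrics["median_mfe"] = summ.median_mfe
            metrics["median_mfed"] = summ.median_mfed
            prof = CompositionProfile(
                id=rec.id,
                provenance=rec.provenance,
                family=rec.family,
                metrics=metrics,
                aux={
                    "sd_mfed": summ.sd_mfed,
                    "median_z": summ.median_z,
                    "length": float(rec.length),
                    "n_windows_used": float(summ.n_windows_used),
                },
            )
            if not prof.is_complete():
                bad = [m for m, v in prof.metrics.items() if not math.isfinite(v)]
                logger.warning("dropping %s: non-finite metrics %s", rec.id, bad)
                continue
            profiles.append(prof)
    if not profiles:
        raise ValueError("no profiles could be built")
    return profiles


def profiles_to_frame(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Tidy DataFrame: one row per genome, metadata + 19 metrics + aux."""
    rows = []
    for p in profiles:
        row = {"id": p.id, "provenance": p.provenance, "family": p.family, "quality_bin": p.quality_bin}
        row.update(p.metrics)
        row.update({a: p.aux.get(a, np.nan) for a in AUX_NAMES})
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def write_profiles_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t")


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    u: float
    p: float
    significant_bonferroni: bool


def compare_groups(
    frame: pd.DataFrame,
    group_by: str = "provenance",
    alpha: float = 0.05,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> pd.DataFrame:
    """Two-tailed Mann–Whitney U per metric for every group pair.

    The Bonferroni threshold is alpha / 19 (the metric count) regardless of
    the number of group pairs, i.e. 0.05/19 < 0.0026 at the default alpha.
    """
    groups = [g for g, sub in frame.groupby(group_by, dropna=True) if len(sub) >= 2]
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups with >= 2 members under {group_by!r}")
    threshold = alpha / N_METRICS
    out: list[GroupComparison] = []
    for ga, gb in itertools.combinations(groups, 2):
        a = frame[frame[group_by] == ga]
        b = frame[frame[group_by] == gb]
        for m in metrics:
            u, p = stats.mannwhitneyu(a[m], b[m], alternative="two-sided", method="auto")
            out.append(
                GroupComparison(
                    metric=m, group_a=str(ga), group_b=str(gb),
                    median_a=float(a[m].median()), median_b=float(b[m].median()),
                    u=float(u), p=float(p), significant_bonferroni=bool(p < threshold),
                )
            )
    return pd.DataFrame([vars(c) for c in out])


def length_distribution_test(cohort_a, cohort_b) -> tuple[float, float]:
    """Two-sample two-tailed Kolmogorov–Smirnov test on genome lengths.

    Accepts Cohorts or plain length vectors.
    """
    la = cohort_a.lengths if hasattr(cohort_a, "lengths") else np.asarray(cohort_a)
    lb = cohort_b.lengths if hasattr(cohort_b, "lengths") else np.asarray(cohort_b)
    res = stats.ks_2samp(la, lb, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bin_virus_score(score: float) -> str:
    """low: s < 0.7; medium: 0.7 <= s < 0.8; high: s >= 0.8."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"virus score must lie in [0, 1], got {score}")
    if score < 0.7:
        return "low"
    if score < 0.8:
        return "medium"
    return "high"


def bin_virus_scores(profiles: list[CompositionProfile], scores: dict[str, float]) -> list[CompositionProfile]:
    """Attach quality bins from an external virus-score table; ids without a
    score keep quality_bin unset."""
    for p in profiles:
        if p.id in scores:
            p.quality_bin = bin_virus_score(scores[p.id])
    return profiles
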