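"""End-to-end orchestration with one master seed and file artifacts.

``run_profile`` turns input (or synthetic) cohorts into the profiles table
and per-genome window tracks; ``run_analysis`` runs every downstream stage
(group comparisons, PCA geometry, clustering, classifier, feature
selection) off a profiles table. All stage seeds derive from the master
seed, so a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, pca, profiles as prof, select, synth
from .sequence_io import Cohort, filter_by_length, read_fasta, write_fasta
from .structure import ViennaEngine, genome_structure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a pipeline run; serialized alongside outputs."""

    out_dir: str = "phagecomp_out"
    natural_fasta: str | None = None
    generated_fasta: str | None = None
    synthetic: bool = True  # use the synthetic benchmark when no FASTA given
    # analysis length cut-off; the 1 kb cut used on real cohorts is a CLI/config
    # choice — the default keeps every window-bearing genome
    min_bp: int = 120
    k: int = 120
    step: int = 10
    n_controls: int = 105
    seed: int = 0
    alpha: float = 0.05
    min_members_clustering: int = 10
    min_members_centroids: int = 25
    n_replicates: int = 12
    test_fraction: float = 0.2
    write_tracks: bool = False
    sweep_counts: list[int] | None = None
    greedy_steps: int | None = None  # None = full trace

    def stage_seed(self, stage: str) -> int:
        h = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(h.generate_state(1)[0] % (2**31))

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _load_cohorts(config: RunConfig) -> tuple[list[Cohort], pd.DataFrame | None]:
    if config.natural_fasta or config.generated_fasta:
        cohorts = []
        if config.natural_fasta:
            cohorts.append(read_fasta(config.natural_fasta, provenance="natural"))
        if config.generated_fasta:
            cohorts.append(read_fasta(config.generated_fasta, provenance="generated"))
        return cohorts, None
    if not config.synthetic:
        raise ValueError("no input FASTA given and synthetic benchmark disabled")
    natural, generated, truth = synth.build_benchmark_cohorts(synth.BenchmarkConfig(seed=config.seed))
    return [natural, generated], truth


def run_profile(config: RunConfig) -> pd.DataFrame:
    """Build the profiles table (and optional per-genome tracks) on disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.json")
    cohorts, truth = _load_cohorts(config)
    cohorts = [filter_by_length(c, min_bp=config.min_bp) for c in cohorts]
    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t")
        for c in cohorts:
            write_fasta(c, out / f"cohort_{c.label}.fasta")
    engine = ViennaEngine()
    plist = prof.build_profiles(
        cohorts, engine, k=config.k, step=config.step,
        n_controls=config.n_controls, seed=config.stage_seed("structure"),
    )
    frame = prof.profiles_to_frame(plist)
    prof.write_profiles_tsv(frame, out / "profiles.tsv")
    if config.write_tracks:
        with open(out / "tracks.tsv", "w") as fh:
            fh.write("id\tmidpoint\tmfe\tmfed\tz\n")
            for c in cohorts:
                for rec in c:
                    if rec.length < config.k:
                        continue
                    track, _ = genome_structure(
                        engine, rec, k=config.k, step=config.step,
                        n_controls=config.n_controls, seed=config.stage_seed("structure"),
                    )
                    for i in range(len(track.midpoints)):
                        if not track.skipped[i]:
                            fh.write(f"{rec.id}\t{track.midpoints[i]}\t{track.mfe[i]:.2f}"
                                     f"\t{track.mfed[i]:.5f}\t{track.z[i]:.4f}\n")
    logger.info("profiles written: %d genomes", len(frame))
    return frame


def run_analysis(config: RunConfig, frame: pd.DataFrame | None = None) -> dict:
    """All downstream stages; returns a dict of the key result tables."""
    out = Path(config.out_dir)
    if frame is None:
        frame = pd.read_csv(out / "profiles.tsv", sep="\t", index_col="id")

    results: dict = {}

    comparisons = prof.compare_groups(frame, group_by="provenance", alpha=config.alpha)
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    results["comparisons"] = comparisons

    space = pca.fit_pca(frame)
    results["space"] = space
    clustering = pca.nn_clustering(space, min_members=config.min_members_clustering)
    clustering.to_csv(out / "clustering.tsv", sep="\t")
    results["clustering"] = clustering
    try:
        centroids = pca.family_centroids(space, min_members=config.min_members_centroids)
        centroids.to_csv(out / "centroid_table.tsv", sep="\t")
        results["centroids"] = centroids
    except ValueError as exc:
        logger.warning("centroid table skipped: %s", exc)
    outliers = pca.nearest_family_of_outliers(space)
    outliers.to_csv(out / "outlier_neighbors.tsv", sep="\t")
    results["outliers"] = outliers
    pca.plot_projection(space, out / "pca_projection.png", min_members=config.min_members_centroids)

    split = classify.make_split(frame, test_fraction=config.test_fraction, seed=config.stage_seed("split"))
    summary = classify.replicate_models(split, n_replicates=config.n_replicates,
                                        base_seed=config.stage_seed("classifier"))
    summary.to_frame().to_csv(out / "classifier_runs.tsv", sep="\t", index=False)
    summary.misidentified.rename("n_misidentified").to_csv(out / "misidentified.tsv", sep="\t")
    results["classifier"] = summary
    results["zeror"] = classify.zeror_benchmark(split.y)

    if config.sweep_counts:
        sweep = select.random_subset_sweep(split, counts=config.sweep_counts,
                                           seed=config.stage_seed("sweep"))
        sweep.results.to_csv(out / "subset_sweep.tsv", sep="\t", index=False)
        results["sweep"] = sweep
    if config.greedy_steps is None or config.greedy_steps > 0:
        trace = select.greedy_selection(split, mode="maximal", seed=config.stage_seed("greedy"),
                                        max_steps=config.greedy_steps)
        trace.to_frame().to_csv(out / "greedy_maximal.tsv", sep="\t", index=False)
        results["greedy"] = trace
    return results
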