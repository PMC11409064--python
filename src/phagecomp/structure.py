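"""Windowed folding-energy metrics: MFE, MFED and Z scores.

Each window's minimum free energy (MFE, kcal/mol) is compared against
permuted controls produced by Altschul–Erikson dinucleotide shuffling,
which conserves the window's exact overlapping-dinucleotide multiset. The
minimum free energy difference is

    MFED = (MFE_obs - mean(MFE_controls)) / mean(MFE_controls)

expressed as a fraction, signed so that a window more structured than
expected from its dinucleotide composition alone is positive (MFE values
are <= 0, so a more negative observed MFE makes both numerator and
denominator negative). The Z score is

    Z = (MFE_obs - mean(MFE_controls)) / sd(MFE_controls).

DNA is folded as RNA (T transliterated to U): for double-stranded genomes
the resulting values are read as measurements of nonrandom base
composition, not of physical single-strand folding.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .composition import explode_windows
from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_N_CONTROLS = 105


class FoldingEngine:
    """Deterministic thermodynamic folding backend: seq -> MFE (<= 0)."""

    name: str = "abstract"

    def mfe(self, rna_seq: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class ViennaEngine(FoldingEngine):
    """ViennaRNA secondary-structure prediction at default temperature (37 C)."""

    name = "viennarna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment guard
            raise RuntimeError(
                "folding engine 'viennarna' unavailable: the ViennaRNA Python "
                "bindings (module 'RNA') are not importable"
            ) from exc
        self._rna = RNA

    def mfe(self, rna_seq: str) -> float:
        return float(self._rna.fold(rna_seq)[1])


def fold_mfe(engine: FoldingEngine, seq: str) -> float:
    """Fold a DNA/RNA sequence (T -> U) and return the engine's MFE."""
    return engine.mfe(seq.upper().replace("T", "U"))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Uniform draw from the sequences sharing ``seq``'s dinucleotide multiset.

    Altschul–Erikson construction: the sequence is an Eulerian path on the
    multigraph whose edges are its overlapping dinucleotides. A uniformly
    random arborescence toward the final character fixes each vertex's last
    outgoing edge (rejection-sampled), all other outgoing edges are
    uniformly permuted, and the path is re-walked from the first character.
    First and last characters, and hence all mono- and dinucleotide counts,
    are conserved exactly.
    """
    if len(seq) < 2:
        raise ValueError("need length >= 2")
    if "N" in seq:
        raise ValueError("cannot shuffle a sequence containing N")

    edges: dict[str, list[str]] = {}
    for x, y in zip(seq[:-1], seq[1:]):
        edges.setdefault(x, []).append(y)
    last = seq[-1]
    verts = [v for v in edges if v != last]

    # uniform arborescence toward `last` by rejection over random last-edge picks
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in verts}
        ok = True
        for v in verts:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break

    # per-vertex edge order: shuffled non-last edges, chosen last edge at the end
    order: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        idx = rng.permutation(len(pool))
        seq_edges = [pool[i] for i in idx]
        if v in last_edge:
            seq_edges.append(last_edge[v])
        order[v] = seq_edges

    out = [seq[0]]
    pos = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = order[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


class WindowMfed(NamedTuple):
    mfe: float
    mfed: float
    z: float
    flagged: bool


def window_mfed(
    engine: FoldingEngine,
    window: str,
    n_controls: int = DEFAULT_N_CONTROLS,
    rng: np.random.Generator | None = None,
) -> WindowMfed:
    """MFE, MFED and Z for one window against dinucleotide-shuffled controls.

    Degenerate windows whose controls have (near-)zero mean MFE get MFED=0,
    and zero control spread gives Z=0; both are flagged.
    """
    if n_controls < 2:
        raise ValueError("n_controls must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    mfe_obs = fold_mfe(engine, window)
    ctrl = np.array([fold_mfe(engine, dinucleotide_shuffle(window, rng)) for _ in range(n_controls)])
    mu = float(ctrl.mean())
    sd = float(ctrl.std(ddof=1))
    flagged = False
    if abs(mu) < 1e-9:
        mfed, flagged = 0.0, True
    else:
        mfed = (mfe_obs - mu) / mu
    if sd == 0.0:
        z, flagged = 0.0, True
    else:
        z = (mfe_obs - mu) / sd
    return WindowMfed(mfe=mfe_obs, mfed=mfed, z=z, flagged=flagged)


@dataclass
class WindowStructureTrack:
    """Per-window positions and folding metrics along one genome."""

    id: str
    midpoints: np.ndarray
    mfe: np.ndarray
    mfed: np.ndarray
    z: np.ndarray
    skipped: np.ndarray
    flagged: np.ndarray


@dataclass
class StructureSummary:
    """Per-genome medians over the usable (non-skipped) windows."""

    median_mfe: float
    median_mfed: float
    sd_mfed: float
    median_z: float
    n_windows_used: int


def genome_rng(seed: int, genome_id: str) -> np.random.Generator:
    """One RNG stream per genome so results do not depend on cohort order."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(genome_id.encode())]))


def genome_structure(
    engine: FoldingEngine,
    rec: SequenceRecord,
    k: int = 120,
    step: int = 10,
    n_controls: int = DEFAULT_N_CONTROLS,
    seed: int = 0,
) -> tuple[WindowStructureTrack, StructureSummary]:
    """Windowed MFE/MFED/Z along a genome plus the per-genome summary."""
    ws = explode_windows(rec.seq, k=k, step=step)
    usable = [i for i in range(len(ws)) if not ws.skip[i]]
    if not usable:
        raise ValueError(f"no windows for {rec.id} (length {rec.length}, k={k})")
    rng = genome_rng(seed, rec.id)

    n = len(ws)
    mfe = np.full(n, np.nan)
    mfed = np.full(n, np.nan)
    z = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    for i in usable:
        res = window_mfed(engine, ws.window(i), n_controls=n_controls, rng=rng)
        mfe[i], mfed[i], z[i], flagged[i] = res
    track = WindowStructureTrack(
        id=rec.id, midpoints=ws.midpoints.copy(), mfe=mfe, mfed=mfed, z=z,
        skipped=ws.skip.copy(), flagged=flagged,
    )
    used = np.array(usable)
    summary = StructureSummary(
        median_mfe=float(np.median(mfe[used])),
        median_mfed=float(np.median(mfed[used])),
        sd_mfed=float(np.std(mfed[used], ddof=1)) if len(used) > 1 else 0.0,
        median_z=float(np.median(z[used])),
        n_windows_used=len(used),
    )
    return track, summary
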