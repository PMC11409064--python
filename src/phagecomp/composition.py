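"""Global composition metrics and the overlapping-window decomposition.

GC content and dinucleotide odds ratios are whole-genome quantities; the
windowed decomposition (default 120 bp windows, 10 bp step, values assigned
to the window midpoint) feeds the folding-energy metrics.

The dinucleotide odds ratio for an ordered pair XpY is

    ratio(XpY) = f(XpY) / (f(X) * f(Y))

with f(XpY) the frequency of the pair among all overlapping adjacent pairs
whose two bases are both unambiguous, and f(X) the mononucleotide frequency
over the unambiguous bases of the same (whole) sequence. A ratio below 1
indicates suppression of the pair, above 1 over-representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

NUCLEOTIDES = "ACGT"
#: the 16 ordered dinucleotides in canonical (ApA ... TpT) order
DINUCLEOTIDES = tuple(f"{x}p{y}" for x in NUCLEOTIDES for y in NUCLEOTIDES)
#: canonical order of the 19 per-genome compositional metrics
METRIC_NAMES = ("gc",) + DINUCLEOTIDES + ("median_mfe", "median_mfed")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NUCLEOTIDES):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a normalized sequence to int codes A=0 C=1 G=2 T=3, N=-1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_content(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N excluded from both sides."""
    codes = encode(seq)
    counts = np.bincount(codes[codes >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous bases")
    return float((counts[1] + counts[2]) / total)


@dataclass(frozen=True)
class DinucleotideOdds:
    """Observed/expected ratios for the 16 ordered dinucleotides.

    ``ratios`` maps e.g. "CpG" to its odds ratio; a ratio is 0.0 when the
    pair was never observed but both mononucleotides occur, and NaN when
    the expected frequency is zero (degenerate input), which is distinct
    from mere non-observation.
    """

    ratios: dict[str, float]
    mono_freqs: dict[str, float]
    n_pairs: int

    def is_complete(self) -> bool:
        return all(math.isfinite(v) for v in self.ratios.values())


def dinucleotide_odds(seq: str) -> DinucleotideOdds:
    """Odds ratios over all overlapping adjacent pairs (linear, no wrap).

    Pairs spanning an N are excluded; mononucleotide frequencies are taken
    over all unambiguous bases of the whole sequence.
    """
    codes = encode(seq)
    valid = codes >= 0
    mono_counts = np.bincount(codes[valid], minlength=4)
    if mono_counts.sum() < 2:
        raise ValueError("need at least 2 unambiguous bases")
    mono = mono_counts / mono_counts.sum()

    a, b = codes[:-1], codes[1:]
    pair_ok = (a >= 0) & (b >= 0)
    n_pairs = int(pair_ok.sum())
    pair_counts = np.bincount((a[pair_ok] * 4 + b[pair_ok]).astype(np.int64), minlength=16)
    f_pair = pair_counts / n_pairs if n_pairs else np.zeros(16)

    ratios: dict[str, float] = {}
    for i, x in enumerate(NUCLEOTIDES):
        for j, y in enumerate(NUCLEOTIDES):
            expected = mono[i] * mono[j]
            name = f"{x}p{y}"
            if expected == 0.0:
                ratios[name] = float("nan")
            else:
                ratios[name] = float(f_pair[i * 4 + j] / expected)
    return DinucleotideOdds(
        ratios=ratios,
        mono_freqs={c: float(mono[i]) for i, c in enumerate(NUCLEOTIDES)},
        n_pairs=n_pairs,
    )


@dataclass
class WindowSet:
    """Overlapping fixed-length windows over one sequence.

    Window i starts at ``starts[i]`` and its value is assigned to the
    midpoint ``starts[i] + k // 2`` (0-based). Windows containing any N are
    retained but flagged ``skip``.
    """

    seq: str
    k: int
    step: int
    starts: np.ndarray
    midpoints: np.ndarray
    skip: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    def window(self, i: int) -> str:
        s = int(self.starts[i])
        return self.seq[s : s + self.k]

    def windows(self):
        for i in range(len(self)):
            yield self.window(i)


def explode_windows(seq: str, k: int = 120, step: int = 10) -> WindowSet:
    """floor((L - k)/step) + 1 windows for L >= k; none otherwise."""
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    L = len(seq)
    if L < k:
        starts = np.empty(0, dtype=np.int64)
    else:
        starts = np.arange(0, L - k + 1, step, dtype=np.int64)
    # cumulative N count for O(1) per-window ambiguity check
    codes = encode(seq)
    has_n = np.concatenate([[0], np.cumsum(codes < 0)])
    skip = np.array([has_n[s + k] - has_n[s] > 0 for s in starts], dtype=bool)
    return WindowSet(seq=seq, k=k, step=step, starts=starts, midpoints=starts + k // 2, skip=skip)
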