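from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from phagecomp.sequence_io import SequenceRecord
from phagecomp.structure import (
    dinucleotide_shuffle,
    fold_mfe,
    genome_rng,
    genome_structure,
    window_mfed,
)


def dinuc_counts(seq: str) -> Counter:
    return Counter(zip(seq[:-1], seq[1:]))


def enumerate_shuffles(seq: str) -> set[str]:
    """Brute-force: all distinct sequences sharing seq's dinucleotide multiset."""
    edges = Counter(zip(seq[:-1], seq[1:]))
    out: set[str] = set()

    def walk(cur: str, remaining: Counter, acc: list[str]) -> None:
        if sum(remaining.values()) == 0:
            out.add("".join(acc))
            return
        for (x, y), c in list(remaining.items()):
            if x == cur and c > 0:
                remaining[(x, y)] -= 1
                acc.append(y)
                walk(y, remaining, acc)
                acc.pop()
                remaining[(x, y)] += 1

    walk(seq[0], edges, [seq[0]])
    return out


def test_shuffle_fixed_point():
    rng = np.random.default_rng(0)
    assert dinucleotide_shuffle("AAAA", rng) == "AAAA"


def test_shuffle_rejects_bad_input():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        dinucleotide_shuffle("A", rng)
    with pytest.raises(ValueError):
        dinucleotide_shuffle("ACNGT", rng)


@given(st.text(alphabet="ACGT", min_size=2, max_size=60), st.integers(0, 2**31 - 1))
def test_shuffle_preserves_dinucleotide_multiset(seq, seed):
    shuffled = dinucleotide_shuffle(seq, np.random.default_rng(seed))
    assert dinuc_counts(shuffled) == dinuc_counts(seq)
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


def test_shuffle_uniform_over_enumerated_outcomes():
    """Empirical shuffle distribution matches the brute-force outcome set."""
    seq = "AACGTACGGT"
    outcomes = enumerate_shuffles(seq)
    assert seq in outcomes and len(outcomes) > 1
    rng = np.random.default_rng(1234)
    n = 10_000
    observed = Counter(dinucleotide_shuffle(seq, rng) for _ in range(n))
    assert set(observed) <= outcomes
    counts = [observed.get(o, 0) for o in sorted(outcomes)]
    chi = stats.chisquare(counts)
    assert chi.pvalue > 1e-3


def test_fold_mfe_examples(engine):
    assert fold_mfe(engine, "A" * 12) == 0.0
    assert fold_mfe(engine, "GGGGGAAAAACCCCC") < 0.0


@given(st.text(alphabet="ACGT", min_size=5, max_size=60))
def test_fold_mfe_never_positive(engine, seq):
    assert fold_mfe(engine, seq) <= 0.0


def test_fold_mfe_deterministic_and_dna_as_rna(engine):
    s = "GGGGCATCAGTACCCC"
    assert fold_mfe(engine, s) == fold_mfe(engine, s)
    assert fold_mfe(engine, s) == fold_mfe(engine, s.replace("T", "U"))


def test_window_mfed_degenerate_window_flagged(engine):
    res = window_mfed(engine, "A" * 60, n_controls=5, rng=np.random.default_rng(0))
    assert res.mfe == 0.0 and res.mfed == 0.0 and res.z == 0.0 and res.flagged


def test_window_mfed_planted_hairpin(engine):
    """A strong inverted repeat gives MFED > 0 (more structured than its
    dinucleotide-preserving controls) and Z < 0."""
    rng = np.random.default_rng(7)
    flank5 = "".join(rng.choice(list("ACGT"), size=40))
    flank3 = "".join(rng.choice(list("ACGT"), size=34))
    stem = "".join(rng.choice(list("ACGT"), size=20))
    comp = stem.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    window = flank5 + stem + "AATTAA" + comp + flank3
    assert len(window) == 120
    res = window_mfed(engine, window, n_controls=25, rng=rng)
    assert res.mfed > 0.0
    assert res.z < 0.0
    assert not res.flagged


def test_genome_structure_track_and_summary(engine):
    rng = np.random.default_rng(3)
    rec = SequenceRecord("g1", "".join(rng.choice(list("ACGT"), size=130)), "natural")
    track, summary = genome_structure(engine, rec, k=120, step=10, n_controls=5, seed=1)
    assert len(track.midpoints) == 2
    assert summary.n_windows_used == 2
    assert np.isfinite(track.mfed).all()


def test_genome_structure_requires_a_window(engine):
    rec = SequenceRecord("short", "ACGT" * 10, "natural")
    with pytest.raises(ValueError, match="no windows"):
        genome_structure(engine, rec, k=120, step=10, n_controls=5, seed=1)


def test_genome_structure_deterministic_per_seed(engine):
    rng = np.random.default_rng(9)
    rec = SequenceRecord("g2", "".join(rng.choice(list("ACGT"), size=150)), "natural")
    t1, s1 = genome_structure(engine, rec, k=120, step=10, n_controls=5, seed=11)
    t2, s2 = genome_structure(engine, rec, k=120, step=10, n_controls=5, seed=11)
    np.testing.assert_array_equal(t1.mfed, t2.mfed)
    np.testing.assert_array_equal(t1.z, t2.z)
    assert s1 == s2


def test_genome_rng_depends_on_id_not_order():
    a1 = genome_rng(5, "genomeA").random(4)
    b = genome_rng(5, "genomeB").random(4)
    a2 = genome_rng(5, "genomeA").random(4)
    np.testing.assert_array_equal(a1, a2)
    assert not np.array_equal(a1, b)


def test_skipped_windows_carry_no_values(engine):
    seq = "ACGT" * 35 + "N" + "ACGT" * 35  # N in the middle
    rec = SequenceRecord("gN", seq, "natural")
    track, summary = genome_structure(engine, rec, k=120, step=20, n_controls=5, seed=2)
    assert track.skipped.any() and not track.skipped.all()
    assert np.isnan(track.mfe[track.skipped]).all()
    assert summary.n_windows_used == int((~track.skipped).sum())
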