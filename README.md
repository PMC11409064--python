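# phagecomp

Compositional profiling of bacteriophage genome cohorts, and detection of
sequences produced by generative sequence models.

Generative language models can now emit whole phage-genome-like sequences,
but natural genomes carry strong, family-structured compositional biases —
GC content, dinucleotide usage, and local base-pairing potential — that a
generator may fail to reproduce. `phagecomp` quantifies those biases per
genome, maps cohorts into a weighted principal-component space to measure
family clustering, and trains replicate neural networks to ask whether
provenance (natural vs. model-generated) is detectable from composition
alone.

## The metrics

Each genome is reduced to 19 compositional metrics:

- **GC content** — (G + C) / (A + C + G + T), ambiguous bases excluded.
- **16 dinucleotide odds ratios** — for each ordered pair XpY,
  `ratio(XpY) = f(XpY) / (f(X) · f(Y))`, observed over expected among all
  overlapping adjacent pairs; < 1 means suppression (e.g. CpG suppression),
  > 1 over-representation.
- **median MFE** — the genome is exploded into overlapping windows
  (120 bp, step 10 by default), each folded as RNA (ViennaRNA) to its
  minimum free energy (kcal/mol); the per-genome median is reported.
- **median MFED** — per window, the MFE is compared with permuted controls
  produced by Altschul–Erikson dinucleotide shuffling (exactly conserving
  the window's dinucleotide multiset):
  `MFED = (MFE_obs − mean MFE_controls) / mean MFE_controls`, positive when
  the window is more structured than expected from dinucleotide composition
  alone. A per-window Z score `(MFE_obs − μ_controls)/σ_controls` travels
  alongside.

Downstream, PCA is fitted on the scaled metric matrix; distances use
per-component variance-share weighting, family clustering is scored by
nearest-neighbour agreement against the `N_f / N` binomial null, and a
19→32→16→1 ReLU/sigmoid network (Adam, binary cross-entropy, 10 epochs,
batch 32, frozen 80:20 split, 12 replicates) discriminates provenance,
benchmarked against ZeroR majority voting and dissected by random-subset
sweeps and greedy forward feature selection.

A first-order-Markov synthetic generator (with family-specific dinucleotide
signatures, tunable GC, and inverted-repeat cassettes for MFED enrichment)
makes the whole pipeline testable without downloading any sequence data.

## Worked example

```python
import numpy as np
from phagecomp import (BenchmarkConfig, build_benchmark_cohorts, build_profiles,
                       profiles_to_frame, fit_pca, nn_clustering,
                       make_split, replicate_models, zeror_benchmark, ViennaEngine)

natural, generated, truth = build_benchmark_cohorts(BenchmarkConfig(seed=20240918))
profiles = build_profiles([natural, generated], ViennaEngine(),
                          k=120, step=250, n_controls=25, seed=20240918)
frame = profiles_to_frame(profiles)
print(frame.groupby("provenance")[["gc", "median_mfe", "median_mfed"]].median())

rates = nn_clustering(fit_pca(frame), min_members=10)
print(rates[["cluster_rate", "expected_rate"]])

split = make_split(frame, seed=101)
runs = replicate_models(split, n_replicates=12, base_seed=202)
print(f"median accuracy {runs.median_accuracy:.3f} vs ZeroR {zeror_benchmark(split.y):.3f}")
```

prints (exactly, for these seeds):

```
                  gc  median_mfe  median_mfed
provenance
generated   0.389301      -20.75    -0.014281
natural     0.499388      -30.60     0.012757
                       cluster_rate  expected_rate
family
Alphasynviridae            0.933333           0.15
Betasynviridae             1.000000           0.15
Deltasynviridae            0.966667           0.15
Epsilonsynviridae          1.000000           0.15
Gammasynviridae            0.966667           0.15
transformer-generated      0.880000           0.25
median accuracy 0.850 vs ZeroR 0.750
```

Read: the generated-like cohort is ~11 GC points poorer, folds ~10 kcal/mol
weaker per 120-bp window, and has median MFED at or below zero while the
natural-like cohort is positive (more secondary structure than its
dinucleotide composition predicts). Every family — and the generated cohort
itself — clusters in the weighted PC space far above the random-association
null, and the classifier's median accuracy beats majority-class voting by
10 points on a 200-genome benchmark.

The same stages are available from a shell:

```bash
phagecomp synth --out synth_out --seed 3          # write benchmark FASTA + truth
phagecomp all --out run_out --seed 3 --step 250 --n-controls 25 --greedy-steps 1
```

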