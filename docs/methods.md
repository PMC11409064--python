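# Methods

## Scope and model

`phagecomp` treats a genome as a linear, single-stranded 5'→3' nucleotide
string and reduces it to 19 compositional metrics: GC content, the 16
ordered dinucleotide odds ratios, and the per-genome medians of windowed
MFE and MFED. Downstream stages — rank-sum group comparisons, a
weighted-PCA family geometry, and a replicate feed-forward classifier —
operate only on that 19-vector (plus metadata), never on the raw sequence.

Sequences are normalized on read: uppercase, U→T, and any other character
collapses to N. Dinucleotide pairs spanning an N are excluded from counts;
windows containing an N are retained in the window set but flagged and
skipped by the folding metrics. Mononucleotide frequencies for the odds
denominator come from the whole genome, not per window. An odds ratio with
a zero expected frequency (a mononucleotide entirely absent) is reported as
missing, which removes that genome from the multivariate stages with a
logged reason — real phage genomes never trigger this; only degenerate
synthetic inputs do.

## Windowed folding metrics

Windows are `floor((L − k)/step) + 1` exact k-mers (defaults k = 120 bp,
step = 10 bp), each metric value assigned to the window midpoint
`start + k//2` (0-based). Each window is folded as RNA by ViennaRNA at the
engine's default temperature (37 °C) and parameter set; dsDNA genomes are
folded the same way, and the resulting MFE/MFED values are read as
measurements of nonrandom base composition rather than physical
single-strand folding.

The MFED null uses Altschul–Erikson dinucleotide shuffling, implemented
here as the classic Eulerian-path construction: a uniformly random
arborescence toward the final character (rejection-sampled, which is exact)
fixes each vertex's last outgoing edge, the remaining edges are uniformly
permuted, and the path is re-walked. This conserves the window's
overlapping-dinucleotide multiset exactly (hence also its mononucleotide
counts and terminal characters), and samples uniformly from that class; a
test verifies uniformity against brute-force enumeration of the class.

With control mean μ and standard deviation σ (ddof = 1) over `n_controls`
shuffled-and-folded windows:

    MFED = (MFE_obs − μ) / μ        (a fraction; positive = more structured)
    Z    = (MFE_obs − μ) / σ

Degenerate windows (|μ| < 1e−9, or σ = 0) get MFED = 0 / Z = 0 and a flag.
The default `n_controls` is 105; it is configurable downward for desk-scale
work. Reducing the control count inflates each window's MFED noise by
~1/sqrt(n_controls) but leaves it unbiased, so per-genome medians shift
only within the Monte-Carlo noise of the window median (a few hundredths
at tens of windows per genome); the test suite uses 25 controls on that
basis, with the null-calibration test pinning down the absence of bias. Per-genome RNG streams are derived from
(seed, CRC32 of the genome id), so results are independent of cohort order.

A practical note on calibration experiments: windows taken at step 10
overlap by 110/120 bp, so the effective number of independent windows is
roughly L/k, not L/step. Null-calibration checks therefore use *disjoint*
windows; with overlapping windows the Monte-Carlo error of the mean is
several times larger than a naive n-window calculation suggests.

## Group statistics

Between-group comparisons use two-tailed Mann–Whitney U tests (SciPy's
`method="auto"`: exact for small untied samples, continuity-corrected
normal otherwise). The Bonferroni threshold is α/19 — the metric count,
fixed regardless of how many group pairs are tested — giving the 0.0026
cut-off at α = 0.05. Length distributions are compared with the two-sample
Kolmogorov–Smirnov test. External per-sequence virus scores can be binned
into low (< 0.7), medium ([0.7, 0.8)) and high (≥ 0.8) quality classes.

## Weighted PCA geometry

PCA is fitted on all genomes after centering and unit-variance scaling
(SVD of the standardized matrix; loadings orthonormal, variance shares
nonincreasing). Distances are Euclidean after multiplying each PC
coordinate by that component's variance share. This weighting — rather than
truncating components by a Kaiser or scree rule — lets high-variance
components dominate the geometry smoothly. Family centroids are
per-component means; the centroid table reports each qualifying family's
(≥ 25 members) distance to the generated pseudo-family centroid,
within-family member-to-centroid distance percentiles (10th/50th/90th), and
the cumulative distance to all other qualifying centroids, with the
generated pseudo-family included among "other centroids".

Nearest-neighbour clustering uses each point's single nearest neighbour
(k = 1) in the weighted space, exact ties resolving to the lowest row
index. The null cluster rate is N_f/N exactly (not the self-exclusion
corrected (N_f−1)/(N−1); the difference is negligible at the cohort sizes
involved), tested one-sided by a binomial test. Families below 10 members
are excluded from reporting but remain as potential neighbours.

## Classifier

Features are standardized on the **full** dataset before the 80:20 split is
drawn — this ordering leaks test-set location/scale into training and is
preserved deliberately, because it is the pipeline being characterized; the
effect on a 19-feature standardization is location/scale only, not labels.
The split is drawn once per experiment seed and frozen: every replicate and
every feature-subset model sees identical train/test genomes. The network
is p→32→16→1 (ReLU, ReLU, sigmoid), Adam at learning rate 1e−3, log-loss,
10 epochs at batch size 32, implemented with scikit-learn's MLPClassifier
(no regularization, no early stopping); predictions threshold at 0.5.
Twelve replicates differing only in initialization/shuffling seeds are
summarized by median accuracy, sensitivity (generated recall) and
specificity (natural recall), plus per-test-sequence misidentification
counts. Class imbalance is left as-is.

ZeroR (majority-class accuracy) is the baseline. Note that replicate
accuracy is measured on the test partition, whose majority fraction
deviates from the full-dataset fraction by sampling; both ZeroRs are
reported, and label-shuffle controls are compared against the
test-partition value, since that is the ceiling a majority-voting model can
reach where accuracy is measured.

Ten epochs at batch 32 means only ~n_train/32 × 10 gradient steps; at
desk-scale cohort sizes (hundreds of genomes) the network is deliberately
under-trained relative to the same recipe on thousands of genomes, which
widens replicate variance. The benchmark margins below absorb this.

## Feature selection

The random sweep trains 12 models per feature count on independently drawn
subsets, all scored on the frozen test partition. Greedy forward selection
starts from the empty set and at each step adds the feature whose addition
gives the highest (maximal mode) or lowest (minimal mode) mean accuracy
over 12 replicates; ties break on canonical metric order; per-candidate
seeds derive from (seed, step, feature index). The stored per-candidate
evaluations let tests assert local optimality directly. Greedy order is
locally optimal only, by construction.

## Synthetic cohorts

First-order Markov chains are the minimal generator able to realize
arbitrary dinucleotide odds targets. `transition_from_targets` builds the
stationary joint dinucleotide distribution by pinning targeted entries at
π_x·π_y·target and alternately rescaling the free entries to restore both
marginals (iterative proportional projection, tolerance 1e−3), with GC
entering through π (A=T, C=G). Infeasible target sets raise with the
residual. MFED enrichment is engineered by overwriting the chain with
inverted-repeat cassettes (stem + loop + reverse-complement stem, default
20 + 8 + 20 bp) at uniform non-overlapping positions — *overwriting* rather
than inserting keeps the sampled length model exact. MFED responds to
base-pairing potential, which dinucleotide-preserving shuffles do not
conserve, so cassettes raise MFED without moving the odds ratios
appreciably.

### Benchmark defaults and what they emulate

The default benchmark is 5 natural-like families × 30 genomes + 50
generated-like genomes. Families carry distinct signatures (GC 0.45–0.55;
CpG odds 0.5–1.5; TpA odds 1.35–0.55) and hairpin rate 2/kb; the
generated-like cohort uses the *across-family mean* odds targets at GC
0.392 with no hairpins — emulating a generator that averages the
compositional pressures of its training families and fails to learn local
base-pairing. Genome lengths are lognormal with medians ~2 kb
(natural-like) and ~1.03 kb (generated-like), preserving a ~1.9× length
ratio. Realized cohort medians at the default seeds: GC 0.499 vs 0.389,
window MFE −30.6 vs −20.8 kcal/mol, median MFED +0.013 vs −0.014.

Problem sizes are desk-scale choices: profile building uses step 250 and
25 controls (≈6 windows per 2-kb genome), so per-genome MFED medians are
much noisier than with step-10 windowing on full-length genomes. Two
consequences, both expected and visible in the outputs: per-genome MFED is
a weak *marginal* discriminator at this scale (its rank-sum p-value
typically misses the Bonferroni cut even though the cohort medians differ
in sign), and the classifier leans more on GC/MFE. Also note a deliberate
property of the design: because the generated cohort sits at the mean of
symmetric family signatures, most individual dinucleotide ratios do *not*
differ marginally between cohorts — provenance separation comes from the
joint structure (GC, MFE, MFED and the PCA geometry), which is exactly the
regime the multivariate stages are for.

What the synthetic cohorts do **not** emulate: genes, promoters, genome
organization, long-range composition heterogeneity, or any token-level
behaviour of a particular generative model. Passing tests demonstrate that
the pipeline's statistics behave correctly under controlled compositional
structure, not that any particular real generator is detectable.

## Numerical and degenerate-input choices

- Window midpoint of an even-length window: `start + k//2` (0-based).
- Shuffle requires ≥ 2 bases and no N (N windows are skipped upstream).
- `mannwhitneyu(method="auto")`; identical samples give p = 1.
- PCA requires ≥ 20 profiles; a constant metric column raises, naming it.
- Replicate/stage seeds derive from NumPy `SeedSequence`; per-genome
  streams from (seed, CRC32(id)); everything below 2³¹.
- Hairpin placement retries up to 50× per cassette, then reduces the count
  with a warning.

## Known limitations

- Folding is ssRNA thermodynamics applied to (often dsDNA) genomes; values
  are composition statistics, not physical folding predictions.
- The MFED sign/normalization convention (fractional difference against the
  control mean, positive = more structured) is one of several in use.
- Greedy selection cost grows quadratically in feature count; the full
  19-step trace trains 2 280 models.
- The desk-scale window stride trades per-genome MFED precision for
  runtime; analyses of real cohorts should use the step-10 default.
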