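# Methods

## The labelling model

The input is a real-valued gene × cell-line matrix of CRISPR gene-effect
scores (missing entries permitted) and an annotation mapping each cell
line to one context (tissue or disease). Two pre-filters run first:
contexts with fewer than 10 cell lines are removed — a mode over fewer
lines is too noisy to be meaningful — and genes missing in strictly more
than 95% of the remaining cell lines are removed. Both cut-offs are
exposed (`min_cell_lines`, `max_missing_frac`); the 95% rule is a strict
inequality, so a gene missing in exactly 95% of lines is kept.

Each cell-line column is binarised independently with Otsu's method: a
256-bin histogram spans `[min, max]` of the column's non-missing scores,
and every interior bin edge is scored as a candidate threshold by the
between-class variance `ω₀ω₁(μ₀ − μ₁)²`, computed from exact within-bin
sums so the objective at an edge equals the exhaustive scan evaluated
there. The upper edge of the winning bin is returned in score units.
Scores strictly below the threshold give an `E` partial label, scores at
or above it `NE` — the boundary goes to the majority class as the
conservative choice. Missing scores produce missing partial labels and
never enter the threshold estimate. A constant column carries no
separation evidence: every gene gets `NE` and a warning is logged, rather
than failing the whole context.

A gene's context label is the mode of its non-missing partial labels;
even splits resolve to `NE`, so `E` requires a strict majority of cell
lines. Genes with no usable score in a context are omitted from that
context's assignment (they reappear if another context covers them).

Common essential genes are computed as a mode *over contexts*: every
context is labelled as above, and a gene is a cEG when it is `E` in a
strict majority of contexts. Aggregating at the context level — rather
than pooling all cell lines — makes the result invariant to how many cell
lines each tissue happens to have; duplicating a cell line can change a
single context's labels but never the two-level mode. Subtracting the
cEGs from a context's `E` set yields the ucsEGs, the genes essential in
that context but not across the organism.

The three-class refinement keeps the `E` set fixed and re-runs the same
per-cell-line thresholding on the scores of the genes whose *final*
context label is `NE`. (Restricting instead by per-cell-line partial
labels would be an equally plausible design; the final-label reading is
implemented because it applies one consistent gene set to every column.) Partial labels below the second
threshold are `aE`, at or above it `sNE`; the mode with ties to `sNE`
gives the final split, so `E ∪ aE ∪ sNE` partitions the labelled genes.

### Numerical choices

- 256 histogram bins: the canonical image-processing resolution; the
  threshold quantisation error is bounded by `range/256`, and tests
  compare against an exhaustive midpoint scan at that tolerance.
- Mode computations only ever face binary alphabets (`E/NE`, `aE/sNE`),
  so "ties" are exactly even splits.

## Network embeddings

Topological gene features come from a weighted, undirected
protein-interaction network (STRING-style combined scores; edges below
0.5 confidence are filtered, scores on a 0–1000 scale are divided by
1000). Walks follow the second-order biased scheme: from a step `t → v`,
the unnormalised probability of moving to `x` is `w(v,x)/p` if `x = t`,
`w(v,x)` if `x` is a neighbour of `t`, and `w(v,x)/q` otherwise. Edge
confidences are used as walk weights — they are already trusted by the
filter, so discarding them would waste information. Defaults are the
original recipe for this family of methods: 128 dimensions, walk length
80, 10 walks per node, window 10, `p = q = 1`, 5 epochs.

The skip-gram objective with 5 negative samples per pair (noise drawn
from the unigram^0.75 distribution) is optimised by pair-wise SGD with a
linearly decaying learning rate (0.025 → ~0), JIT-compiled with numba.
Training is seeded end to end: same graph, config and seed give a
bit-identical embedding table. Isolated nodes never appear in an edge
list and are therefore absent from the table.

## Feature assembly and pre-processing

Feature tables carry a group tag (`Bio`, `CCcfs`, `N2V`). Assembly joins
the selected tables on gene symbol (the join key throughout the package;
`"SYMBOL (ENTREZ)"` header tokens are reduced to the symbol on read) and
keeps the genes that are labelled and carry at least one attribute;
labelled genes with no attributes cannot be predicted and are logged.
Constant attributes are removed. Remaining missing values are imputed
with per-column medians — robust to the heavy-tailed count attributes
typical of the `Bio` group — and `Bio`/`CCcfs` columns are z-scored.
`N2V` columns are exempt from scaling: embedding coordinates share a
common scale by construction and their geometry is the signal.

All statistics (medians, means, standard deviations, the constant-column
test) are computed on an explicit fitting subset and applied unchanged to
held-out rows. Inside cross-validation they are refit on the training
folds of every split, so no information leaks from the evaluation fold.
Whether the original analysis scaled globally or per fold is not
documented; per-fold fitting is the defensible choice and may shift
metrics slightly relative to global scaling.

## The Splitting Voting Ensemble

Essential genes are ~7% of the genome, so a single classifier trained on
the raw data buys specificity with sensitivity. The SVE partitions the
majority-class training rows into `n = max(1, ⌊N_maj/N_min⌋)` slices —
this choice makes every slice approximately minority-sized, i.e. every
member trains on a roughly balanced set; it is overridable via
`n_override`. Rows are shuffled with the run seed and dealt round-robin,
so slices are disjoint, exhaustive and within one row of equal size.
Member `i` trains on slice `i` plus *all* minority rows; the ensemble
probability is the exact arithmetic mean of the members' class-1
probabilities, and hard labels use a 0.5 threshold with the boundary
assigned to the positive class. With `n = 1` the ensemble is identical to
its base learner trained on the full set.

The base learner is a pluggable sklearn-style classifier; the default is
LightGBM with library defaults, single-threaded and seeded. Tuned
hyper-parameters can be passed through `SVEConfig.base_params`. Note that
LightGBM's `min_child_samples` default (20) prevents any split on very
small member training sets; small-sample uses should lower it.

## Cross-validation harness

Validation is k-fold stratified CV (default `k = 5`) repeated for
`rounds` rounds (default 10). Round `r` derives its seed as
`seed + r`, giving a different random partition per round,
reproducibly. Within a round every gene is predicted exactly once while
held out, so per-gene probability means/sds over rounds are well defined.
Metrics (BA, Sensitivity, Specificity, ROC-AUC with midrank ties, MCC)
are computed on the pooled confusion of each round and then averaged over
rounds; an MCC with a vanishing denominator is reported as missing rather
than zero. The subset TPR — the fraction of a user-supplied gene set
predicted essential while held out — defaults to the first round and can
also be averaged over rounds; subset genes absent from the model matrix
are excluded from the denominator and logged.

## Synthetic data

The generator emulates the *shape* of a gene-effect screen, not its
covariance: per context, essential genes draw scores i.i.d. from
`N(−1.5, 0.3²)` and the rest from `N(0, 0.2²)` — two clearly separated
modes, as the large screens show after quality control — with 7%
essential genes (the prevalence reported for genome-wide screens),
three contexts of 30/20/10 cell lines, 5% missing entries placed
uniformly, and 80% of each context's essential set shared across all
contexts so that the remaining 20% are planted ucsEGs with a known
answer. An optional `aE` layer inserts an intermediate mode (default
`N(−0.8, 0.1²)`) inside the non-essential class. An overlapping-modes
configuration is available for stress tests by narrowing the gap.

Because scores are i.i.d. and the modes are separated by many standard
deviations, labelling recovery on these defaults is essentially perfect;
passing tests therefore demonstrates the correctness of the thresholding
and aggregation machinery, *not* performance on real screens, where
scores are noisier, correlated across cell lines, and the two modes
overlap. The same caveat applies to the classifier benchmarks: the
feature generator produces class-conditional Gaussians with a chosen
shift, so CV metrics measure the harness and the ensemble mechanics, not
attainable real-data accuracy.

The graph generator plants `n_blocks` communities (planted-partition
model, `p_in = 0.3`, `p_out = 0.01`, Uniform(0.5, 1) confidences) with
the block encoded in the node id, giving the embedding tests an
unambiguous community-separation target.

## Problem sizes and determinism

Test and acceptance runs use desk-scale inputs — 2,000–3,000 genes,
tens of cell lines, a 100-node graph — chosen so the full pipeline and
its repetitions complete in minutes on one CPU while every structural
property (partitions, modes, slices, fold coverage) is exercised at
realistic class ratios. Every stochastic stage (score/feature/graph
generation, walk simulation, skip-gram SGD, slice assignment, fold
partitions) consumes a seed derived from one run-level seed; two runs
with the same configuration and seed produce byte-identical label files
and identical metric tables.

## Known limitations

- Symbol-based gene joining: no Entrez↔symbol mapping beyond stripping
  the `"(ENTREZ)"` suffix; identifier drift between score, network and
  feature sources must be resolved upstream.
- The labelling has no notion of screen quality or batch effects; it
  trusts the score matrix as given.
- The skip-gram trainer is single-threaded by design (determinism over
  speed); graphs with millions of edges will be slow and are better
  embedded once and cached via `helpess embed`.
- `label_common` weights every context equally regardless of its
  cell-line count; that is intentional (it is what removes the size
  bias) but means a 10-line tissue counts as much as a 30-line one.
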