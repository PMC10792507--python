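# Methods

## Scope and model of the data

`degcompare` operates on differential-expression *result tables*: one
row per gene with a log2 fold change (logFC) and an FDR-adjusted
p-value (padj), as exported by limma's `topTable` or DESeq2's
`results`. All upstream processing — normalization, model fitting,
multiple-testing correction — is assumed done, and done as uniformly as
practical per platform. Genes absent from a platform are *missing
cells* in the woven master table; a measured gene whose padj was
reported NA upstream (e.g. DESeq2 independent filtering) is kept and
simply can never be called significant. Rows whose logFC itself is NA
are dropped at read time with a warning: such genes are effectively
unmeasured, and treating them so keeps the missing-cell semantics
single-valued (a cell is missing if and only if its logFC is missing).

## DEG calling

A gene is a DEG in experiment i when padj < α (default α = 0.05,
strict inequality; an inclusive ≤ variant is selectable) and |logFC| ≥
a floor that defaults to 0, i.e. significance alone decides by default.
Experiments with zero DEGs at the threshold are dropped from the set
with a warning; lists with fewer than 10 DEGs are retained but flagged,
since ratio indicators on tiny lists are dominated by single genes.
Duplicated gene IDs in one input file are an error by default; an
opt-in rule collapses them keeping the smallest padj (ties: largest
|logFC|, then first occurrence).

## Indicators

With m retained lists and union size N: n_i, the specific count s_i
(DEGs in no other list), δ_i = s_i/n_i, and R_i = δ_i/(n_i/N).
Specificity is defined *relative to the current set*: adding or
removing one experiment changes s, δ and R for every other experiment.
Lists dropped at DEG calling are excluded from N and from specificity.
The similarity index is the overlap coefficient
I = c/(c + min(a, b)); matrix entries are stored at full precision and
rounded to two decimals only for display. No significance is attached
to pairwise overlaps — I is descriptive.

## Clustering

Distances are computed in log2FC space ignoring significance, after two
preprocessing steps in fixed order: per-experiment min-max scaling to
[0, 1] ("normalized to the range"; a divide-by-span alternative is
selectable), then per-gene standardization to mean 0, SD 1 (population
SD; rows with spread below 1e−9 are set to zero rather than amplifying
numerical noise). The gene universe defaults to the union DEGs; an
all-complete-genes scope is available because significance is
deliberately not part of the distance. Genes with a missing logFC in
any experiment are dropped, never imputed — cross-platform universes
make imputation unjustifiable — and the dropped count is logged.
Agglomeration is Ward.D2 (SciPy's `ward` on Euclidean distances):
merge the pair of clusters whose fusion minimally increases the total
within-cluster sum of squares; merge heights are therefore monotone.
Bootstrap support resamples *genes* with replacement (experiments are
the objects being clustered), reclusters the same preprocessed matrix,
and scores each internal node by the fraction of replicates containing
the same leaf bipartition (a bipartition is identified with the smaller
of the node's leaf set and its complement). Default 1,000 replicates.

## Homogeneity test

For each subsample size k from m−1 down to 1, each of `iterations`
rounds (default 5,000) draws two independent pseudo-samples with
replacement — one of k lists, one of m lists — and records
d = N_m − N_k, the difference of union sizes. Percentile bounds at
coverage `ci_level` (default 0.95) are the inclusive empirical order
statistics (lower rank floored, upper rank ceiled); with 5,000 samples
the estimator choice is immaterial but it is pinned for
bit-reproducibility. A k is significant when the interval excludes 0;
the verdict is heterogeneous when any tested k is significant, and a
restricted sweep scopes the verdict to the tested k values.

Randomness comes from one root seed; the stream for each k is derived
as a k-indexed substream, so restricting or reordering the sweep never
changes the numbers at any individual k. The two pseudo-samples in a
round share no draws.

Union sizes are computed on a pattern-compressed representation: union
genes are grouped by their membership pattern across the m lists, so
each union size is a masked sum over distinct patterns (at most 2^m,
in practice a few hundred) instead of a pass over all genes.

**Interpretation caveat.** E[N_k] grows deterministically with k even
for perfectly exchangeable lists, so at very small k the d distribution
sits far from zero for *any* non-degenerate family and the interval may
exclude 0 without any batch structure — the example in the README shows
exactly this at k = 1. The informative comparisons are at large k
(leave-few-out), where a significant drop really does mean some lists
contribute genes the others lack. Users restricting the sweep (e.g. to
k = m−1) trade sensitivity for this cleaner null behaviour. No
correction is applied across k values.

## Synthetic families

The generator emulates the statistical structure the methods probe, not
sequencing data: no dispersion model, no library sizes. A gene universe
contains a shared pool (genes responsive to the target factor in every
experiment) and optionally disjoint batch pools (responsive only within
one batch of experiments). Each eligible gene becomes a DEG per
experiment independently with its pool's inclusion probability. DEG
logFC is drawn as sign · Normal(effect_size, noise_sd) where the sign
is a per-gene fair coin fixed for the whole family — a regulated gene
responds in a consistent direction wherever it responds, which is what
makes batches coherent in fold-change space — and non-DEG logFC is
Normal(0, noise_sd). Adjusted p-values are *placed* uniformly on the
correct side of α with a 2 % margin rather than simulated from a test
statistic: the methods under test consume padj, and placement makes the
planted truth exact under both the strict and the inclusive calling
rule.

Defaults — 10,000 genes, 7 experiments, shared pool 1,000, inclusion
0.3, effect size 2.0, noise SD 0.25, α = 0.05 — describe a mid-sized
bulk compendium in which any two experiments share roughly a third of
their DEGs. What passing tests on such families shows is that the set
algebra, resampling machinery and clustering behave as designed under
controlled overlap structure; they say nothing about upstream pipeline
quality, annotation mismatches between platforms, or correlated noise
across experiments from one lab, none of which the generator models.

## Numerical and design choices

* Strict padj < α by default: the common DE-tool convention; the
  inclusive rule is one flag away.
* Output tables sort by ascending padj then gene ID (union table: by
  descending membership count then gene ID) so re-runs are
  byte-identical.
* Input delimiter is auto-detected between tab and comma from the
  header line, with an override; decimal points only.
* SVG figures pin the hash salt and omit timestamps, making vector
  output byte-stable for regression testing.
* Problem sizes in the test-suite simulations (e.g. 50 replicate
  families of 7 experiments at 500 resampling iterations) were chosen
  as the smallest sizes at which the binomial tolerances quoted in the
  tests are meaningful.

## Known limitations

* No gene-ID translation: profiles must share an annotation, or the
  overlap indicators undercount agreement.
* The homogeneity verdict aggregates over k without multiplicity
  control, and small-k significance is expected even under the null
  (see the caveat above).
* The bootstrap support convention (gene resampling, bipartition
  matching) is one of several reasonable choices; support values are
  comparable within a run, not across software.
* Similarity and specificity ignore fold-change direction; two lists
  regulated in opposite directions but overlapping in membership score
  as similar. Direction enters only through the clustering.
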