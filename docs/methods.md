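# Methods

`regage` implements an inference chain for age-associated transcriptional
regulation from two-condition ("young" vs "aged") expression data: bulk
differential expression with a concordance intersection across replicate
comparisons, ranking-based motif enrichment in two promoter windows, signed
regulon construction under an activator/repressor direction rule, per-cell
regulon activity scoring, consensus miRNA targeting across prediction
databases, and a redundancy-pruned functional-term network. All stages are
exercised end to end on synthetic data with planted ground truth.

Effect signs are reported aged-vs-young throughout: direction "up" means
higher in the aged condition.

## Bulk differential expression

Counts are normalized by median-of-ratios size factors (genes with a zero in
any sample are excluded from the geometric-mean reference), transformed to
`log2(count/sf + 0.5)`, and fit gene-wise by ordinary least squares on an
intercept + condition + batch-dummy design. The aged-vs-young contrast, its
unit standard error, the residual variance `s_g^2` and residual degrees of
freedom feed an empirical-Bayes moderation step: a scaled-F prior
(`d0`, `s0^2`) is fit by matching the first two moments of `log s_g^2`
(digamma/trigamma inversion), and posterior variances
`(d0*s0^2 + df*s^2)/(d0 + df)` give a moderated t on `d0 + df` degrees of
freedom. Zero (or negative) excess spread collapses to `d0 = infinity`
(z-test at the pooled variance); a `moderation=False` flag gives the
ordinary t (`d0 = 0`).

Significance uses BH-adjusted p < 0.01 and |log2FC| > 1 (both configurable),
followed by an abundance floor: a gene must reach median TPM >= 1 in at
least one condition (boundary inclusive). Two independent comparisons are
intersected on their significant genes; the concordance fraction is the
share of shared genes whose fold-change signs agree.

*Assumptions and calibration.* The model assumes log-transformed normalized
counts are approximately homoscedastic Gaussian per gene. For negative
binomial counts the true log-scale variance is mean-dependent
(`~ alpha + 1/mu`), which a single pooled prior cannot represent; measured
against simulation, the null probability of any BH discovery at q < 0.01 is
about 0.02 per dataset rather than the nominal 0.01 — a mild
anticonservatism that an abundance-trend prior would remove and that is
accepted here for the simplicity of a scalar prior.

## Single-cell stages

Cells are dropped when mitochondrial expression (genes with a configurable
`MT-` prefix) exceeds 15% strictly, or detected genes fall strictly below
500; a cell exactly at either boundary is kept. Differential expression
between two cell groups uses a two-sided Wilcoxon rank-sum test on
log1p depth-normalized expression, restricted to genes detected in at least
10% of either group, with `log2((mean_b + 1e-9)/(mean_a + 1e-9))` as the
fold change and BH-adjusted p < 0.05, |log2FC| > 0.25 thresholds. The exact
null distribution is used for tie-free groups of <= 10, otherwise the
normal approximation with mid-rank ties. The rank-sum test stands in for a
hurdle-model test; the thresholds and expression floor are kept as stated
above.

## Motif enrichment and regulons

Each motif in a ranking database (a motifs x genes permutation table, one
database per promoter window) is scored by the area under its recovery
curve `rc(x)` — the number of query-set genes within its top-x ranks —
summed to `max_rank = ceil(0.05 * G)` and normalized by the ideal curve of
an equally sized set, so a saturated motif scores exactly 1. The NES
standardizes AUC against all motifs of the same database (sample sd;
zero spread degrades to NES 0 with a warning). Motifs with NES > 3 are
annotated to transcription factors; target genes are the query genes above
the rank at which the motif's recovery curve deviates maximally from the
database mean + 2 sd curve (ties to the smallest rank — precision over
recall). Edges from the proximal and distal windows are merged by union,
tagged with their supporting window(s).

A candidate TF becomes a regulon only if it is itself significantly DE and
satisfies the direction rule: activators must be enriched in the gene set's
condition, repressors in the opposite condition (a repressor enriched in
aged suppresses its targets there, so its targets surface among
young-enriched genes). Regulons with fewer than 5 targets are dropped.

Per-cell activity (AUCell) reuses the identical recovery-AUC kernel on
within-cell expression rankings (descending, ties broken by a seeded random
permutation; a lexicographic mode exists for exact reproducibility).
Group activity differences use the same rank-sum machinery as above, and
the overexpression validation crosses predicted targets with
repressed/activated gene sets in a one-sided Fisher exact test
(hypergeometric upper tail; Haldane 0.5 odds-ratio correction at zero
cells).

## miRNA consensus targeting

Log-intensities are tested with the same moderation machinery (no
transform, no fold-change floor, q < 0.01). A gene is a consensus target of
a miRNA when at least `min_src = 2` of the prediction databases list it;
its aggregate rank is the geometric mean of its ranks over the databases
that contain it (no penalty padding for absent sources), sorted ascending
with lexicographic tie-break (keys rounded at 1e-9 so numerically equal
geometric means tie exactly). Summaries count, per miRNA enriched in
condition c, its consensus targets among genes enriched in the other
condition, and the coverage of those genes by the union of all such miRNAs.
Network assembly keeps miRNA->gene edges only across opposite conditions
and curated TF->miRNA edges only between entities that are both DE.

## Functional-term network

Term enrichment is a hypergeometric upper-tail test of each term's
annotated genes against the DE set within the analysis universe,
BH-adjusted and retained at q < 0.001. The activation z-score is
`(n_consistent - n_inconsistent)/sqrt(n_total)` over genes with an expected
direction. Redundant terms are pruned greedily in order of ascending p
(ties: larger |z|, then term id), accepting a term only if its Jaccard
similarity with every accepted term is <= 0.5; the sweep is idempotent.
Retained terms and their DE overlap genes form a bipartite network;
communities come from seeded Louvain modularity maximization on the largest
connected component (isolates get module 0, smaller components their own
modules), with the guarantee that the returned partition's modularity is at
least that of the all-singleton partition. The enrichment score and term
network are a transparent surrogate for proprietary pathway tools: same
thresholds, documented statistics.

## Synthetic data generator

The generator emulates every input with planted ground truth recorded in a
ledger; all outputs are a pure function of (config, seed), with each stage
drawing from a generator derived from the seed plus a fixed stage offset.

Default study conditions: 2,000 genes; 8 young vs 3 aged samples in 2
batches (balanced within condition, additive log2 batch offsets of sd
0.25); four aged repressors with 50 disjoint targets each at a 2.0 log2
effect (the TF gene itself rises in its own condition) plus 100
regulon-independent DE genes split between conditions; negative binomial
counts with baseline log2 means uniform on (5, 9) and dispersion
`alpha = 0.05` (`var = mu + alpha*mu^2`), a level typical of
well-controlled bulk designs and chosen so that planted effects are
recoverable at the stated thresholds; two 200-motif ranking databases whose
planted motifs place 90% of their regulon's targets uniformly in the top 5%
of ranks; a 200-cells-per-group overexpression experiment (dispersion 0.3,
lognormal depth variation, ten `MT-` genes carrying ~5% of counts) in which
the repressor's targets drop 4-fold, a disjoint set of 100
indirect-response genes rises mildly (effect/4) to emulate the secondary
transcriptional response, and a 5% tail of deliberate low-quality cells
(either ~55% mitochondrial or total counts below a third of the
detected-genes floor, so they must fail the filter) is appended and
ledgered; 60 miRNAs (two thirds DE at ±1.5 log2, Gaussian noise sd 0.25,
n = 4 + 4) with 40 true targets each drawn from opposite-condition DE
genes, entering each of 5 target databases with probability 0.7 at a
uniform top-half rank plus 20 decoys per database; a curated TF->miRNA
table of planted edges among DE entities plus decoys touching non-DE
entities; and 50 terms (10 enriched with 80% condition-consistent DE genes,
3 near-duplicate copies at Jaccard > 0.8, the rest uniform decoys).

What the generator does **not** emulate: gene length and GC effects, count
library-composition artifacts, per-gene dispersion trends, UMI/dropout
structure beyond NB sampling, correlated (co-regulated) noise, motif
similarity between decoys and planted motifs, and real database rank
biases. Passing tests therefore demonstrate the correctness and internal
calibration of the machinery under a faithful but idealized data model, not
performance on real tissue data.

## Numerical choices

- BH adjustment: exact step-up with stable sort, capped at 1, order
  preserved.
- Trigamma inversion: Newton iteration from the asymptotic start, 1e-8
  relative tolerance; non-convergence falls back to `d0 = infinity` with a
  warning.
- Degenerate inputs: all-zero cells rank randomly (seeded) and are flagged;
  all-equal activity scores report p = 1; an empty intersection of two DE
  comparisons is flagged and reports concordance 1 by convention; zero AUC
  spread yields NES 0 for all motifs.
- Fisher p-values use the hypergeometric survival function directly; tests
  verify exact agreement with enumeration to 1e-12 at small margins.
- Seeds: every stochastic component takes an explicit seed; the pipeline
  echoes its effective configuration and produces byte-identical outputs
  for equal (config, seed).

## Known limitations

- The scalar variance prior under-serves strongly mean-dependent count
  noise (see calibration note above).
- Rank-sum DE ignores cell-level covariates (batch, cell cycle) and the
  within-gene zero-inflation structure a hurdle model would capture.
- The term-network surrogate uses only gene membership and sign
  consistency; it cannot reproduce scores of curated commercial knowledge
  bases.
- TF roles are taken from a user-supplied table; no automated curation is
  attempted.
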