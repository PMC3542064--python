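# Methods

## Data model

The counting unit throughout the package is the *annotation occurrence*:
one functional or taxonomic assignment of one predicted gene in one sample.
A gene with three COG hits contributes three occurrences. This convention
determines the `n` of every frequency in the enrichment statistic ("total
counts of all function occurrences"), and it is why annotation tables keep
duplicate rows — they are occurrences, not a set. Two operations deliberately
deviate and deduplicate to genes first: taxonomic domain composition (a gene
has one domain) and assignment rates (a gene either has an assignment in a
namespace or does not).

Two denominator conventions coexist in published summary tables and are kept
strictly separate here:

- **Domain composition** percentages divide each domain's gene count by the
  *assigned pool* — the sum of the six domain counts (Archaea, Bacteria,
  Eukarya, Plasmid, Virus, Unassigned). This is the only convention under
  which the percentages of the summary tables this package emulates are
  internally consistent (e.g. 2,420/9,273 = 26.10%), even where a table
  header nominally says "% of total CDSs".
- **Assignment rates** divide the number of distinct genes with ≥ 1
  assignment in a namespace by the sample's *total CDS count*
  (1,105/22,335 = 4.95%). Published companion values for other
  sample/namespace combinations do not always equal the printed counts
  divided by total CDSs; the package implements the division and does not
  try to reproduce internally inconsistent figures.

Printed-style percentages round half-away-from-zero to two decimals
(`_util.round_half_up`), matching how such tables are typeset rather than
Python's banker's rounding.

## The D-score

For family counts x1 of n1 (query) and x2 of n2 (reference),

d = (f1 − f2) / sqrt(p·q·(1/n1 + 1/n2)),  f_i = x_i/n_i,
p = (x1+x2)/(n1+n2),  q = 1 − p.

This is the classical pooled two-proportion z-statistic; the test suite
verifies equality (to 1e-12) with an independently coded z and with
`statsmodels.stats.proportion.proportions_ztest`, which is used only as an
oracle, never as the implementation. Degenerate pooled probabilities (p = 0
or p = 1) make the denominator vanish while the numerator is already 0; the
statistic is uninformative there and is defined as d = 0, avoiding 0/0. No
continuity correction is applied — the statistic is the bare formula. P
values are two-sided standard-normal tails; one-sidedness was a genuinely
open choice and two-sided is the conservative default. Benjamini–Hochberg
adjustment is available (`multiple_testing="BH"`) but defaults to off,
matching the raw P < 0.05 convention of comparative metagenome reports.

Report rows are ordered by |d| descending with lexicographic family-id
tie-break, so exports are byte-reproducible.

## The D-rank

d_rank(c) = Σ_{f ∈ c} d_f / sqrt(K), with K the total number of categories
in the category map. The normalisation by sqrt(K) (rather than by the
category's own size) is taken literally from the statistic's definition;
because the plausible alternative reading — per-category sqrt(m_c), which
standardises every category to unit null variance — is defensible, it is
exposed as `k_mode="per_category_families"` without changing the default.
Under sqrt(K) normalisation, quadrupling K halves every D-rank exactly; the
test suite checks this scale property.

### Significance threshold

No closed-form threshold accompanies the statistic's definition, so the
package derives one. A category with m_c members sums m_c approximately
standard-normal, approximately independent scores, so its null standard
deviation after the sqrt(K) division is sqrt(m_c/K) and the default
two-sided threshold is z_{1−α/2}·sqrt(m_c/K). The rigorous alternative
(`null_mode="permutation"`) re-draws both samples' family counts from the
pooled multinomial, conditioning on the observed totals n1 and n2, and takes
the per-category empirical (1−α) quantile of |d_rank| — the two-sided
construction that coincides with the normal threshold for a symmetric null
(the tests confirm agreement within 10% on a 2,000-family null). The
permutation RNG is seeded through `EnrichmentConfig.seed`, so permutation
reports are reproducible. When the tested matrix is a subset of the
namespace, the occurrences outside it are folded into one extra multinomial
cell so re-drawn totals still sum to n1 + n2.

Families missing from the category map are collected into an
`uncategorized` bucket that is reported like a category but does not raise
K.

## Clustering

Heatmap figures in this field rarely state their clustering algorithm. The
package defaults to average linkage (UPGMA) on Euclidean distances over
column-normalised percentages — a conventional, easily-explained choice —
with both knobs exposed. Count matrices are converted to percent of each
sample's total before distances are computed so samples of different
sequencing depth are comparable. Labels are sorted lexicographically before
linkage, which makes results invariant to input row order and resolves
equal-distance merges deterministically. Dendrograms are serialised as
Newick with branch lengths (parent height minus child height), so the path
between two leaves is twice their merge height; a naive O(n³) UPGMA
re-implementation in the tests confirms the heights. The display cap (e.g.
5% for abundance heatmaps where a few taxa reach ~25%) saturates exported
matrix values only; distances and leaf orders never see it.

## Synthetic data

The generator draws each sample's family occurrence counts as a single
multinomial of fixed size n_j over a base frequency vector π — multinomial
rather than Poisson so sample totals are exact, mirroring the fixed-n
conditioning implicit in f = x/n. Differential abundance multiplies selected
entries of π by 2^(log2 fold change) and renormalises: a simple, invertible
ground truth. Per-gene taxonomy is drawn independently of function from
configurable domain and class mixtures; genes beyond the annotated pool (up
to each sample's total CDS count) are emitted as purely taxonomic records so
gene-level summaries behave like real tables.

Defaults (`SyntheticConfig.study_like`) mirror the scale of a two-sample
insect-gut comparison: occurrence totals 8,954 and 11,317 against 22,335
and 25,208 CDSs, 2,000 families (the studies it emulates report ~1,700–2,300
COG clusters per sample) with a Zipf-like rank^(−0.9) abundance spectrum,
K = 25 categories assigned round-robin, and domain/class mixtures matching
a grass-feeding insect gut (Bacteria-dominated assigned pool,
γ-proteobacteria the leading class). `null_two_sample` is the stripped-down
configuration for calibration work: two samples of n = 10,000 over 200
uniform families in 25 categories, unless told otherwise.

What the simulator does **not** model: genome-size variation (real
gene-model abundances only roughly track organismal abundance), gene-length
effects, annotation error, overdispersion between biological replicates, and
phylogenetic correlation between family abundances. Passing calibration and
power tests therefore validate the statistic under its own sampling
assumptions — exactly what a calibration harness should do — and say nothing
about robustness to, e.g., overdispersed real communities, where the
binomial variance is known to be optimistic.

## Experiments

`type1_experiment` re-draws a zero-effect configuration `replicates` times
and reports the fraction of tested families with |d| ≥ z(α) and of
categories beyond their D-rank threshold. Rejection uses ≥ so the α → 1
limit (z = 0) rejects everything; at conventional α the boundary has
probability zero. Two error bars are reported: the binomial approximation
sqrt(r(1−r)/R) and the empirical standard error of per-replicate rates,
which also absorbs the (weak) negative correlation the multinomial
constraint induces between families. The empirical one is the honest
uncertainty for the mean rate and is what the calibration tests use.

`power_experiment` designates effect families via the configuration,
sweeps a list of fold changes, and reports per-fold-change power (effect
families), type-I error (null families) and — for categories whose every
member carries the effect — category recovery, which requires both crossing
the threshold and the correct (positive) sign. Fold change 1 reduces to the
type-I experiment. The closed-form two-sample proportion power calculation
is used in the tests as an oracle for the high-power regime.

Problem sizes in the shipped tests and the acceptance script (100
replicates, 200 families, n = 10,000, 1,000 permutations per replicate for
the permutation-null recovery run) were chosen so the full suite and the
script each complete in well under a minute of CPU while leaving
Monte-Carlo error small relative to the margins being checked.

## Known limitations

- The statistic treats each family as an independent binomial draw; with
  compositional (multinomial) data the per-family tests are weakly
  negatively correlated, which the calibration experiment shows is
  negligible at realistic family counts but is not corrected for.
- The normal D-rank threshold assumes member D-scores are approximately
  independent; strong within-category count correlation would require the
  permutation null.
- No overdispersion model: comparisons are between two fixed annotation
  pools, not between populations of replicate communities.
- CAZy parsing covers the GH/CBM/GT classes the profiling targets; other
  CAZy classes (PL, CE, AA) are rejected as malformed rather than silently
  binned.
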