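# Methods

This note records the models and procedures implemented in `coextree`,
the defaults and why they were chosen, and what the synthetic data used
by the tests can and cannot demonstrate.

## Preprocessing

The preprocessing driver (`preprocess_pipeline`) applies, in order: the
zero-SD gene filter, the ID filters (`_PAR_Y` suffix on versioned IDs,
deprecated stable IDs), the cell-line sample filter, smoothed quantile
normalization of the surviving count matrix, and finally the
lowest-non-zero floor plus log2 transform. Gene filters run before
normalization so that quantile profiles are not estimated from rows that
are about to be discarded. Zero replacement uses the single matrix-wide
minimum non-zero value (not per-gene or per-sample), so the transform is
monotone within every sample and identical rows stay identical. The
zero-SD test is exact constancy (row max == row min): a tolerance-based
test would make the filter depend on float noise. When both a TPM and a
count matrix are supplied, non-expressed genes are detected on TPM and
removed from the counts, since TPM is the scale on which "not expressed"
is well defined. Which matrix feeds the correlation step is a
configuration choice; the default is log2 of qsmooth-normalized counts.

### Smoothed quantile normalization

Plain quantile normalization assumes all samples share one expression
distribution; with multiple tissues that assumption erases genuine
global differences. The smoothed variant computes, at each quantile q of
the per-sample sorted values, the total sum of squares SST_q around the
grand mean profile and the between-group sum of squares SSB_q, and sets
the weight `w_q = 1 − SSB_q/SST_q` (clipped to [0, 1]; defined as 1
where SST_q ≈ 0, i.e. all samples agree). Each sample's q-th normalized
value is `w_q · grand_q + (1 − w_q) · group_q`. Raw weights are smoothed
with a running median over a window of 5% of the quantiles
(`scipy.ndimage.median_filter`, `mode="nearest"` at the edges). Ties
within a sample receive the mean of the normalized values at their tied
ranks, so the output rank order equals the input rank order exactly.

Two boundary behaviours follow from the algebra and are used as tests:
identical group distributions give SSB = 0, weight 1, hence plain
quantile normalization; one sample per group gives SSB = SST, weight 0,
hence the identity map.

## Correlation distance and UPGMA

Distances are `d = 1 − r` with Pearson r, clamped to [0, 2] against
floating-point excursions and with the diagonal forced to exactly 0.
Zero-variance vectors are rejected rather than patched with an epsilon —
the upstream zero-SD filter is the supported way to handle them.

UPGMA is implemented directly (not via a library linkage routine) so
that tie-breaking is defined: when several cluster pairs share the
minimal average distance bit-for-bit, the pair whose smallest contained
leaf labels sort lexicographically first is merged. This makes the tree
a pure function of the labelled distance matrix, independent of input
row order; with continuous data ties essentially never occur, but
crafted and degenerate inputs (all-equal distances) stay deterministic.
Cluster distances use the weighted average update
`d(ij,k) = (n_i d(i,k) + n_j d(j,k))/(n_i + n_j)`, which is exactly the
mean over leaf pairs; merge height is half the merge distance, making
the tree ultrametric by construction (checked to 1e−9 in tests). The
input matrix is symmetrized (`(D + Dᵀ)/2`) first: `numpy.corrcoef`
output is symmetric only to the last ulp, and the exact-equality tie
scan requires bitwise symmetry. Memory is the binding constraint at
genome scale: a double-precision distance matrix over G genes needs
8·G² bytes (~24 GB at G = 55k), and the implementation holds two such
arrays; the tested regime is 10²–10³ leaves.

The cophenetic matrix (twice the LCA height per leaf pair) is the
quality handle: for average linkage every cophenetic value is an average
of original distances, so it lies within the input's range (a tested
invariant), and rebuilding a tree from an already-ultrametric matrix
reproduces the matrix exactly.

Newick parsing is delegated to dendropy (`preserve_underscores=True`,
since gene and sample IDs routinely contain underscores); writing is a
small serializer so sibling order follows merge-operand order. The
PHYLIP distance format is the square dialect with relaxed
(whitespace-delimited, unlimited-length) names; names containing
whitespace are sanitized with a returned mapping.

## Representative pruning

`prune_to_n` repeatedly finds the cherry with minimal parent height (the
two most similar remaining samples) and deletes one member, contracting
the parent, until n leaves remain. Heights are never re-estimated, so
cophenetic distances between survivors are unchanged, and the minimal
surviving pairwise distance is non-decreasing as n shrinks — both tested
on random trees.

Which member to delete was an open design point. The implemented rule —
keep the member with the larger summed cophenetic distance to all other
leaves — turns out to be degenerate on ultrametric trees: cherry members
share every ancestor, so their sums are exactly equal and the
lexicographic tie-break (delete the larger name) always decides. The
rule is kept because pruning also accepts near-ultrametric trees read
from Newick files, where the sums can differ; on UPGMA output the
procedure is simply deterministic by name. The tree must be strictly
binary (UPGMA output always is; other input is rejected), so a cherry
always exists.

## Clade extraction

The clade at internal-node count k is the subtree rooted at the k-th
ancestor of the driver leaf. Clade size is capped at ceil(25% of all
leaves); when the k-th ancestor exceeds the cap the largest smaller k
within it is returned, flagged `capped`. Two small-tree guards keep the
definitions usable off genome scale: the cap is floored at 2 (a clade is
minimally a cherry, and k = 1 must always return driver + sibling), and
if even the parent clade exceeds the cap a driver-only clade with
internal-node count 0 is returned rather than violating the cap.

The default clade minimizes |size − 25| over the driver's ancestors;
ties pick the smaller clade (fewer false co-members). On trees with
fewer than 100 leaves the 25% cap would forbid the 25-gene target
entirely, so the default selection waives it there and may return the
whole tree; `clade_at` always enforces the cap. Re-anchoring to a
different driver in the same clade restarts internal-node counting from
the new leaf, so equal k may give a different clade — intended, since k
is defined relative to the driver.

## Enrichment

The universe defaults to all genes in the tree (configurable by passing
any other id set). Only terms with at least one clade hit are tested,
and only those enter the BH family size m; including never-hit terms
would deflate every adjusted p by a constant factor without changing
ranks. Identifiers are matched case-sensitively on stable IDs after
truncating versions at the first dot. Raw p is the hypergeometric upper
tail (scipy's `hypergeom.sf`, which is accurate in the far tail);
adjustment is statsmodels' BH step-up. Both are cross-checked in the
tests against an exact rational enumeration and a literal step-up
implementation. Ranking is by raw p ascending, ties broken by
over-representation descending then term id, so output order is total
and reproducible.

## Family scan

The scan enumerates every internal-node clade of at least `min_size`
leaves, counts family members, and ranks by count (descending), then
clade size (ascending), then smallest leaf name. A clade nested inside
an already-reported clade is suppressed; under this order the earlier
report always has at least the nested clade's count, so reporting is
maximal-clade. Ranking smaller clades first means the tightest clade
capturing a given number of family members outranks its own ancestors.
No significance is attached to the counts; the scan is descriptive.

## Synthetic data

`make_module_matrix` draws each module gene as
`√ρ · z_m + √(1 − ρ) · ε` with a shared latent profile z_m and
independent Gaussian noise, so the expected within-module pairwise
Pearson correlation is exactly ρ (default 0.9) with no calibration step;
background genes are independent noise. `make_grouped_samples` emits
Poisson counts around group-shifted log-normal means, giving clean
group-wise sample clades at shift 2.0 and indistinguishable groups at
shift 0. `make_term_library` pairs each planted module with a term plus
size-matched random decoys.

What these generators do not emulate: mean–variance coupling and
over-dispersion of real RNA-seq counts, correlated backgrounds, batch
effects, overlapping or nested modules, and annotation bias in term
libraries. Tests passing on them show that the machinery recovers
planted structure under its own model assumptions — not that any
particular biological dataset will yield clean clades.

Default problem sizes in the tests and the acceptance script (60–1,000
genes, 20–100 samples, 20 seeds for recovery checks) were chosen so
the planted-structure checks are statistically comfortable at desk
scale; the algorithms themselves have no size-dependent switches.

## Known limitations

- O(G²) memory and O(G³)-ish time for UPGMA put genome-scale trees
  (tens of thousands of genes) out of reach of this pure-Python
  implementation without chunked/streamed distance handling.
- The enrichment model treats gene sets as flat; term hierarchy (e.g.
  ontology parent–child redundancy) is not collapsed.
- Pruning optimizes a greedy local criterion (lowest cherry first);
  it is not guaranteed to maximize any global diversity functional.
- qsmooth edge smoothing uses nearest-value padding, which can differ
  from other running-median end rules in the outermost 2–3 quantiles.
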