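# Methods

## Model and assumptions

All statistics condition on a fixed gene universe of size N (default
19,814, the GENCODE v22 gene count).  Two lists of sizes n_A and n_B are
modelled, under the null, as independent uniform draws without replacement
from the universe, so their overlap k is Hypergeometric(N, n_A, n_B) with
expectation n_A·n_B/N.  The representation factor RF = k/(n_A·n_B/N)
summarises effect size; the inclusive upper tail P(X ≥ k) gives exact
significance (p = 1 at k = 0 by construction).  This null assumes
exchangeable genes: it ignores correlated list membership due to gene
families, gene length, or shared ascertainment, which real curated lists
violate to an unknown degree — RF is a descriptive index, not a causal
estimate.

Two entry modes exist deliberately.  *Membership mode* intersects actual
symbol sets.  *Count mode* takes (n_A, n_B, k, N) directly and reproduces
published table arithmetic when the underlying lists are not available.
By default list sizes are used as-is against the fixed N (mirroring the
standard web-calculator usage); a strict mode (`restrict_to_universe`)
first intersects each list with an explicit universe catalogue for users
who have one.

## Reporting conventions

One-decimal RFs round half away from zero (2.252 → 2.3, 1.993 → 2.0);
full precision is retained in all JSON mirrors, rounding is display-only.
RF at k = 0 is defined as 0; RF is undefined (an error) only when a list
is empty.  In pipeline reports a pair is flagged "overrepresented" only
when RF > 1 and p is below the threshold (default 0.05, configurable);
the full table is always written regardless.  Pairwise p-values are
reported raw by default — matching how such overlap batteries are usually
published — with Bonferroni/BH available for the category-enrichment
battery where correction is standard.

## Conformance checking

Count-mode input may carry the values a source printed (`rf_printed`,
`pct_printed`, `k_alt` for a second count quoted elsewhere for the same
cell).  The engine recomputes everything from the counts and flags each
disagreement in a conformance log; it never adjusts its output toward a
printed value.  On the packaged reference counts this surfaces five
genuine printed inconsistencies, e.g. a printed RF of 1.6 for a cell
whose own counts give 9/(44·2657/19814) = 1.53 → 1.5, and one overlap
quoted as both 28 and 30 in different places of the same source.

## Category enrichment

Overrepresentation of a test list (⊆ reference list) in an annotation
category with reference share p_ref uses the binomial upper tail
P(X ≥ k), X ~ Binomial(n_test, p_ref) — the classic annotation-tool test.
n_test counts only annotated test genes; unannotated genes are excluded
with logged counts.  Multi-label genes count once per category, no
fractional weighting.  Correction defaults to Bonferroni over the
categories tested (BH-FDR selectable) because the classic tools corrected
that way; both raw and adjusted columns are always emitted since published
p-values often do not say which they are.  The binomial is itself an
approximation to the exact hypergeometric draw of the test list from the
reference; it is used deliberately for fidelity to the tools it emulates.

## Tissue enrichment

A gene's focal tissue is its argmax column (ties broken by lexicographic
tissue name, for determinism).  The call compares the focal level with the
*maximum* over the other tissues — the strict reading of "at least 5×
higher than all other tissues" — with the mean selectable for sensitivity
analysis.  The threshold is inclusive (ratio ≥ fold).  The denominator is
floored at ε = 10⁻⁶ (matrix units): this handles an all-zero background
without perturbing the exact-boundary case, and an all-zero gene is never
enriched.  Calls are invariant to rescaling the whole matrix.  Tissues
enter downstream overlap analysis only with ≥ 5 enriched genes (default,
configurable).

## Region-to-gene assignment

Genes get a strand-aware basal window (defaults 5 kb upstream, 1 kb
downstream of the TSS; the TSS of a minus-strand gene is the higher
coordinate) extended outward from each basal edge by at most 1 Mb,
stopping at a neighbouring gene's basal window; extensions may overlap
other extensions but never invade a foreign basal window, and domains are
clipped to [0, chromosome length).  All four numbers are configurable;
this single, auditable rule is the only association mode provided —
curated-domain and nearest-gene variants are out of scope, and no
enrichment-over-genome-fraction statistic is computed here (enrichment of
the derived gene list is the category-enrichment module's job).
Assignment uses an interval tree; a quadratic all-pairs scan serves as the
independent oracle in tests.

## Synthetic data

The generator emulates the statistical structure of curated-list studies:
fixed-size lists over a ~20,000-gene universe with specified
intersections, expression matrices with planted ≥ 5×-enriched genes,
annotation tables with one category inflated to a target fold, and a
gene-dense chromosome with known interval assignments.  Deterministic
planting allocates disjoint Venn-region blocks, so pairwise (and triple)
overlaps are exact — sharp recovery tests; stochastic mode samples lists
independently so the hypergeometric null itself can be validated
(10,000-rep calibration agrees with the analytic tail within binomial
error).  Background expression is log-normal (log-scale μ = 1, σ = 1),
the right-skew typical of expression data; with that dispersion a few
percent of unplanted genes clear the 5× rule by chance, which the tests
treat as the property it is (rare, shrinking with tissue count) rather
than as noise to suppress.  Planted expression values are nudged up by at
most a few ulps so floating-point division cannot drop an exact-boundary
plant below the inclusive threshold.  Synthetic symbols are zero-padded
("G000001") so lexicographic and numeric order coincide.  What the
generator does *not* emulate: real symbol vocabularies, gene families,
length/GC ascertainment biases, or correlated membership across lists —
passing recovery tests therefore demonstrates correctness of the
machinery, not robustness of RF to real-data confounding.

## Problem sizes and determinism

Default test and acceptance runs use: exact-tail grids up to N = 100
(brute-force cross-check at 10⁻¹²) and N ≤ 60 (Fisher one-sided
equivalence); 10,000 permutation reps at (500, 400, N = 20,000); planted
recovery at n = 500 lists, 100-gene test lists over 1,000-gene
references, 2,000-gene × 24-tissue matrices, and 200 intervals × 50
domains.  Every stochastic routine takes a single integer seed and builds
one `numpy` Generator per call; identical seeds give byte-identical
outputs, including written datasets and report bundles.

## Known limitations

- The hypergeometric null ignores structured ascertainment shared between
  lists; RFs on real curated lists are best read comparatively.
- Count-mode inherits whatever normalisation the source applied to its
  lists; it cannot detect symbol-level inconsistencies, only arithmetic
  ones.
- The basal-plus-extension rule is one published default among several
  association heuristics; derived gene lists can differ substantially
  from those produced by other rules or other annotation builds.
- No Venn figure rendering is provided; region counts and memberships are
  the contract.
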