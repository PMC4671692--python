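"""Binomial category overrepresentation against a chosen reference list.

Builds a 1,000-gene reference with 10 annotation categories, plants one
category at 3x its base rate in a 100-gene test list, and asks which
categories are overrepresented (Bonferroni-corrected binomial upper tail).
"""
from convergene import GeneSet, binomial_enrichment, gen_annotations, gen_universe
from convergene.enrichment import results_to_frame

universe = gen_universe(2_000, seed=7)
reference = GeneSet(name="reference", members=frozenset(sorted(universe.members)[:1000]))
annot, test, truth = gen_annotations(
    reference, n_categories=10, planted_category="C004", planted_fold=3.0,
    n_test=100, seed=7)

results = binomial_enrichment(test, reference, annot, correction="bonferroni")
df = results_to_frame(results)
print(df[["category", "k_test", "expected", "fold", "p_raw", "p_adj"]]
      .head(5).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(f"\nplanted category: {truth['planted_category']} at fold {truth['planted_fold']}")
print(f"top-ranked:       {results[0].category} (fold {results[0].fold:.2f}, "
      f"p_adj {results[0].p_adj:.2e})")

# The planted category tops the ranking with fold ~3; unplanted categories
# hover near fold 1 with adjusted p near 1 — the test is calibrated.
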