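"""Binomial category overrepresentation and the enrichment battery."""
from math import comb

import pytest

from convergene import (AnnotationTable, GeneSet, binomial_enrichment,
                        enrichment_battery, gen_annotations, gen_universe,
                        load_annotation_gmt, load_annotation_tsv)
from convergene.enrichment import results_to_frame
from convergene.errors import ConfigError, ContractError


def binom_upper_brute(n: int, p: float, k: int) -> float:
    """Direct summation of the binomial upper tail P(X >= k)."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def simple_annot(mapping):
    return AnnotationTable(
        ontology="test",
        gene_to_categories={g: frozenset(c) for g, c in mapping.items()},
        labels={},
    )


@pytest.fixture
def planted_case():
    """1,000-gene reference, category C001 covering 10%, 100-gene test list
    with 30 genes in C001 (fold 3)."""
    ref_genes = [f"G{i:04d}" for i in range(1000)]
    mapping = {g: {"C001"} if i < 100 else {"C%03d" % (2 + i % 9)}
               for i, g in enumerate(ref_genes)}
    reference = GeneSet(name="ref", members=frozenset(ref_genes))
    test = GeneSet(name="test",
                   members=frozenset(ref_genes[:30] + ref_genes[100:170]))
    return test, reference, simple_annot(mapping)


class TestBinomialEnrichment:
    def test_planted_fold_and_tail(self, planted_case):
        test, reference, annot = planted_case
        res = binomial_enrichment(test, reference, annot)
        top = {r.category: r for r in res}["C001"]
        assert top.n_test == 100 and top.k_test == 30
        assert top.fold == pytest.approx(3.0)
        assert top.p_raw == pytest.approx(binom_upper_brute(100, 0.1, 30), rel=1e-9)
        assert res[0].category == "C001"  # strongest enrichment ranks first

    def test_tail_matches_bruteforce_generally(self, planted_case):
        test, reference, annot = planted_case
        for r in binomial_enrichment(test, reference, annot, correction="none"):
            assert r.p_raw == pytest.approx(
                binom_upper_brute(r.n_test, r.p_ref, r.k_test), rel=1e-9, abs=1e-15)

    def test_self_reference_gives_fold_one(self, planted_case):
        _, reference, annot = planted_case
        res = binomial_enrichment(reference, reference, annot)
        assert all(r.fold == pytest.approx(1.0) for r in res)

    def test_fold_times_expected_is_k(self, planted_case):
        test, reference, annot = planted_case
        for r in binomial_enrichment(test, reference, annot):
            assert r.fold * r.expected == pytest.approx(r.k_test)

    def test_bonferroni_is_m_times_p_capped(self, planted_case):
        test, reference, annot = planted_case
        res = binomial_enrichment(test, reference, annot, correction="bonferroni")
        m = len(res)
        for r in res:
            assert r.p_adj == pytest.approx(min(1.0, m * r.p_raw))
            assert r.p_adj >= r.p_raw

    def test_bh_monotone_in_rank(self, planted_case):
        test, reference, annot = planted_case
        res = binomial_enrichment(test, reference, annot, correction="bh")
        adj = [r.p_adj for r in sorted(res, key=lambda r: r.p_raw)]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_absent_category_omitted_unless_under_mode(self):
        mapping = {"G1": {"A"}, "G2": {"A"}, "G3": {"B"}, "G4": {"B"}}
        ref = GeneSet(name="r", members=frozenset(mapping))
        test = GeneSet(name="t", members=frozenset({"G1", "G2"}))
        annot = simple_annot(mapping)
        over = binomial_enrichment(test, ref, annot)
        assert {r.category for r in over} == {"A"}
        both = binomial_enrichment(test, ref, annot, include_under=True)
        under = {r.category: r for r in both}["B"]
        assert under.direction == "under" and under.k_test == 0

    def test_stray_test_genes_dropped(self, planted_case, caplog):
        test, reference, annot = planted_case
        bigger = GeneSet(name="t2", members=test.members | {"NOT_IN_REF"})
        with caplog.at_level("WARNING"):
            res = binomial_enrichment(bigger, reference, annot)
        assert res[0].n_test == 100
        assert any("not in reference" in r.message for r in caplog.records)

    def test_multilabel_expected_sum_identity(self):
        # sum of expected counts = n_test * mean categories per reference gene
        mapping = {f"G{i}": {"A", "B"} if i % 2 else {"C"} for i in range(100)}
        ref = GeneSet(name="r", members=frozenset(mapping))
        test = GeneSet(name="t", members=frozenset(list(mapping)[:20]))
        res = binomial_enrichment(test, ref, simple_annot(mapping), include_under=True)
        n_test = res[0].n_test
        mean_cats = sum(len(c) for c in mapping.values()) / len(mapping)
        assert sum(r.expected for r in res) == pytest.approx(n_test * mean_cats)

    def test_unknown_correction_rejected(self, planted_case):
        test, reference, annot = planted_case
        with pytest.raises(ContractError):
            binomial_enrichment(test, reference, annot, correction="holm-sidak-nope")

    def test_unannotated_test_list_returns_empty(self):
        mapping = {"G1": {"A"}}
        ref = GeneSet(name="r", members=frozenset({"G1", "G2"}))
        test = GeneSet(name="t", members=frozenset({"G2"}))
        assert binomial_enrichment(test, ref, simple_annot(mapping)) == []


class TestPlantedRecovery:
    def test_planted_threefold_category_ranks_first(self):
        u = gen_universe(2000, seed=21)
        reference = GeneSet(name="ref", members=frozenset(sorted(u.members)[:1000]))
        annot, test, truth = gen_annotations(
            reference, n_categories=10, planted_category="C003",
            planted_fold=3.0, n_test=100, seed=21)
        res = binomial_enrichment(test, reference, annot)
        assert res[0].category == "C003"
        assert res[0].fold == pytest.approx(
            truth["k_planted"] / (100 * truth["base_p"]), rel=0.01)


class TestBattery:
    def test_cardinality_and_missing_reference(self, planted_case):
        test, reference, annot = planted_case
        annot2 = AnnotationTable(ontology="other",
                                 gene_to_categories=annot.gene_to_categories,
                                 labels={})
        out = enrichment_battery({"s1": test, "s2": test},
                                 {"s1": reference, "s2": reference},
                                 [annot, annot2])
        assert len(out) == 4
        with pytest.raises(ConfigError, match="s2"):
            enrichment_battery({"s1": test, "s2": test}, {"s1": reference}, [annot])

    def test_empty_battery(self):
        assert enrichment_battery({}, {}, []) == {}


class TestAnnotationIO:
    def test_tsv_and_gmt_agree(self, tmp_path):
        tsv = tmp_path / "a.tsv"
        tsv.write_text("gene\tcategory\nG1\tC1\nG2\tC1\nG2\tC2\n")
        gmt = tmp_path / "a.gmt"
        gmt.write_text("C1\tdesc one\tG1\tG2\nC2\tdesc two\tG2\n")
        t1 = load_annotation_tsv(tsv)
        t2 = load_annotation_gmt(gmt)
        assert t1.gene_to_categories == t2.gene_to_categories
        assert t2.label("C1") == "desc one"

    def test_frame_columns(self, planted_case):
        test, reference, annot = planted_case
        df = results_to_frame(binomial_enrichment(test, reference, annot))
        assert list(df.columns)[:4] == ["category", "label", "n_test", "k_test"]
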