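import pytest

from girem.corpus_io import AbstractDoc, GeneLexicon, GoAnnotationTable
from girem.features import (
    FIRST_WITH_GOS_OF_SECOND,
    SECOND_WITH_GOS_OF_FIRST,
    build_feature_matrix,
    gene_go_weight,
    pair_weight,
    tally,
)
from girem.synthetic import SynthConfig, generate

from conftest import make_doc
from oracles import bruteforce_tallies, bruteforce_weights


@pytest.fixture(scope="module")
def small_lexicon():
    return GeneLexicon(entries={"G1": "TP53", "G2": "BRCA1", "G3": "EGFR"})


@pytest.fixture(scope="module")
def small_go():
    return GoAnnotationTable(
        records={
            "G1": frozenset({("GO:0006915", "apoptotic process")}),
            "G2": frozenset({("GO:0006281", "DNA repair"),
                             ("GO:0006915", "apoptotic process")}),
        }
    )


class TestTally:
    def test_single_related_sentence_counts_at_all_levels(
        self, small_lexicon, small_go, rules
    ):
        corpus = [make_doc("TP53 and BRCA1 interact.")]
        t = tally(corpus, small_lexicon, small_go, rules)
        for g in ("G1", "G2"):
            assert t.solo_gene_count(g, "A") == 1
            assert t.solo_gene_count(g, "S") == 1
        assert t.co_count("G1", "G2", "A") == 1
        assert t.co_count("G1", "G2", "S") == 1
        assert t.co_count("G1", "G2", "SE") == 1  # "and" marks the pair related

    def test_cross_sentence_cooccurrence_counts_only_at_abstract_level(
        self, small_lexicon, small_go, rules
    ):
        corpus = [make_doc("TP53 was mutated. BRCA1 was lost.")]
        t = tally(corpus, small_lexicon, small_go, rules)
        assert t.co_count("G1", "G2", "A") == 1
        assert t.co_count("G1", "G2", "S") == 0
        assert t.co_count("G1", "G2", "SE") == 0

    def test_empty_corpus_all_zero(self, small_lexicon, small_go, rules):
        t = tally([], small_lexicon, small_go, rules)
        assert t.unit_counts == {"A": 0, "S": 0, "SE": 0}
        assert t.co_count("G1", "G2", "A") == 0

    def test_shared_go_term_mention_credits_every_annotated_gene(
        self, small_lexicon, small_go, rules
    ):
        # "apoptotic process" annotates both G1 and G2
        corpus = [make_doc("EGFR drives apoptotic process changes.")]
        t = tally(corpus, small_lexicon, small_go, rules)
        assert t.solo_go_count("G1", "A") == 1
        assert t.solo_go_count("G2", "A") == 1
        assert t.co_gene_go_count("G3", "G1", "A") == 1
        assert t.co_gene_go_count("G3", "G2", "A") == 1

    def test_repeated_mentions_count_once_per_unit(self, small_lexicon, small_go, rules):
        corpus = [make_doc("TP53 and TP53 and BRCA1 and TP53 were assayed.")]
        t = tally(corpus, small_lexicon, small_go, rules)
        assert t.solo_gene_count("G1", "S") == 1
        assert t.co_count("G1", "G2", "S") == 1


class TestWeights:
    def test_direct_ratio_arithmetic(self, small_lexicon, small_go):
        # co=2, so_x=4, so_y=6 -> 2/(4+6) = 0.2
        from girem.features import TalliedCorpus

        t = TalliedCorpus(genes=frozenset({"G1", "G2"}))
        t.co_gene["A"][("G1", "G2")] = 2
        t.solo_gene["A"]["G1"] = 4
        t.solo_gene["A"]["G2"] = 6
        assert pair_weight(t, "G1", "G2", "A") == pytest.approx(0.2)

    def test_always_cooccurring_pair_hits_the_half_ceiling(
        self, small_lexicon, small_go, rules
    ):
        corpus = [make_doc("TP53 and BRCA1 interact.") for _ in range(4)]
        corpus = [AbstractDoc(f"d{i}", d.text) for i, d in enumerate(corpus)]
        t = tally(corpus, small_lexicon, small_go, rules)
        for level in ("A", "S", "SE"):
            assert pair_weight(t, "G1", "G2", level) == pytest.approx(0.5)

    def test_zero_cooccurrence_and_zero_denominator_give_zero(self, small_lexicon):
        from girem.features import TalliedCorpus

        t = TalliedCorpus(genes=frozenset({"G1", "G2"}))
        assert pair_weight(t, "G1", "G2", "A") == 0.0

    def test_unknown_gene_raises(self, small_lexicon, small_go, rules):
        t = tally([], small_lexicon, small_go, rules)
        with pytest.raises(KeyError):
            pair_weight(t, "G1", "NOPE", "A")

    def test_gene_without_go_terms_scores_zero_on_go_weights(
        self, small_lexicon, small_go, rules
    ):
        # G3 has no GO annotations: co(gx, GOs(G3)) must be 0
        corpus = [make_doc("TP53 and EGFR interact.")]
        t = tally(corpus, small_lexicon, small_go, rules)
        for level in ("A", "S", "SE"):
            assert gene_go_weight(t, "G1", "G3", level, FIRST_WITH_GOS_OF_SECOND) == 0.0

    def test_gene_with_partner_go_name_in_one_abstract(self, small_lexicon, small_go, rules):
        # co=1, so(TP53)=1, so(GOs(BRCA1))=1 -> 1/(1+1) = 0.5
        corpus = [make_doc("TP53 interacts with DNA repair machinery.")]
        t = tally(corpus, small_lexicon, small_go, rules)
        assert gene_go_weight(t, "G1", "G2", "A", FIRST_WITH_GOS_OF_SECOND) == pytest.approx(0.5)


class TestFeatureMatrix:
    def test_pairs_without_abstract_cooccurrence_get_no_row(
        self, small_lexicon, small_go, rules
    ):
        corpus = [make_doc("TP53 was assayed."), make_doc("BRCA1 was lost.", "doc2")]
        t = tally(corpus, small_lexicon, small_go, rules)
        assert build_feature_matrix(t, small_go) == []

    def test_row_count_matches_hand_enumeration(self, small_lexicon, small_go, rules):
        corpus = [
            make_doc("TP53 and BRCA1 interact.", "d1"),
            make_doc("BRCA1 binds to EGFR.", "d2"),
            make_doc("TP53 regulates EGFR.", "d3"),
        ]
        t = tally(corpus, small_lexicon, small_go, rules)
        rows = build_feature_matrix(t, small_go)
        assert [(r.gene_a, r.gene_b) for r in rows] == [
            ("G1", "G2"),
            ("G1", "G3"),
            ("G2", "G3"),
        ]

    def test_recompute_is_identical(self, small_lexicon, small_go, rules):
        cfg = SynthConfig(n_genes=6, n_abstracts=20, seed=3)
        data = generate(cfg)
        t1 = tally(data.corpus, data.lexicon, data.go_table, rules)
        t2 = tally(data.corpus, data.lexicon, data.go_table, rules)
        assert build_feature_matrix(t1, data.go_table) == build_feature_matrix(
            t2, data.go_table
        )


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tallies_and_weights_match_recount(self, rules, seed):
        cfg = SynthConfig(
            n_genes=8,
            n_go_terms=6,
            go_terms_per_gene=2,
            n_abstracts=30,
            sentences_per_abstract=4,
            true_network_density=0.25,
            seed=seed,
        )
        data = generate(cfg)
        t = tally(data.corpus, data.lexicon, data.go_table, rules)
        oracle = bruteforce_tallies(data.corpus, data.lexicon, data.go_table, rules)
        assert t.unit_counts == oracle["unit_counts"]
        genes = sorted(data.lexicon.entries)
        for g in genes:
            for level in ("A", "S"):
                assert t.solo_gene_count(g, level) == oracle["solo_gene"][level][g]
                assert t.solo_go_count(g, level) == oracle["solo_go"][level][g]
        rows = {r.pair: r for r in build_feature_matrix(t, data.go_table)}
        for i, gx in enumerate(genes):
            for gy in genes[i + 1 :]:
                for level in ("A", "S", "SE"):
                    assert (
                        t.co_count(gx, gy, level) == oracle["co_gene"][level][(gx, gy)]
                    )
                    for key in ((gx, gy), (gy, gx)):
                        assert (
                            t.co_gene_go_count(*key, level)
                            == oracle["co_gene_go"][level][key]
                        )
                if (gx, gy) in rows:
                    assert rows[(gx, gy)].w == bruteforce_weights(oracle, gx, gy)

    def test_symmetry_swapping_genes_exchanges_go_directions(self, rules):
        data = generate(
            SynthConfig(n_genes=6, n_abstracts=25, true_network_density=0.3, seed=11)
        )
        t = tally(data.corpus, data.lexicon, data.go_table, rules)
        rows = build_feature_matrix(t, data.go_table)
        for r in rows:
            for level in ("A", "S", "SE"):
                assert pair_weight(t, r.gene_a, r.gene_b, level) == pair_weight(
                    t, r.gene_b, r.gene_a, level
                )
                assert gene_go_weight(
                    t, r.gene_a, r.gene_b, level, FIRST_WITH_GOS_OF_SECOND
                ) == gene_go_weight(t, r.gene_b, r.gene_a, level, SECOND_WITH_GOS_OF_FIRST)

    def test_bounds_and_level_monotonicity(self, rules):
        data = generate(SynthConfig(n_genes=10, n_abstracts=40, seed=23))
        t = tally(data.corpus, data.lexicon, data.go_table, rules)
        for r in build_feature_matrix(t, data.go_table):
            assert all(0.0 <= w <= 0.5 for w in r.w)
            assert r.w[2] <= r.w[1]  # SE co-occurrences are a subset of S
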