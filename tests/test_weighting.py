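"""Co-occurrence counting and the three term-weighting schemes."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ontosim import synthetic, toy
from ontosim.errors import (
    FormatError,
    LookupError_,
    UndefinedDenominatorError,
    ValidationError,
)
from ontosim.ontology import feature_space
from ontosim.vectors import Report
from ontosim.weighting import (
    CorpusCountProvider,
    QueryGroup,
    TableCountProvider,
    TermWeight,
    concept_query_group,
    corpus_count_provider,
    equal_weights,
    generic_weights,
    rank_terms,
    specific_term_probability,
    specific_weights,
    table_count_provider,
)


class TestQueryGroup:
    def test_case_insensitive_dedup(self):
        g = QueryGroup(("HCC", "hcc", "hepatoma"))
        assert g.names == ("HCC", "hepatoma")

    def test_empty_name_rejected(self):
        with pytest.raises(ValidationError):
            QueryGroup(("ok", ""))

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            QueryGroup(())


class TestCorpusProvider:
    def test_single_abstract_hit_and_miss(self):
        prov = CorpusCountProvider({"a1": "HCC with dysplastic nodule"})
        assert prov.count(QueryGroup(("dysplastic nodule",))) == 1
        assert prov.count(QueryGroup(("cirrhosis",))) == 0

    def test_whole_phrase_word_boundaries(self):
        prov = CorpusCountProvider({"a1": "carcinomatosis is not carcinoma"})
        assert prov.count(QueryGroup(("carcinoma",))) == 1  # the standalone word
        prov2 = CorpusCountProvider({"a1": "we saw carcinomatosis only"})
        assert prov2.count(QueryGroup(("carcinoma",))) == 0

    def test_abstract_counted_once_per_group(self):
        prov = CorpusCountProvider({"a1": "HCC and hcc and HCC again"})
        assert prov.count(QueryGroup(("HCC",))) == 1

    def test_joint_bounded_by_marginals(self):
        prov = CorpusCountProvider(toy.liver_corpus())
        g1 = QueryGroup(("cirrhosis", "cirrhosis of liver"))
        g2 = QueryGroup(toy.DISEASE_NAMES)
        joint = prov.count_joint(g1, g2)
        assert joint == prov.count_joint(g2, g1)
        assert joint <= min(prov.count(g1), prov.count(g2))

    def test_file_roundtrip_and_format_errors(self, tmp_path):
        p = tmp_path / "corpus.tsv"
        p.write_text("a1\tsome text\na2\tmore text\n")
        assert corpus_count_provider(p).n_abstracts == 2
        bad = tmp_path / "bad.tsv"
        bad.write_text("justonefield\n")
        with pytest.raises(FormatError, match=":1"):
            corpus_count_provider(bad)
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(ValidationError):
            corpus_count_provider(empty)

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_naive_regex_scan(self, seed):
        # independent oracle: per-name scan with its own regex construction
        g = synthetic.generate_ontology(synthetic.OntologySpec(depth=4, seed=seed))
        terms = g.concept_ids[1:6]
        corpus = synthetic.generate_corpus(
            synthetic.CorpusSpec(
                n_abstracts=200,
                p_term_given_disease={t: 0.4 for t in terms},
                seed=seed,
            ),
            g,
        )
        prov = CorpusCountProvider(corpus)
        for tid in terms:
            group = concept_query_group(g, tid)
            oracle = sum(
                1
                for text in corpus.values()
                if any(
                    re.search(rf"(?<!\w){re.escape(n)}(?!\w)", text, re.I)
                    for n in group.names
                )
            )
            assert prov.count(group) == oracle


class TestTableProvider:
    def test_lookup_and_marginal(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("termx\tdisease\t5\ndisease\t*\t10\n")
        prov = table_count_provider(p)
        assert prov.count_joint(QueryGroup(("termX",)), QueryGroup(("Disease",))) == 5
        assert prov.count(QueryGroup(("disease",))) == 10

    def test_joint_exceeding_marginal_rejected(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("termx\tdisease\t12\ndisease\t*\t10\n")
        with pytest.raises(ValidationError, match="exceeds"):
            table_count_provider(p)

    def test_missing_pair_errors(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("disease\t*\t10\n")
        prov = table_count_provider(p)
        with pytest.raises(LookupError_):
            prov.count_joint(QueryGroup(("x",)), QueryGroup(("disease",)))

    def test_write_reload_identity(self, tmp_path):
        p1 = tmp_path / "c1.tsv"
        p1.write_text("a\tb\t3\na\t*\t7\nb\t*\t9\n")
        prov = table_count_provider(p1)
        p2 = tmp_path / "c2.tsv"
        prov.write(p2)
        prov2 = table_count_provider(p2)
        ga, gb = QueryGroup(("a",)), QueryGroup(("b",))
        assert prov2.count(ga) == 7 and prov2.count(gb) == 9
        assert prov2.count_joint(ga, gb) == 3


class TestSchemes:
    def test_equal_weights_all_ones(self, liver):
        space = feature_space(liver, 4)
        wv = equal_weights(space)
        assert wv.scheme == "equal"
        assert all(wv[f] == 1.0 for f in space.feature_ids)

    def test_generic_weights_on_hand_counted_corpus(self, liver):
        # liver corpus: disease marginal 8; "fatty liver" group joint 2
        space = feature_space(liver, 4)
        prov = CorpusCountProvider(toy.liver_corpus())
        wv = generic_weights(space, QueryGroup(toy.DISEASE_NAMES), prov, liver)
        assert wv.scheme == "generic"
        assert wv["fatty-liver"] == pytest.approx(2 / 8)
        assert wv["liver-finding"] == 0.0

    def test_zero_disease_count_raises(self, liver):
        space = feature_space(liver, 4)
        prov = CorpusCountProvider({"a1": "nothing relevant"})
        with pytest.raises(UndefinedDenominatorError):
            generic_weights(space, QueryGroup(("absent disease",)), prov, liver)

    def test_specific_term_probability_arithmetic(self, tmp_path):
        # a constructed count pair with the ratio 467/500 = 0.934
        p = tmp_path / "counts.tsv"
        p.write_text("dysplastic nodule\thcc\t467\nhcc\t*\t500\n")
        prov = table_count_provider(p)
        from ontosim.ontology import Concept

        tw = specific_term_probability(
            Concept("dn", "dysplastic nodule"), QueryGroup(("HCC",)), prov
        )
        assert tw.q == pytest.approx(0.934)

    def test_specific_weights_average_descendant_probabilities(self, liver):
        # r1 holds cirrhosis (under liver finding) and fatty liver (its own
        # feature, also under liver finding via its second parent)
        space = feature_space(liver, 4)
        prov = CorpusCountProvider(toy.liver_corpus())
        disease = QueryGroup(toy.DISEASE_NAMES)
        report = Report("r1", "HCC", frozenset({"cirrhosis", "fatty-liver"}))
        wv = specific_weights(report, space, liver, disease, prov)
        q_cirr = 4 / 8
        q_fatty = 2 / 8
        assert wv["liver-finding"] == pytest.approx((q_cirr + q_fatty) / 2)
        assert wv["fatty-liver"] == pytest.approx(q_fatty)  # single descendant
        assert wv["abdominal-organ-finding"] == 0.0  # no term underneath
        assert wv.scheme == "specific" and wv.report_id == "r1"

    def test_specific_weights_vary_with_report_generic_do_not(self, liver):
        space = feature_space(liver, 4)
        prov = CorpusCountProvider(toy.liver_corpus())
        disease = QueryGroup(toy.DISEASE_NAMES)
        r1, r2, _ = toy.liver_reports()
        w1 = specific_weights(r1, space, liver, disease, prov)
        w2 = specific_weights(r2, space, liver, disease, prov)
        assert w1.weights != w2.weights
        g1 = generic_weights(space, disease, prov, liver)
        g2 = generic_weights(space, disease, prov, liver)
        assert g1.weights == g2.weights

    @pytest.mark.parametrize("seed", range(5))
    def test_weights_always_within_unit_interval(self, seed):
        g = synthetic.generate_ontology(synthetic.OntologySpec(depth=5, seed=seed))
        space = feature_space(g, 3)
        deep = [c for c in g.concept_ids if c not in space.feature_ids]
        corpus = synthetic.generate_corpus(
            synthetic.CorpusSpec(
                n_abstracts=150,
                p_term_given_disease={t: 0.5 for t in deep[:8]},
                seed=seed,
            ),
            g,
        )
        prov = CorpusCountProvider(corpus)
        disease = QueryGroup(("hepatocellular carcinoma",))
        wv = generic_weights(space, disease, prov, g)
        assert all(0 <= v <= 1 for v in wv.weights.values())
        report = Report("r", "HCC", frozenset(deep[:4]))
        sv = specific_weights(report, space, g, disease, prov)
        assert all(0 <= v <= 1 for v in sv.weights.values())

    def test_planted_conditional_probability_recovered(self):
        # binomial oracle: with n disease abstracts and planted p, the
        # estimate should fall within 3 standard errors of p
        g = synthetic.generate_ontology(synthetic.OntologySpec(depth=4, seed=0))
        term = g.concept_ids[-1]
        p_true = 0.30
        corpus = synthetic.generate_corpus(
            synthetic.CorpusSpec(
                n_abstracts=5000,
                disease_mention_prob=1.0,
                p_term_given_disease={term: p_true},
                p_term_given_background=0.0,
                seed=42,
            ),
            g,
        )
        prov = CorpusCountProvider(corpus)
        disease = QueryGroup(("hepatocellular carcinoma", "HCC"))
        n_disease = prov.count(disease)
        assert n_disease == 5000
        tw = specific_term_probability(g.concept(term), disease, prov)
        se = np.sqrt(p_true * (1 - p_true) / n_disease)
        assert abs(tw.q - p_true) < 3 * se


class TestRankTerms:
    def test_descending_with_lexicographic_ties(self):
        ranked = rank_terms(
            [TermWeight("b", 0.9), TermWeight("a", 0.1), TermWeight("c", 0.9)]
        )
        assert [t.term_id for t in ranked] == ["b", "c", "a"]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.text("abc", min_size=1, max_size=3),
                              st.floats(0, 1)), max_size=10))
    def test_agrees_with_oracle_sort(self, pairs):
        terms = [TermWeight(tid, q) for tid, q in pairs]
        ranked = rank_terms(terms)
        oracle = sorted(terms, key=lambda t: (-t.q, t.term_id))
        assert ranked == oracle
        assert sorted(t.q for t in ranked) == sorted(q for _, q in pairs)
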