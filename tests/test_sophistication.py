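"""Lexical sophistication, Gini/megalalia, syntactic metrics, PCA composite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from textmarkers import (NormTable, SyntacticMetrics, fit_syntactic_pca, gini,
                         lexical_sophistication, load_norms, load_pca, megalalia,
                         save_pca, score_pc1, syntactic_metrics, write_norms)
from textmarkers.parsed_text import ROOT, ParsedDocument, Sentence, Token

from test_parsed_text import make_doc

NORMS = NormTable(
    ratings={"mamma": 2.0, "cibo": 2.0, "sifilide": 8.0, "semplice": 2.0, "raro": 9.0},
    scale_min=1.0,
    scale_max=10.0,
)


def gini_pairwise_oracle(values):
    """O(n^2) mean-absolute-difference definition, written independently."""
    x = list(values)
    n = len(x)
    total = sum(abs(a - b) for a in x for b in x)
    return total / (2 * n * n * (sum(x) / n))


class TestLexicalSophistication:
    def test_constant_ratings_mean(self):
        doc = make_doc([("mamma", "NOUN"), ("cibo", "NOUN")])
        assert lexical_sophistication(doc, NORMS).lexical_mean == 2.0

    def test_arithmetic_mean(self):
        doc = make_doc([("mamma", "NOUN"), ("sifilide", "NOUN")])
        assert lexical_sophistication(doc, NORMS).lexical_mean == 5.0

    def test_unmapped_lemma_skipped_with_coverage(self):
        doc = make_doc([("mamma", "NOUN"), ("zzz", "NOUN")])
        res = lexical_sophistication(doc, NORMS)
        assert res.lexical_mean == 2.0 and res.coverage == 0.5

    def test_punct_num_excluded(self):
        doc = make_doc([("mamma", "NOUN"), (".", "PUNCT"), ("5", "NUM")])
        res = lexical_sophistication(doc, NORMS)
        assert res.mapped_values == (2.0,) and res.coverage == 1.0

    def test_no_mapped_lemma_gives_nan(self):
        res = lexical_sophistication(make_doc([("zzz", "NOUN")]), NORMS)
        assert math.isnan(res.lexical_mean)

    def test_norm_roundtrip(self, tmp_path):
        path = tmp_path / "norms.tsv"
        write_norms(NORMS, path)
        again = load_norms(path)
        assert dict(again.ratings) == dict(NORMS.ratings)
        assert (again.scale_min, again.scale_max) == (1.0, 10.0)


class TestGini:
    def test_uniform_is_zero(self):
        assert gini([3.0, 3.0, 3.0]) == pytest.approx(0.0, abs=1e-15)

    def test_spiked_example(self):
        assert gini([1, 1, 1, 9]) == pytest.approx(0.5, abs=1e-12)

    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=40),
           st.floats(0.01, 50))
    @settings(deadline=None, max_examples=100)
    def test_scale_invariance(self, values, c):
        assert gini([v * c for v in values]) == pytest.approx(gini(values), rel=1e-9, abs=1e-9)

    def test_matches_pairwise_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            x = rng.uniform(0.0, 10.0, size=rng.integers(2, 60))
            if x.sum() == 0:
                continue
            assert gini(x) == pytest.approx(gini_pairwise_oracle(x), abs=1e-12)

    def test_bounded_by_one_minus_inverse_n(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 5, size=rng.integers(2, 30))
            n = x.size
            if x.sum() == 0:
                continue
            assert -1e-12 <= gini(x) <= 1 - 1 / n + 1e-12

    @pytest.mark.parametrize(
        "bad,match",
        [([1.0], "at least 2"), ([1.0, -2.0], "non-negative"), ([0.0, 0.0], "all-zero")],
    )
    def test_error_conditions_named(self, bad, match):
        with pytest.raises(ValueError, match=match):
            gini(bad)


class TestMegalalia:
    def test_uniform_document_is_zero(self):
        doc = make_doc([("mamma", "NOUN"), ("cibo", "NOUN"), ("semplice", "NOUN")])
        assert megalalia(doc, NORMS) == pytest.approx(0.0, abs=1e-15)

    def test_spike_strictly_increases(self):
        plain = make_doc([("mamma", "NOUN")] * 6)
        spiked = make_doc([("mamma", "NOUN")] * 5 + [("raro", "NOUN")])
        assert megalalia(spiked, NORMS) > megalalia(plain, NORMS)
        assert (
            lexical_sophistication(spiked, NORMS).lexical_mean
            > lexical_sophistication(plain, NORMS).lexical_mean
        )

    def test_synthetic_quarter_spike(self):
        # ratings [2,2,2,2]+[raro=9] absent; use 1,1,1,9 via a custom table
        table = NormTable(ratings={"a": 1.0, "b": 9.0}, scale_min=0, scale_max=10)
        doc = make_doc([("a", "NOUN")] * 3 + [("b", "NOUN")])
        assert megalalia(doc, table) == pytest.approx(0.5, abs=1e-12)

    def test_sentence_order_invariance(self, small_corpus):
        doc = small_corpus.docs[1]
        reordered = ParsedDocument(doc_id=doc.doc_id, sentences=tuple(reversed(doc.sentences)))
        assert megalalia(doc, small_corpus.norms) == pytest.approx(
            megalalia(reordered, small_corpus.norms), abs=1e-12
        )
        a = lexical_sophistication(doc, small_corpus.norms).lexical_mean
        b = lexical_sophistication(reordered, small_corpus.norms).lexical_mean
        assert a == pytest.approx(b, abs=1e-12)


class TestSyntacticMetrics:
    def test_mean_sentence_length(self):
        s1 = Sentence(tuple(
            Token(index=i, surface="x", lemma="x", upos="NOUN", head=ROOT if i == 0 else 0)
            for i in range(3)))
        s2 = Sentence(tuple(
            Token(index=i, surface="x", lemma="x", upos="NOUN", head=ROOT if i == 0 else 0)
            for i in range(5)))
        doc = ParsedDocument(doc_id="d", sentences=(s1, s2))
        assert syntactic_metrics(doc).mean_sentence_length == 4.0

    def test_clause_count_includes_aux(self):
        doc = make_doc([("io", "PRON"), ("avere", "AUX"), ("fare", "VERB")])
        assert syntactic_metrics(doc).mean_clauses == 2.0

    def test_max_dependency_distance_hand_enumerated(self):
        # heads: 0->1 (d=1), 1->ROOT (d=0), 2->1 (d=1), 3->0 (d=3) => max 3
        tokens = (
            Token(index=0, surface="a", lemma="a", upos="NOUN", head=1),
            Token(index=1, surface="b", lemma="b", upos="VERB", head=ROOT),
            Token(index=2, surface="c", lemma="c", upos="NOUN", head=1),
            Token(index=3, surface="d", lemma="d", upos="NOUN", head=0),
        )
        doc = ParsedDocument(doc_id="d", sentences=(Sentence(tokens),))
        assert syntactic_metrics(doc).mean_max_dep_distance == 3.0


def one_factor_metrics(n=200, noise_sd=0.1, seed=0):
    """Three metrics driven by one latent complexity factor plus noise."""
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n)
    return [
        SyntacticMetrics(
            doc_id=str(i),
            mean_sentence_length=10 + 2 * l + rng.normal(0, noise_sd),
            mean_clauses=2 + 0.5 * l + rng.normal(0, noise_sd),
            mean_max_dep_distance=5 + l + rng.normal(0, noise_sd),
        )
        for i, l in enumerate(latent)
    ]


class TestPcaComposite:
    def test_collinear_metrics_explain_everything(self):
        metrics = [
            SyntacticMetrics(doc_id=str(i), mean_sentence_length=v,
                             mean_clauses=2 * v, mean_max_dep_distance=3 * v)
            for i, v in enumerate([1.0, 2.0, 3.0, 4.0])
        ]
        model = fit_syntactic_pca(metrics)
        assert model.explained_variance_ratio == pytest.approx(1.0, abs=1e-12)

    def test_one_latent_factor_dominates(self):
        model = fit_syntactic_pca(one_factor_metrics())
        assert model.explained_variance_ratio > 0.8

    def test_orientation_deterministic_and_positive_on_length(self):
        model = fit_syntactic_pca(one_factor_metrics())
        assert model.loadings[0] > 0
        pc1 = score_pc1(model, one_factor_metrics())
        lengths = [m.mean_sentence_length for m in one_factor_metrics()]
        assert np.corrcoef(pc1, lengths)[0, 1] > 0

    def test_scores_centered_with_eigenvalue_variance(self):
        metrics = one_factor_metrics(noise_sd=0.5, seed=3)
        model = fit_syntactic_pca(metrics)
        pc1 = score_pc1(model, metrics)
        assert np.mean(pc1) == pytest.approx(0.0, abs=1e-10)
        assert np.var(pc1, ddof=1) == pytest.approx(model.first_eigenvalue, rel=1e-9)

    def test_zero_variance_metric_named_in_error(self):
        metrics = [
            SyntacticMetrics(doc_id=str(i), mean_sentence_length=5.0,
                             mean_clauses=float(i), mean_max_dep_distance=float(i * 2))
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="mean_sentence_length"):
            fit_syntactic_pca(metrics)

    def test_too_few_documents(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_syntactic_pca(one_factor_metrics(n=2))

    def test_model_roundtrip(self, tmp_path):
        model = fit_syntactic_pca(one_factor_metrics())
        path = tmp_path / "pca.txt"
        save_pca(model, path)
        again = load_pca(path)
        assert again.loadings == pytest.approx(model.loadings, abs=0)
        assert again.explained_variance_ratio == model.explained_variance_ratio
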