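"""The enrichment-difference lexicon and Pearson paper scoring."""

import math

import numpy as np
import pytest
from scipy import stats

from motifcurate import (
    BagOfWords,
    Document,
    PaperScore,
    ScoredLexicon,
    pearson,
    rank_papers,
    score_paper,
    train_lexicon,
    word_enrichment,
)
from motifcurate.corpus import bag_of_words
from motifcurate.scoring import (
    DegenerateDocumentError,
    ScoringError,
    TrainingError,
    ZeroVarianceError,
    read_lexicon,
    read_scores,
    score_bag,
    write_lexicon,
    write_scores,
)
from conftest import random_documents


# ---------------------------------------------------------------- oracles


def oracle_pearson(x, y):
    """Closed-form product-moment correlation, coded independently."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def oracle_lexicon(pos_bags, neg_bags):
    """Direct-summation lexicon: plain loops over raw counts."""
    vocab = sorted(
        {w for b in pos_bags for w in b.counts}
        | {w for b in neg_bags for w in b.counts}
    )
    scores = {}
    for w in vocab:
        wp = sum(b.counts.get(w, 0) / b.length for b in pos_bags) / len(pos_bags)
        wn = sum(b.counts.get(w, 0) / b.length for b in neg_bags) / len(neg_bags)
        scores[w] = wp - wn
    return scores


def oracle_paper_score(bag, words, scores):
    v = [bag.counts.get(w, 0) / bag.length for w in words]
    return oracle_pearson(v, list(scores))


def _bags(docs, stoplist):
    return [bag_of_words(d, stoplist) for d in docs]


# ---------------------------------------------------------------- enrichment


class TestWordEnrichment:
    def test_count_over_size(self):
        bag = BagOfWords({"kinase": 2, "binds": 1, "motif": 1}, 4)
        assert word_enrichment("kinase", bag) == 0.5

    def test_absent_word_is_zero(self):
        assert word_enrichment("absent", BagOfWords({"a": 1}, 1)) == 0.0

    def test_single_word_document_upper_bound(self):
        assert word_enrichment("a", BagOfWords({"a": 3}, 3)) == 1.0

    def test_zero_length_bag_is_an_error(self):
        with pytest.raises(DegenerateDocumentError):
            word_enrichment("a", BagOfWords({}, 0))


# ---------------------------------------------------------------- pearson


class TestPearson:
    def test_identity(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == 1.0

    def test_anti_linearity(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == -1.0

    def test_hand_computed_case(self):
        # centered x=(0,-1,1), y=(-2/3,1/3,1/3): covariance is exactly 0
        assert pearson([1, 0, 2], [0, 1, 1]) == pytest.approx(0.0, abs=1e-15)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_affine_invariance_and_symmetry(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson(x, y)
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson(3.5 * x + 2.0, y) == pytest.approx(r, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(2, 30)))
            y = rng.normal(size=len(x))
            assert pearson(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12
            )


# ---------------------------------------------------------------- training


class TestTrainLexicon:
    def test_single_word_extremes(self):
        p = [Document(pmid="1", abstract="motif")]
        n = [Document(pmid="2", abstract="control")]
        lex = train_lexicon(p, n, set())
        scores = dict(zip(lex.words, lex.scores))
        assert scores["motif"] == 1.0
        assert scores["control"] == -1.0

    def test_balanced_word_scores_zero(self):
        p = [Document(pmid="1", abstract="shared motif")]
        n = [Document(pmid="2", abstract="shared control")]
        lex = train_lexicon(p, n, set())
        assert dict(zip(lex.words, lex.scores))["shared"] == 0.0

    def test_antisymmetry(self, rng):
        vocab = [f"w{i}" for i in range(25)]
        p = random_documents(rng, 6, vocab, start=1)
        n = random_documents(rng, 7, vocab, start=100)
        fwd = train_lexicon(p, n, set())
        rev = train_lexicon(n, p, set())
        assert fwd.words == rev.words
        np.testing.assert_allclose(fwd.scores, -rev.scores, atol=1e-15)

    def test_matches_direct_summation_oracle(self, rng, stoplist):
        for _ in range(20):
            vocab = [f"w{i}" for i in range(20)]
            p = random_documents(rng, int(rng.integers(2, 10)), vocab, start=1)
            n = random_documents(rng, int(rng.integers(2, 10)), vocab, start=50)
            lex = train_lexicon(p, n, stoplist)
            expected = oracle_lexicon(_bags(p, stoplist), _bags(n, stoplist))
            assert lex.words == sorted(expected)
            for w, s in zip(lex.words, lex.scores):
                assert s == pytest.approx(expected[w], abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(TrainingError):
            train_lexicon([], [Document(pmid="1", abstract="x1")], set())

    def test_overlapping_pmids_rejected(self):
        d = Document(pmid="1", abstract="w1")
        with pytest.raises(TrainingError, match="overlap"):
            train_lexicon([d], [d], set())

    def test_zero_length_document_rejected(self):
        with pytest.raises(TrainingError, match="zero-length"):
            train_lexicon(
                [Document(pmid="1")], [Document(pmid="2", abstract="x1")], set()
            )

    def test_scores_bounded(self, rng):
        vocab = [f"w{i}" for i in range(15)]
        for _ in range(25):
            p = random_documents(rng, 4, vocab, start=1)
            n = random_documents(rng, 4, vocab, start=10)
            lex = train_lexicon(p, n, set())
            assert lex.scores.min() >= -1.0 and lex.scores.max() <= 1.0

    def test_determinism_bit_identical(self, rng, stoplist):
        vocab = [f"w{i}" for i in range(30)]
        p = random_documents(rng, 5, vocab, start=1)
        n = random_documents(rng, 5, vocab, start=20)
        a = train_lexicon(p, n, stoplist)
        b = train_lexicon(p, n, stoplist)
        assert a.words == b.words
        assert (a.scores == b.scores).all()


# ---------------------------------------------------------------- scoring


class TestScorePaper:
    def lexicon(self):
        return ScoredLexicon(["a", "b"], np.array([1.0, -1.0]), 1, 1)

    def test_perfectly_aligned_document(self):
        doc = Document(pmid="1", abstract="a a")
        ps = score_paper(doc, self.lexicon(), set())
        assert ps.pc == 1.0 and not ps.degenerate

    def test_uniform_counts_over_lexicon_degenerate(self):
        doc = Document(pmid="1", abstract="a b")
        ps = score_paper(doc, self.lexicon(), set())
        assert ps.pc == 0.0 and ps.degenerate

    def test_no_shared_words_degenerate(self):
        doc = Document(pmid="1", abstract="unrelated words here")
        ps = score_paper(doc, self.lexicon(), set())
        assert ps.pc == 0.0 and ps.degenerate

    def test_empty_document_degenerate(self):
        ps = score_paper(Document(pmid="1"), self.lexicon(), set())
        assert ps.pc == 0.0 and ps.degenerate

    def test_scale_invariance_of_counts(self, rng, stoplist):
        vocab = [f"w{i}" for i in range(20)]
        p = random_documents(rng, 5, vocab, start=1)
        n = random_documents(rng, 5, vocab, start=10)
        lex = train_lexicon(p, n, stoplist)
        doc = random_documents(rng, 1, vocab, mean_len=20, start=99)[0]
        base = score_paper(doc, lex, stoplist)
        for k in (2, 5, 17):
            bag = bag_of_words(doc, stoplist)
            scaled = BagOfWords(
                {w: c * k for w, c in bag.counts.items()}, bag.length * k
            )
            pc, degenerate = score_bag(scaled, lex)
            assert degenerate == base.degenerate
            assert pc == pytest.approx(base.pc, abs=1e-12)

    def test_matches_oracle_on_random_corpora(self, rng, stoplist):
        for _ in range(20):
            vocab = [f"w{i}" for i in range(25)]
            p = random_documents(rng, 5, vocab, start=1)
            n = random_documents(rng, 5, vocab, start=10)
            lex = train_lexicon(p, n, stoplist)
            doc = random_documents(rng, 1, vocab, mean_len=15, start=99)[0]
            ps = score_paper(doc, lex, stoplist)
            if not ps.degenerate:
                expected = oracle_paper_score(
                    bag_of_words(doc, stoplist), lex.words, lex.scores
                )
                assert ps.pc == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- ranking


class TestRankPapers:
    def test_descending_order(self):
        scores = [
            PaperScore("p1", 0.2),
            PaperScore("p2", 0.9),
            PaperScore("p3", -0.1),
        ]
        assert [s.pmid for s in rank_papers(scores)] == ["p2", "p1", "p3"]

    def test_tie_broken_by_ascending_pmid(self):
        scores = [PaperScore("20", 0.5), PaperScore("3", 0.5)]
        assert [s.pmid for s in rank_papers(scores)] == ["3", "20"]

    def test_display_cap_default_1000(self):
        scores = [PaperScore(str(i), i / 2000.0) for i in range(1, 1501)]
        assert len(rank_papers(scores)) == 1000

    def test_explicit_limit(self):
        scores = [PaperScore(str(i), 0.0) for i in range(1, 11)]
        assert len(rank_papers(scores, limit=3)) == 3


# ---------------------------------------------------------------- persistence


class TestPersistence:
    def test_lexicon_roundtrip_to_six_decimals(self):
        lex = ScoredLexicon(
            ["alpha", "beta"], np.array([0.123456789, -1.0]), 3, 4
        )
        text = write_lexicon(lex)
        assert text.startswith("#n_pos=3 n_neg=4\n")
        back = read_lexicon(text)
        assert back.words == lex.words
        assert (back.n_pos, back.n_neg) == (3, 4)
        np.testing.assert_allclose(back.scores, lex.scores, atol=5e-7)

    def test_scores_roundtrip(self):
        scores = [PaperScore("1", 0.25), PaperScore("2", -0.5, True)]
        back = read_scores(write_scores(scores))
        assert [(s.pmid, s.degenerate) for s in back] == [
            ("1", False),
            ("2", True),
        ]

    def test_bad_header_rejected(self):
        with pytest.raises(ScoringError, match="header"):
            read_lexicon("word\t0.5\n")
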