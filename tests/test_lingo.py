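"""LINGO extraction, LINGOsim, and the TF / TF-IDF cosine kernels."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import smilesim as sm

smiles_like = st.text(alphabet="CcNO()=#0", min_size=4, max_size=30)


@pytest.fixture
def sample_profiles(sample_records):
    r1, r2 = sample_records
    return sm.extract_lingos(r1), sm.extract_lingos(r2)


@pytest.fixture
def sample_vocab(sample_profiles):
    return sm.build_vocabulary(list(sample_profiles))


class TestExtraction:
    def test_sample_profiles_match_tabulated_counts(self, sample_profiles):
        p1, p2 = sample_profiles
        assert dict(p1.counts) == {"OC(O": 1, "C(O)": 1, "(O)=": 1, "O)=O": 1}
        assert dict(p2.counts) == {
            "CCCC": 2, "CCC(": 1, "CC(O": 1, "C(O)": 1, "(O)=": 1, "O)=C": 1, ")=C0": 1,
        }

    def test_short_string_gives_empty_profile(self):
        assert not sm.extract_lingos("AB", q=4).counts

    @given(smiles_like, st.integers(min_value=1, max_value=5))
    def test_lingo_count_formula(self, s, q):
        profile = sm.extract_lingos(s, q)
        assert profile.total() == max(0, len(s) - (q - 1))
        assert all(len(t) == q for t in profile.counts)


class TestLingosim:
    def test_worked_example(self, sample_profiles):
        assert sm.lingosim(*sample_profiles) == pytest.approx(2 / 9)

    def test_identity_and_disjoint(self):
        p = sm.extract_lingos("CCCCC(O)=C0")
        assert sm.lingosim(p, p) == 1.0
        q = sm.extract_lingos("NNNNNNN")
        assert sm.lingosim(p, q) == 0.0

    def test_q_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            sm.lingosim(sm.extract_lingos("CCCCC", 4), sm.extract_lingos("CCCCC", 3))

    @given(smiles_like, smiles_like)
    def test_symmetric_and_bounded(self, s1, s2):
        p1, p2 = sm.extract_lingos(s1), sm.extract_lingos(s2)
        v = sm.lingosim(p1, p2)
        assert v == pytest.approx(sm.lingosim(p2, p1))
        assert 0.0 <= v <= 1.0


class TestWeighting:
    @pytest.mark.parametrize(
        ("count", "expected"), [(0, 0.0), (1, 1.0), (2, 1 + math.log10(2)), (10, 2.0)]
    )
    def test_tf_weight(self, count, expected):
        assert sm.tf_weight(count) == pytest.approx(expected)

    def test_vocabulary_build(self, sample_vocab):
        assert len(sample_vocab.terms) == 9
        assert sample_vocab.n_docs == 2
        assert sample_vocab.doc_freq["C(O)"] == 2
        assert sample_vocab.doc_freq["CCCC"] == 1
        # deterministic insertion order of first appearance
        assert sample_vocab.terms == [
            "OC(O", "C(O)", "(O)=", "O)=O", "CCCC", "CCC(", "CC(O", "O)=C", ")=C0",
        ]

    def test_vocabulary_requires_nonempty_uniform_corpus(self):
        with pytest.raises(ValueError, match="empty"):
            sm.build_vocabulary([])
        with pytest.raises(ValueError, match="mixed"):
            sm.build_vocabulary([sm.extract_lingos("CCCCC", 4), sm.extract_lingos("CCCCC", 3)])

    def test_idf_enzyme_corpus_values(self):
        # stop-word-like vs rare LINGO of a 445-compound corpus
        vocab = sm.CorpusVocabulary(
            q=4, terms=["(=O)", "O)CO"], doc_freq={"(=O)": 300, "O)CO": 18}, n_docs=445
        )
        assert round(sm.idf("(=O)", vocab), 2) == 0.17
        assert round(sm.idf("O)CO", vocab), 2) == 1.39
        with pytest.raises(KeyError):
            sm.idf("XXXX", vocab)

    def test_idf_of_ubiquitous_term_is_zero(self):
        vocab = sm.CorpusVocabulary(q=4, terms=["CCCC"], doc_freq={"CCCC": 3}, n_docs=3)
        assert sm.idf("CCCC", vocab) == 0.0


class TestCosine:
    def test_tf_vectors_match_worked_example(self, sample_profiles, sample_vocab):
        p1, p2 = sample_profiles
        v1 = sm.vectorize(p1, sample_vocab, "tf")
        v2 = sm.vectorize(p2, sample_vocab, "tf")
        assert v1.to_dense().tolist() == [1, 1, 1, 1, 0, 0, 0, 0, 0]
        expected2 = [0, 1, 1, 0, 1 + math.log10(2), 1, 1, 1, 1]
        assert v2.to_dense() == pytest.approx(expected2)

    def test_tf_cosine_worked_example(self, sample_profiles, sample_vocab):
        p1, p2 = sample_profiles
        v1 = sm.vectorize(p1, sample_vocab, "tf")
        v2 = sm.vectorize(p2, sample_vocab, "tf")
        value = sm.cosine_similarity(v1, v2)
        assert value == pytest.approx(2 / (2 * math.sqrt(6 + (1 + math.log10(2)) ** 2)))
        assert round(value, 2) == 0.36

    def test_tfidf_cosine_from_printed_rounded_vectors(self):
        # cosine of the worked example's tabulated (rounded) vectors
        a = [2.3, 0.5, 0.6, 0.4, 0, 0, 0, 0, 0]
        b = [0, 0.5, 0.6, 0, 1.04, 0.9, 1, 2, 1.9]
        dot = sum(x * y for x, y in zip(a, b))
        norm = math.sqrt(sum(x * x for x in a)) * math.sqrt(sum(y * y for y in b))
        assert dot == pytest.approx(0.61)
        assert norm == pytest.approx(8.2, abs=0.01)
        assert round(dot / norm, 2) == 0.07

    def test_tfidf_cosine_full_precision(self, sample_profiles):
        # same pair embedded in a 445-document corpus with the tabulated
        # document frequencies; full-precision IDFs give ~0.084
        dfs = {"OC(O": 2, "C(O)": 113, "(O)=": 105, "O)=O": 143, "CCCC": 61,
               "CCC(": 49, "CC(O": 36, "O)=C": 4, ")=C0": 5}
        vocab = sm.CorpusVocabulary(q=4, terms=list(dfs), doc_freq=dfs, n_docs=445)
        p1, p2 = sample_profiles
        v1 = sm.vectorize(p1, vocab, "tf-idf")
        v2 = sm.vectorize(p2, vocab, "tf-idf")
        assert sm.cosine_similarity(v1, v2) == pytest.approx(0.0843, abs=1e-3)

    def test_identity_orthogonal_and_zero(self, sample_profiles, sample_vocab):
        p1, p2 = sample_profiles
        v1 = sm.vectorize(p1, sample_vocab, "tf")
        assert sm.cosine_similarity(v1, v1) == pytest.approx(1.0)
        empty = sm.vectorize(sm.extract_lingos("AB"), sample_vocab, "tf")
        assert sm.cosine_similarity(v1, empty) == 0.0

    def test_all_ubiquitous_tfidf_degenerates_to_zero(self, sample_profiles):
        p1, _ = sample_profiles
        vocab = sm.build_vocabulary([p1])
        v = sm.vectorize(p1, vocab, "tf-idf")  # all idf = 0
        assert sm.cosine_similarity(v, v) == 0.0

    def test_vocabulary_mismatch_raises(self, sample_profiles):
        p1, p2 = sample_profiles
        va = sm.build_vocabulary([p1])
        vb = sm.build_vocabulary([p2])
        with pytest.raises(ValueError, match="vocabular"):
            sm.cosine_similarity(sm.vectorize(p1, va), sm.vectorize(p2, vb))

    def test_out_of_vocabulary_lingos_dropped(self, sample_profiles):
        p1, p2 = sample_profiles
        vocab = sm.build_vocabulary([p1])
        v2 = sm.vectorize(p2, vocab, "tf")
        assert set(v2.weights) <= set(range(len(vocab.terms)))


class TestReport:
    def test_ranked_by_document_frequency(self):
        vocab = sm.CorpusVocabulary(
            q=4, terms=["BBBB", "AAAA"], doc_freq={"AAAA": 3, "BBBB": 1}, n_docs=3
        )
        rows = sm.corpus_lingo_report(vocab, top_k=2)
        assert [r[0] for r in rows] == ["AAAA", "BBBB"]
        assert rows[0][2] == 0.0  # ubiquitous term ranks first with idf 0

    def test_planted_ubiquitous_lingo_ranks_first(self):
        spec = sm.SyntheticSpec(n_drugs=20, n_targets=10, n_clusters=1, motif_len=8, seed=3)
        records, _ = sm.generate_smiles_corpus(spec)
        vocab = sm.build_vocabulary([sm.extract_lingos(r) for r in records])
        top = sm.corpus_lingo_report(vocab, top_k=1)[0]
        assert top[1] == len(records)  # motif 4-grams appear in every drug
        assert top[2] == 0.0

    def test_top_k_validation(self):
        vocab = sm.CorpusVocabulary(q=4, terms=["AAAA"], doc_freq={"AAAA": 1}, n_docs=1)
        with pytest.raises(ValueError):
            sm.corpus_lingo_report(vocab, top_k=0)
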