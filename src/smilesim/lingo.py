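"""LINGO q-gram profiles, LINGOsim, and TF / TF-IDF cosine kernels.

A LINGO is a contiguous q-character substring of a (ring-zeroed) SMILES
string; a string of length n yields ``n - (q - 1)`` LINGOs with
multiplicity.  LINGOsim compares two profiles directly with a per-term
count Tanimoto averaged over the union of their LINGOs.  The TF and
TF-IDF cosine kernels borrow the vector space model from information
retrieval: each compound is a "document", each LINGO a "term", and
compound similarity is the cosine between weighted term vectors over a
corpus-wide vocabulary.  Rare LINGOs get high inverse document
frequency (IDF) weight; ubiquitous ones behave like stop words.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .prep import CompoundRecord

logger = logging.getLogger(__name__)

DEFAULT_Q = 4


@dataclass
class LingoProfile:
    """Multiset of q-character LINGOs of one SMILES string."""

    q: int
    counts: Counter

    def total(self) -> int:
        return sum(self.counts.values())


def extract_lingos(record: CompoundRecord | str, q: int = DEFAULT_Q) -> LingoProfile:
    """Sliding-window q-grams of the ring-zeroed SMILES, with multiplicity.

    Accepts a :class:`CompoundRecord` (its ``lingo_smiles`` is used) or a
    string already preprocessed by the caller.  Strings shorter than
    ``q`` give an empty profile.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    s = record.lingo_smiles if isinstance(record, CompoundRecord) else record
    if len(s) < q:
        logger.debug("string %r shorter than q=%d; empty LINGO profile", s, q)
        return LingoProfile(q, Counter())
    return LingoProfile(q, Counter(s[i : i + q] for i in range(len(s) - q + 1)))


def lingosim(p1: LingoProfile, p2: LingoProfile) -> float:
    """Per-LINGO count Tanimoto averaged over the union of unique LINGOs.

    ``(1/m) * sum_i [1 - |N1_i - N2_i| / (N1_i + N2_i)]`` over the m
    unique LINGOs of the union.
    """
    if p1.q != p2.q:
        raise ValueError(f"LINGO length mismatch: {p1.q} != {p2.q}")
    terms = set(p1.counts) | set(p2.counts)
    if not terms:
        logger.warning("lingosim of two empty profiles; returning 0")
        return 0.0
    total = sum(
        1.0 - abs(p1.counts[t] - p2.counts[t]) / (p1.counts[t] + p2.counts[t])
        for t in terms
    )
    return total / len(terms)


def tf_weight(count: int) -> float:
    """Sublinear term-frequency weight: ``1 + log10(count)``, 0 for 0."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return 0.0 if count == 0 else 1.0 + math.log10(count)


@dataclass
class CorpusVocabulary:
    """Unique LINGOs of a compound corpus with document frequencies.

    Term order is the insertion order of first appearance over the
    corpus, which makes vectors and reports reproducible byte-for-byte.
    """

    q: int
    terms: list[str]
    doc_freq: dict[str, int]
    n_docs: int
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")

    def idf(self, term: str) -> float:
        return idf(term, self)


def build_vocabulary(corpus: Sequence[LingoProfile]) -> CorpusVocabulary:
    """Union of corpus LINGOs with per-term document frequencies."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    q = corpus[0].q
    terms: list[str] = []
    doc_freq: dict[str, int] = {}
    for profile in corpus:
        if profile.q != q:
            raise ValueError(f"mixed LINGO lengths in corpus: {profile.q} != {q}")
        for t in profile.counts:
            if t not in doc_freq:
                terms.append(t)
                doc_freq[t] = 0
            doc_freq[t] += 1
    return CorpusVocabulary(q=q, terms=terms, doc_freq=doc_freq, n_docs=len(corpus))


def idf(term: str, vocab: CorpusVocabulary) -> float:
    """Inverse document frequency ``log10(N / df)``, unsmoothed."""
    if term not in vocab.doc_freq:
        raise KeyError(f"term {term!r} not in vocabulary")
    return math.log10(vocab.n_docs / vocab.doc_freq[term])


@dataclass
class WeightedVector:
    """Sparse non-negative term weights over a fixed vocabulary."""

    vocabulary: CorpusVocabulary
    weights: dict[int, float]

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))

    def to_dense(self) -> np.ndarray:
        v = np.zeros(len(self.vocabulary.terms))
        for i, w in self.weights.items():
            v[i] = w
        return v


Scheme = Literal["tf", "tf-idf"]


def vectorize(
    profile: LingoProfile, vocab: CorpusVocabulary, scheme: Scheme = "tf"
) -> WeightedVector:
    """Weight a LINGO profile against a corpus vocabulary.

    LINGOs absent from the vocabulary (possible when scoring unseen
    compounds against a training-fold vocabulary) are dropped; the
    dropped count is logged at debug level.
    """
    if scheme not in ("tf", "tf-idf"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    if profile.q != vocab.q:
        raise ValueError(f"LINGO length mismatch: profile q={profile.q}, vocab q={vocab.q}")
    weights: dict[int, float] = {}
    dropped = 0
    for term, count in profile.counts.items():
        i = vocab.index.get(term)
        if i is None:
            dropped += 1
            continue
        w = tf_weight(count)
        if scheme == "tf-idf":
            w *= idf(term, vocab)
        if w != 0.0:
            weights[i] = w
    if dropped:
        logger.debug("vectorize dropped %d out-of-vocabulary LINGOs", dropped)
    return WeightedVector(vocab, weights)


def cosine_similarity(v1: WeightedVector, v2: WeightedVector) -> float:
    """Cosine of two weighted vectors; 0 if either is the zero vector."""
    if v1.vocabulary is not v2.vocabulary and v1.vocabulary.terms != v2.vocabulary.terms:
        raise ValueError("vectors built over different vocabularies")
    n1, n2 = v1.norm(), v2.norm()
    if n1 == 0.0 or n2 == 0.0:
        logger.warning("cosine_similarity with a zero vector; returning 0")
        return 0.0
    small, big = (v1.weights, v2.weights) if len(v1.weights) <= len(v2.weights) else (
        v2.weights,
        v1.weights,
    )
    dot = sum(w * big.get(i, 0.0) for i, w in small.items())
    return dot / (n1 * n2)


def corpus_lingo_report(
    vocab: CorpusVocabulary, top_k: int
) -> list[tuple[str, int, float]]:
    """Most common LINGOs of a corpus: (term, doc_freq, idf) rows.

    Sorted by ascending IDF (descending document frequency), ties broken
    lexicographically; low-IDF terms are the corpus "stop LINGOs".
    """
    if top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    ranked = sorted(vocab.terms, key=lambda t: (-vocab.doc_freq[t], t))
    return [(t, vocab.doc_freq[t], idf(t, vocab)) for t in ranked[:top_k]]
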