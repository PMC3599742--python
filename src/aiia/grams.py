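"""Gram vocabulary enumeration, overlapping n-gram counting, and
per-record probability features.

A "gram" is a contiguous, order-sensitive run of n symbols ("ab" and "ba"
are distinct grams).  For alphabet size k and maximal order n_max the
vocabulary holds k + k^2 + ... + k^n_max grams — 18,278 for k=26, n_max=3.
Counting uses every overlapping window of stride 1, so a sequence of
length L contributes L - n + 1 windows of order n; each gram's probability
is its count divided by the window total of its order, making each order a
proper probability distribution over its grams.
"""

from __future__ import annotations

import itertools
import string
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    AlphabetMismatchError,
    AlphabetOverflowError,
    ParameterError,
)
from .symbolize import SymbolSequence

__all__ = [
    "GramVocabulary",
    "GramFeatures",
    "build_vocabulary",
    "count_ngrams",
    "featurize",
    "NGramFeaturizer",
]


@dataclass(frozen=True)
class GramVocabulary:
    """Canonical ordered list of all grams of orders 1..n_max over k letters.

    Canonical order is by gram length, then lexicographic, so e.g. for
    k=2, n_max=2 the order is a, b, aa, ab, ba, bb.  This order defines the
    column order of every feature matrix, making files byte-comparable
    across runs.
    """

    k: int
    n_max: int
    grams: tuple

    @property
    def size(self) -> int:
        return len(self.grams)

    @property
    def alphabet(self) -> str:
        return string.ascii_lowercase[: self.k]

    def index(self) -> Dict[str, int]:
        """Gram -> canonical column position."""
        return {g: i for i, g in enumerate(self.grams)}


def build_vocabulary(k: int, n_max: int) -> GramVocabulary:
    """Enumerate all grams of orders 1..n_max over the first k letters.

    The vocabulary size is sum_{n=1}^{n_max} k^n; with the full 26-letter
    alphabet and n_max=3 this is 26 + 676 + 17,576 = 18,278.
    """
    if k > 26:
        raise AlphabetOverflowError(f"k={k} exceeds the 26-letter alphabet")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if n_max < 1:
        raise ParameterError(f"n_max must be >= 1, got {n_max}")
    letters = string.ascii_lowercase[:k]
    grams = tuple(
        "".join(p)
        for n in range(1, n_max + 1)
        for p in itertools.product(letters, repeat=n)
    )
    return GramVocabulary(k=k, n_max=n_max, grams=grams)


def count_ngrams(
    symbols: Union[SymbolSequence, str], n: int
) -> Dict[str, int]:
    """Count overlapping n-grams (stride 1) in a symbol sequence.

    Counts sum to max(L - n + 1, 0).  Counting is order-sensitive: "ab" and
    "ba" are different grams.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    s = symbols.symbols if isinstance(symbols, SymbolSequence) else symbols
    return dict(Counter(s[i : i + n] for i in range(len(s) - n + 1)))


@dataclass(frozen=True)
class GramFeatures:
    """Per-record gram probabilities over a fixed vocabulary.

    ``probabilities`` is sparse: grams never observed are absent and read
    as 0.  For each order n with sequence length L >= n the probabilities
    of that order sum to 1.
    """

    record_id: str
    label: Optional[str]
    vocabulary: GramVocabulary
    probabilities: Dict[str, float]

    def get(self, gram: str) -> float:
        return self.probabilities.get(gram, 0.0)

    def to_vector(self) -> np.ndarray:
        """Dense probability vector in canonical vocabulary order."""
        vec = np.zeros(self.vocabulary.size)
        idx = self.vocabulary.index()
        for gram, p in self.probabilities.items():
            vec[idx[gram]] = p
        return vec


def featurize(
    symbols: SymbolSequence, vocabulary: GramVocabulary
) -> GramFeatures:
    """Build the per-record probability vector over the full vocabulary.

    The probability of a gram of order n is count / (L - n + 1), i.e. the
    fraction of the sequence's overlapping order-n windows showing that
    gram; normalisation holds per order.
    """
    seq = symbols.symbols
    extra = set(seq) - set(vocabulary.alphabet)
    if extra:
        raise AlphabetMismatchError(
            f"record {symbols.record_id!r}: letters {sorted(extra)} outside "
            f"the vocabulary alphabet {vocabulary.alphabet!r}"
        )
    probs: Dict[str, float] = {}
    L = len(seq)
    for n in range(1, vocabulary.n_max + 1):
        windows = L - n + 1
        if windows <= 0:
            continue
        for gram, c in count_ngrams(seq, n).items():
            probs[gram] = c / windows
    return GramFeatures(
        record_id=symbols.record_id,
        label=symbols.label,
        vocabulary=vocabulary,
        probabilities=probs,
    )


class NGramFeaturizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: symbol sequences to a dense feature matrix.

    Parameters
    ----------
    n_clusters : int, default 10
        Alphabet size k of the upstream symbolizer; fixes the vocabulary.
    n_max : int, default 3
        Maximal gram order.

    The output matrix has one row per sequence and one column per gram in
    canonical vocabulary order.  The transformer is stateless apart from
    the vocabulary it enumerates at fit time (``vocabulary_``).
    """

    def __init__(self, n_clusters: int = 10, n_max: int = 3):
        self.n_clusters = n_clusters
        self.n_max = n_max

    def fit(self, X: Sequence, y=None) -> "NGramFeaturizer":
        self.vocabulary_ = build_vocabulary(self.n_clusters, self.n_max)
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            self.fit(X)
        vocab = self.vocabulary_
        idx = vocab.index()
        out = np.zeros((len(X), vocab.size))
        for row, item in enumerate(X):
            seq = item if isinstance(item, SymbolSequence) else SymbolSequence("", item)
            feats = featurize(seq, vocab)
            for gram, p in feats.probabilities.items():
                out[row, idx[gram]] = p
        return out
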