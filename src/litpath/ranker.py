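"""Relevance ranking of abstracts against a background set.

A small training set of hand-picked relevant abstracts is compared with a
background set; each vocabulary word gets a smoothed log-odds weight based
on document frequency,

    weight(w) = log[(df_train(w)+s) / (|train|+2s)]
             -  log[(df_bg(w)+s)    / (|bg|+2s)],

and an abstract scores the sum of the weights of its *distinct* words
(presence-based, matching the document-frequency fit).  Empirical p-values
come from a null of word-wise resamples of the background unigram
distribution: p = (1 + #{null >= score}) / (null_size + 1).  The working
corpus is the top-N abstracts that also clear the p-value threshold
(defaults: N=1000, p<0.01).
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import AbstractRecord
from .errors import UsageError
from .resources import stopwords

__all__ = ["WordWeightTable", "RankedAbstract", "tokenize", "fit_weights",
           "score_abstract", "rank_and_select"]

_TOKEN = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lower-cased alphanumeric tokens with stop-words removed."""
    if not text:
        return []
    stops = stopwords()
    return [t for t in _TOKEN.findall(text.lower()) if t not in stops]


@dataclass(frozen=True)
class WordWeightTable:
    """Per-word discrimination weights plus the smoothing that produced them."""

    weights: dict[str, float]
    vocab_size: int
    smoothing: float

    def weight(self, word: str) -> float:
        return self.weights.get(word, 0.0)


@dataclass(frozen=True)
class RankedAbstract:
    pmid: str
    score: float
    p_value: float
    rank: int


def _doc_words(abstract: AbstractRecord) -> set[str]:
    return set(tokenize(abstract.text))


def fit_weights(training: Sequence[AbstractRecord], background: Sequence[AbstractRecord],
                smoothing: float = 1.0) -> WordWeightTable:
    """Fit discriminating-word weights from document frequencies."""
    if not training:
        raise UsageError("fit_weights: training set is empty")
    if not background:
        raise UsageError("fit_weights: background set is empty")
    if smoothing <= 0:
        raise UsageError("fit_weights: smoothing must be > 0")
    df_train: dict[str, int] = {}
    df_bg: dict[str, int] = {}
    for abstract in training:
        for w in _doc_words(abstract):
            df_train[w] = df_train.get(w, 0) + 1
    for abstract in background:
        for w in _doc_words(abstract):
            df_bg[w] = df_bg.get(w, 0) + 1
    vocab = set(df_train) | set(df_bg)
    s, nt, nb = smoothing, len(training), len(background)
    weights = {
        w: math.log((df_train.get(w, 0) + s) / (nt + 2 * s))
        - math.log((df_bg.get(w, 0) + s) / (nb + 2 * s))
        for w in sorted(vocab)
    }
    return WordWeightTable(weights=weights, vocab_size=len(vocab), smoothing=s)


def score_abstract(abstract: AbstractRecord | str, table: WordWeightTable) -> float:
    """Sum of weights of the abstract's distinct vocabulary words."""
    text = abstract.text if isinstance(abstract, AbstractRecord) else abstract
    return float(sum(table.weight(w) for w in set(tokenize(text))))


def _null_scores(background: Sequence[AbstractRecord], table: WordWeightTable,
                 null_size: int, rng: np.random.Generator) -> np.ndarray:
    """Score word-wise resamples of the background distribution.

    Null abstracts draw their length from the empirical background length
    distribution and their words i.i.d. from the pooled background tokens.
    """
    pool: list[str] = []
    lengths: list[int] = []
    for abstract in background:
        toks = tokenize(abstract.text)
        pool.extend(toks)
        lengths.append(len(toks))
    if not pool:
        return np.zeros(null_size)
    pool_arr = np.array(pool)
    lengths_arr = np.array(lengths)
    scores = np.empty(null_size)
    for i in range(null_size):
        n = int(rng.choice(lengths_arr))
        words = rng.choice(pool_arr, size=n) if n else []
        scores[i] = sum(table.weight(w) for w in set(words))
    return scores


def rank_and_select(
    corpus: Sequence[AbstractRecord],
    table: WordWeightTable,
    background: Sequence[AbstractRecord],
    *,
    n_top: int = 1000,
    p_threshold: float = 0.01,
    null_size: int = 10_000,
    rng_seed: int = 0,
    exclude_pmids: Optional[Iterable[str]] = None,
) -> list[RankedAbstract]:
    """Rank a corpus and select the significant top-N working set.

    Abstracts in ``exclude_pmids`` (typically the training set) are dropped
    before ranking.  Ties in score order by ascending PMID.  Returns the
    top ``n_top`` abstracts with ``p_value < p_threshold`` in rank order.
    """
    if null_size < 1:
        raise UsageError("rank_and_select: null_size must be >= 1")
    if n_top < 0:
        raise UsageError("rank_and_select: n_top must be >= 0")
    excluded = set(exclude_pmids or ())
    pool = [a for a in corpus if a.pmid not in excluded]
    if n_top > len(pool):
        raise UsageError(f"rank_and_select: n_top={n_top} exceeds corpus size {len(pool)}")
    rng = np.random.default_rng(rng_seed)
    null = np.sort(_null_scores(background, table, null_size, rng))
    ranked = sorted(pool, key=lambda a: (-score_abstract(a, table), a.pmid))
    out = []
    for rank, abstract in enumerate(ranked, 1):
        s = score_abstract(abstract, table)
        n_ge = null_size - int(np.searchsorted(null, s, side="left"))
        p = (1 + n_ge) / (null_size + 1)
        out.append(RankedAbstract(pmid=abstract.pmid, score=s, p_value=p, rank=rank))
    return [r for r in out[:n_top] if r.p_value < p_threshold]
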