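"""Gene/interaction-word tagging and biointeraction classification.

The classifier follows the sentence/abstract evidence hierarchy used by
dictionary-based biointeraction extractors:

* **type 1** — within one sentence: a gene name, then an interaction word,
  then another gene name, in that order (the strongest evidence class; the
  one used for pathway building);
* **type 2** — both genes in one sentence and an interaction word present
  in the sentence but not between them;
* **type 3** — both genes in one sentence, no interaction word;
* **type 4** — the two genes co-occur in the abstract but never in the
  same sentence (weakest evidence).

Tagging is purely dictionary-based: longest match, left to right, anchored
at token boundaries.  Symbols of three characters or fewer match
case-sensitively to limit false hits on common words; longer names match
case-insensitively.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

from .corpus import AbstractRecord

__all__ = [
    "Sentence",
    "GeneMention",
    "WordMention",
    "Biointeraction",
    "segment_sentences",
    "tag_genes",
    "tag_interaction_words",
    "classify_sentence",
    "extract_abstract",
]

# Trailing tokens that end in '.' without ending a sentence.
_ABBREVIATIONS = {
    "e.g", "i.e", "et al", "al", "cf", "vs", "etc", "fig", "figs",
    "dr", "no", "ref", "approx", "ca",
}

_SHORT_SYMBOL_LEN = 3  # symbols this short match case-sensitively


@dataclass(frozen=True)
class Sentence:
    """One sentence with its position in the source text.

    ``raw`` is the exact source slice including trailing whitespace, so
    concatenating the raw slices of all sentences reconstructs the text.
    """

    index: int
    start: int
    raw: str

    @property
    def text(self) -> str:
        return self.raw.rstrip()

    @property
    def end(self) -> int:
        return self.start + len(self.raw)


@dataclass(frozen=True)
class GeneMention:
    symbol: str
    surface: str
    sentence_index: int
    span: tuple[int, int]  # half-open char offsets within the sentence
    pmid: Optional[str] = None


@dataclass(frozen=True)
class WordMention:
    word: str  # canonical (lower-case) lexicon entry
    surface: str
    sentence_index: int
    span: tuple[int, int]
    polarity: str


@dataclass(frozen=True)
class Biointeraction:
    gene_a: str
    word: Optional[str]
    gene_b: str
    type_code: int
    pmid: Optional[str] = None
    sentence_index: Optional[int] = None  # None only for type 4
    polarity: str = "unknown"

    def __post_init__(self):
        if self.type_code not in (1, 2, 3, 4):
            raise ValueError(f"type_code must be 1-4, got {self.type_code}")
        if self.type_code == 4 and self.sentence_index is not None:
            raise ValueError("type-4 interactions are abstract-level: sentence_index must be None")

    @property
    def key(self) -> tuple:
        return (self.pmid, self.gene_a, self.word, self.gene_b, self.type_code)


def segment_sentences(text: str) -> list[Sentence]:
    """Rule-based sentence segmentation with offsets.

    Splits on sentence-final punctuation (., !, ?) followed by whitespace
    and a capital letter or digit, protecting common abbreviations.
    Concatenating ``raw`` slices reconstructs the input exactly.
    """
    if not text:
        return []
    splits = []
    for m in re.finditer(r"[.!?](\s+)(?=[A-Z0-9])", text):
        before = text[: m.start()]
        token = re.search(r"[\w.]*\w$", before)
        if token and token.group(0).lower() in _ABBREVIATIONS:
            continue
        two = re.search(r"(\w+)\s+(\w+)$", before)
        if two and f"{two.group(1)} {two.group(2)}".lower() in _ABBREVIATIONS:
            continue
        splits.append(m.end())
    sentences = []
    prev = 0
    for i, pos in enumerate([*splits, len(text)]):
        if pos > prev:
            sentences.append(Sentence(index=len(sentences), start=prev, raw=text[prev:pos]))
            prev = pos
    return sentences


def _boundary_pattern(terms_ci: Sequence[str], terms_cs: Sequence[str]) -> re.Pattern:
    """Alternation over terms, longest first, token-boundary anchored.

    ``terms_ci`` match case-insensitively, ``terms_cs`` exactly.
    """
    alts = [(t, True) for t in terms_ci] + [(t, False) for t in terms_cs]
    alts.sort(key=lambda p: (-len(p[0]), p[0]))
    body = "|".join(f"(?i:{re.escape(t)})" if ci else re.escape(t) for t, ci in alts)
    return re.compile(rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])")


@lru_cache(maxsize=16)
def _gene_matcher(items: tuple[tuple[str, str], ...]):
    """items: (synonym, symbol) pairs -> (pattern, surface->symbol map)."""
    ci = [syn for syn, _ in items if len(syn) > _SHORT_SYMBOL_LEN]
    cs = [syn for syn, _ in items if len(syn) <= _SHORT_SYMBOL_LEN]
    lookup_ci = {syn.lower(): sym for syn, sym in items if len(syn) > _SHORT_SYMBOL_LEN}
    lookup_cs = {syn: sym for syn, sym in items if len(syn) <= _SHORT_SYMBOL_LEN}
    return _boundary_pattern(ci, cs), lookup_ci, lookup_cs


def tag_genes(
    sentence: str | Sentence,
    dictionary: dict[str, list[str]],
    *,
    sentence_index: int = 0,
    pmid: Optional[str] = None,
) -> list[GeneMention]:
    """Tag gene-name mentions in one sentence.

    Longest-match, left-to-right, token-boundary anchored over all synonyms
    of all dictionary symbols; each surface form maps back to its canonical
    symbol.  Mentions are returned in span order and never overlap.
    """
    if isinstance(sentence, Sentence):
        sentence_index = sentence.index
        sentence = sentence.text
    items = tuple(
        sorted((syn, sym) for sym, syns in dictionary.items() for syn in dict.fromkeys([sym, *syns]))
    )
    if not items:
        return []
    pattern, lookup_ci, lookup_cs = _gene_matcher(items)
    mentions = []
    for m in pattern.finditer(sentence):
        surface = m.group(0)
        symbol = lookup_cs.get(surface) or lookup_ci.get(surface.lower())
        if symbol is None:  # short synonym matched with wrong case via a ci alt
            continue
        mentions.append(
            GeneMention(symbol=symbol, surface=surface, sentence_index=sentence_index,
                        span=(m.start(), m.end()), pmid=pmid)
        )
    return mentions


@lru_cache(maxsize=16)
def _word_matcher(items: tuple[tuple[str, str], ...]):
    pattern = _boundary_pattern([w for w, _ in items], [])
    return pattern, dict(items)


def tag_interaction_words(
    sentence: str | Sentence,
    lexicon: dict[str, str],
    *,
    sentence_index: int = 0,
) -> list[WordMention]:
    """Tag interaction-word mentions (case-insensitive, token-boundary)."""
    if isinstance(sentence, Sentence):
        sentence_index = sentence.index
        sentence = sentence.text
    if not lexicon:
        return []
    pattern, polarity = _word_matcher(tuple(sorted(lexicon.items())))
    return [
        WordMention(word=m.group(0).lower(), surface=m.group(0), sentence_index=sentence_index,
                    span=(m.start(), m.end()), polarity=polarity[m.group(0).lower()])
        for m in pattern.finditer(sentence)
    ]


def classify_sentence(
    gene_mentions: Sequence[GeneMention],
    word_mentions: Sequence[WordMention],
) -> list[Biointeraction]:
    """Classify all ordered gene pairs of one sentence into types 1-3.

    For each ordered pair (A before B, distinct symbols):

    * type 1 if an interaction word lies strictly between them (the word
      nearest to A wins when several do);
    * else type 2 if the sentence has an interaction word elsewhere (the
      earliest such word is attributed);
    * else type 3 (co-occurrence with no interaction word).
    """
    genes = sorted(gene_mentions, key=lambda g: g.span)
    words = sorted(word_mentions, key=lambda w: w.span)
    out = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if a.symbol == b.symbol or b.span[0] < a.span[1]:
                continue
            between = [w for w in words if w.span[0] >= a.span[1] and w.span[1] <= b.span[0]]
            if between:
                w = between[0]  # nearest to A
                out.append(Biointeraction(a.symbol, w.word, b.symbol, 1,
                                          pmid=a.pmid, sentence_index=a.sentence_index,
                                          polarity=w.polarity))
            elif words:
                outside = [w for w in words if w not in between]
                w = outside[0]
                out.append(Biointeraction(a.symbol, w.word, b.symbol, 2,
                                          pmid=a.pmid, sentence_index=a.sentence_index,
                                          polarity=w.polarity))
            else:
                out.append(Biointeraction(a.symbol, None, b.symbol, 3,
                                          pmid=a.pmid, sentence_index=a.sentence_index,
                                          polarity="unknown"))
    return out


def extract_abstract(
    abstract: AbstractRecord,
    dictionary: dict[str, list[str]],
    lexicon: dict[str, str],
    *,
    types: Iterable[int] = (1, 2, 3, 4),
) -> list[Biointeraction]:
    """Extract all biointeractions from one abstract.

    Sentence-level types 1-3 come from :func:`classify_sentence`; every
    unordered gene pair co-mentioned in the abstract but never within one
    sentence yields a type-4 interaction (alphabetical order, no word).
    Results are deduplicated per (pmid, pair, word, type).
    """
    wanted = set(types)
    interactions: list[Biointeraction] = []
    seen: set[tuple] = set()
    symbols_by_sentence: list[set[str]] = []
    for sent in segment_sentences(abstract.text):
        genes = tag_genes(sent, dictionary, pmid=abstract.pmid)
        words = tag_interaction_words(sent, lexicon)
        symbols_by_sentence.append({g.symbol for g in genes})
        for bi in classify_sentence(genes, words):
            if bi.type_code in wanted and bi.key not in seen:
                seen.add(bi.key)
                interactions.append(bi)
    if 4 in wanted:
        all_symbols = sorted(set().union(*symbols_by_sentence) if symbols_by_sentence else set())
        for i, x in enumerate(all_symbols):
            for y in all_symbols[i + 1:]:
                if any(x in s and y in s for s in symbols_by_sentence):
                    continue
                bi = Biointeraction(x, None, y, 4, pmid=abstract.pmid,
                                    sentence_index=None, polarity="unknown")
                if bi.key not in seen:
                    seen.add(bi.key)
                    interactions.append(bi)
    return interactions
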