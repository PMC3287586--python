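"""Synthetic inputs with planted ground truth.

Every stage of the pipeline is exercised against data generated here:

* abstract corpora — a "relevant" topic class and a background class drawn
  from distinct unigram tables, with interaction sentences of known type
  planted into relevant abstracts (bag-of-sentences model);
* protein universes — families derived from random ancestors by i.i.d.
  per-site substitution, one member per taxon, plus unrelated decoys;
* a mini-taxonomy — a pinned fragment of the human lineage (Eumetazoa →
  Coelomata → Chordata → Euteleostomi → Eutheria → Homo sapiens) with
  mouse, a zebrafish-like leaf and Drosophila melanogaster as outgroup.
  Coelomata is kept deliberately: the taxonomy is version-pinned data and
  the lineage binning expects it, even though current NCBI dropped it.

Everything is deterministic for a fixed seed.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import AbstractRecord
from .errors import ConfigurationError
from .orthology import ProteinRecord
from .taxonomy import TaxonomyTree

__all__ = [
    "PlantedInteraction",
    "CorpusConfig",
    "ProteomeConfig",
    "make_corpus",
    "make_proteome",
    "make_taxonomy",
    "default_gene_dictionary",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


def default_gene_dictionary() -> dict[str, list[str]]:
    """A small preimplantation-flavoured gene dictionary (symbol -> synonyms)."""
    return {
        "CDX2": ["Cdx2"],
        "NANOG": ["Nanog"],
        "POU5F1": ["Oct4", "Oct-4", "Pou5f1"],
        "SOX2": ["Sox2"],
        "TEAD4": ["Tead4"],
        "YAP1": ["Yap", "Yap1"],
        "LATS1": ["Lats", "Lats1"],
        "GATA3": ["Gata3"],
        "GATA4": ["Gata4"],
        "GATA6": ["Gata6"],
        "TCF3": ["Tcf3"],
        "ESRRB": ["Esrrb"],
        "KLF4": ["Klf4"],
        "STAT3": ["Stat3"],
        "SALL4": ["Sall4"],
        "SOX7": ["Sox7"],
        "SOX17": ["Sox17"],
        "FGF4": ["Fgf4"],
        "EOMES": ["Eomes"],
        "FOXD3": ["Foxd3"],
    }


@dataclass(frozen=True)
class PlantedInteraction:
    """One ground-truth co-mention to plant: (A, word, B, type, multiplicity)."""

    gene_a: str
    word: Optional[str]
    gene_b: str
    type_code: int
    multiplicity: int = 1


@dataclass
class CorpusConfig:
    n_relevant: int
    n_background: int
    topic_words: dict[str, float]
    background_words: dict[str, float]
    planted_interactions: list[PlantedInteraction] = field(default_factory=list)
    gene_dictionary: dict[str, list[str]] = field(default_factory=default_gene_dictionary)
    lexicon: dict[str, str] = field(default_factory=dict)
    rng_seed: int = 0
    sentences_per_abstract: tuple[int, int] = (4, 8)
    words_per_sentence: tuple[int, int] = (8, 15)

    def validate(self) -> None:
        for name, table in (("topic_words", self.topic_words),
                            ("background_words", self.background_words)):
            if not table:
                raise ConfigurationError(f"{name}: empty probability table")
            total = float(sum(table.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name}: probabilities sum to {total}, not 1")
            if any(p < 0 for p in table.values()):
                raise ConfigurationError(f"{name}: negative probability")
        if self.n_relevant < 0 or self.n_background < 0:
            raise ConfigurationError("n_relevant/n_background: must be non-negative")
        for pi in self.planted_interactions:
            if pi.type_code not in (1, 2, 3, 4):
                raise ConfigurationError(
                    f"planted_interactions: type_code {pi.type_code} not in 1-4")
            for g in (pi.gene_a, pi.gene_b):
                if g not in self.gene_dictionary:
                    raise ConfigurationError(
                        f"gene_dictionary: planted gene {g!r} missing from dictionary")
            if pi.type_code in (1, 2):
                if not pi.word:
                    raise ConfigurationError(
                        f"planted_interactions: type {pi.type_code} requires a word")
                if self.lexicon and pi.word not in self.lexicon:
                    raise ConfigurationError(
                        f"lexicon: planted word {pi.word!r} missing from lexicon")
            elif pi.word:
                raise ConfigurationError(
                    f"planted_interactions: type {pi.type_code} must have no word")
            if pi.multiplicity < 1:
                raise ConfigurationError("planted_interactions: multiplicity must be >= 1")


@dataclass
class ProteomeConfig:
    taxa: list[int]
    families: int
    family_size_range: tuple[int, int] = (2, 6)
    mutation_rate: float = 0.05
    decoy_rate: float = 0.0
    complete_genome_taxa: frozenset[int] = frozenset()
    rng_seed: int = 0
    seq_length_range: tuple[int, int] = (90, 150)

    def validate(self) -> None:
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ConfigurationError("mutation_rate: must be in [0, 0.5]")
        if not (0.0 <= self.decoy_rate < 1.0):
            raise ConfigurationError("decoy_rate: must be in [0, 1)")
        lo, hi = self.family_size_range
        if lo < 2 or hi > len(self.taxa) or lo > hi:
            raise ConfigurationError(
                f"family_size_range: {self.family_size_range} not within [2, {len(self.taxa)}]")
        if self.families < 0:
            raise ConfigurationError("families: must be non-negative")
        if not set(self.complete_genome_taxa) <= set(self.taxa):
            raise ConfigurationError("complete_genome_taxa: not a subset of taxa")


def _sample_sentence(rng: np.random.Generator, words: list[str], probs: np.ndarray,
                     n_words: int) -> str:
    chosen = rng.choice(words, size=n_words, p=probs)
    text = " ".join(chosen)
    return text[0].upper() + text[1:] + "."


def _planted_sentences(pi: PlantedInteraction) -> list[str]:
    """Render a planted interaction as sentence(s) matching its type pattern."""
    a, b, w = pi.gene_a, pi.gene_b, pi.word
    if pi.type_code == 1:
        return [f"{a} {w} {b} in the preimplantation embryo."]
    if pi.type_code == 2:
        return [f"{w[0].upper()}{w[1:]} signaling was required before {a} and {b} appeared."]
    if pi.type_code == 3:
        return [f"{a} and {b} were detected in the inner cell mass."]
    return [f"{a} was detected in the morula.",
            f"{b} was detected in the trophectoderm."]


def _self_check(text: str, pi: PlantedInteraction) -> bool:
    """Ground-truth completeness: the planted pattern is regex-recoverable."""
    a, b = re.escape(pi.gene_a), re.escape(pi.gene_b)
    if pi.type_code == 1:
        return re.search(rf"\b{a}\b [^.]*\b{re.escape(pi.word)}\b[^.]*\b{b}\b", text) is not None
    return re.search(rf"\b{a}\b", text) is not None and re.search(rf"\b{b}\b", text) is not None


def make_corpus(config: CorpusConfig):
    """Generate a corpus with planted interactions.

    Returns ``(abstracts, ground_truth, relevant_pmids)`` where
    ``ground_truth`` is a list of ``(pmid, gene_a, word, gene_b, type_code)``
    tuples and ``relevant_pmids`` the set of topic-class PMIDs.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    topic_words = sorted(config.topic_words)
    topic_p = np.array([config.topic_words[w] for w in topic_words], dtype=float)
    topic_p /= topic_p.sum()
    bg_words = sorted(config.background_words)
    bg_p = np.array([config.background_words[w] for w in bg_words], dtype=float)
    bg_p /= bg_p.sum()

    lo_s, hi_s = config.sentences_per_abstract
    lo_w, hi_w = config.words_per_sentence

    def build(pmid: str, words, probs) -> list[str]:
        n_sent = int(rng.integers(lo_s, hi_s + 1))
        return [_sample_sentence(rng, words, probs, int(rng.integers(lo_w, hi_w + 1)))
                for _ in range(n_sent)]

    relevant = {f"1{i:06d}": build(f"1{i:06d}", topic_words, topic_p)
                for i in range(1, config.n_relevant + 1)}
    background = {f"2{i:06d}": build(f"2{i:06d}", bg_words, bg_p)
                  for i in range(1, config.n_background + 1)}

    ground_truth: list[tuple[str, str, Optional[str], str, int]] = []
    rel_pmids = sorted(relevant)
    for pi in config.planted_interactions:
        if not rel_pmids:
            raise ConfigurationError("n_relevant: cannot plant interactions with no relevant abstracts")
        hosts = rng.choice(rel_pmids, size=pi.multiplicity, replace=False)
        for pmid in hosts:
            sentences = relevant[pmid]
            planted = _planted_sentences(pi)
            pos = int(rng.integers(0, len(sentences) + 1))
            relevant[pmid] = sentences[:pos] + planted + sentences[pos:]
            ground_truth.append((pmid, pi.gene_a, pi.word, pi.gene_b, pi.type_code))

    abstracts = []
    for pmid in sorted([*relevant, *background]):
        sentences = relevant.get(pmid) or background[pmid]
        abstracts.append(AbstractRecord(pmid=pmid, title=sentences[0],
                                        body=" ".join(sentences[1:])))

    by_pmid = {a.pmid: a for a in abstracts}
    for pmid, ga, w, gb, tc in ground_truth:
        pi = PlantedInteraction(ga, w, gb, tc)
        assert _self_check(by_pmid[pmid].text, pi), "planted interaction not recoverable"

    return abstracts, ground_truth, set(rel_pmids)


def _mutate(rng: np.random.Generator, sequence: np.ndarray, rate: float) -> np.ndarray:
    """i.i.d. substitution: each site replaced w.p. `rate` by a different residue."""
    seq = sequence.copy()
    hits = rng.random(len(seq)) < rate
    for i in np.nonzero(hits)[0]:
        choices = [c for c in _AA if c != seq[i]]
        seq[i] = choices[int(rng.integers(len(choices)))]
    return seq


def make_proteome(config: ProteomeConfig):
    """Generate protein records with a known family partition.

    Returns ``(records, partition)``; ``partition`` maps family id (e.g.
    ``"F001"``) to the set of member seq_ids.  Decoys (ids ``DEC...``) are
    i.i.d. random sequences outside every family.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    aa = np.array(list(_AA))
    records: list[ProteinRecord] = []
    partition: dict[str, set[str]] = {}
    lo, hi = config.family_size_range
    for f in range(1, config.families + 1):
        fam_id = f"F{f:03d}"
        size = int(rng.integers(lo, hi + 1))
        # always include the first taxon (the seed's species) for pipeline use
        others = list(rng.choice(config.taxa[1:], size=size - 1, replace=False)) \
            if size > 1 else []
        taxa = [config.taxa[0], *sorted(int(t) for t in others)]
        length = int(rng.integers(*config.seq_length_range))
        ancestor = rng.choice(aa, size=length)
        members = set()
        for taxid in taxa:
            seq = _mutate(rng, ancestor, config.mutation_rate)
            seq_id = f"{fam_id}_{taxid}"
            records.append(ProteinRecord(
                seq_id=seq_id, taxid=taxid, sequence="".join(seq),
                source_db="sp" if taxid == config.taxa[0] else ("sp" if rng.random() < 0.25 else "tr"),
                complete_genome=taxid in config.complete_genome_taxa))
            members.add(seq_id)
        partition[fam_id] = members
    n_family = len(records)
    n_decoys = int(round(config.decoy_rate / (1 - config.decoy_rate) * n_family))
    for d in range(1, n_decoys + 1):
        length = int(rng.integers(*config.seq_length_range))
        taxid = int(rng.choice(config.taxa))
        records.append(ProteinRecord(
            seq_id=f"DEC{d:03d}", taxid=taxid,
            sequence="".join(rng.choice(aa, size=length)),
            source_db="tr", complete_genome=taxid in config.complete_genome_taxa))
    return records, partition


# Pinned mini-taxonomy: (taxid, parent, rank, scientific name).
_MINI_TAXONOMY = [
    (131567, 131567, "no rank", "cellular organisms"),
    (6072, 131567, "clade", "Eumetazoa"),
    (33316, 6072, "clade", "Coelomata"),
    (7227, 33316, "species", "Drosophila melanogaster"),
    (7711, 33316, "phylum", "Chordata"),
    (117571, 7711, "clade", "Euteleostomi"),
    (7955, 117571, "species", "Danio rerio"),
    (9347, 117571, "clade", "Eutheria"),
    (10090, 9347, "species", "Mus musculus"),
    (9606, 9347, "species", "Homo sapiens"),
]


def make_taxonomy() -> TaxonomyTree:
    """The pinned human-lineage mini-taxonomy fixture.

    Root-to-tip, the human leaf's ancestor chain is: cellular organisms,
    Eumetazoa, Coelomata, Chordata, Euteleostomi, Eutheria, Homo sapiens.
    Drosophila melanogaster branches below Coelomata (outside Chordata).
    """
    nodes = {t: (p, r, n) for t, p, r, n in _MINI_TAXONOMY}
    return TaxonomyTree(nodes=nodes, root=131567)
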