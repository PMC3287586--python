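"""Extraction tests: segmentation round-trips, dictionary tagging, and the
type 1-4 classifier against a brute-force enumeration oracle."""
import random

import pytest

from litpath.corpus import AbstractRecord
from litpath.extract import (Biointeraction, classify_sentence,
                             extract_abstract, segment_sentences, tag_genes,
                             tag_interaction_words)
from litpath.synth import CorpusConfig, PlantedInteraction, make_corpus


class TestSegmentSentences:
    def test_two_plain_sentences(self):
        sents = segment_sentences("A binds B. C represses D.")
        assert len(sents) == 2
        assert sents[0].text == "A binds B."
        assert sents[1].text == "C represses D."

    def test_empty_text(self):
        assert segment_sentences("") == []

    def test_abbreviations_do_not_split(self):
        text = "Genes were assayed by Smith et al. Nothing else was found, e.g. Cdx2."
        assert len(segment_sentences(text)) == 1

    def test_reconstruction_on_random_synthetic_abstracts(self):
        topic = {"blastocyst": 0.5, "embryo": 0.5}
        cfg = CorpusConfig(n_relevant=50, n_background=50, topic_words=topic,
                           background_words={"assay": 1.0}, rng_seed=3)
        abstracts, _, _ = make_corpus(cfg)
        assert len(abstracts) == 100
        for a in abstracts:
            sents = segment_sentences(a.text)
            assert "".join(s.raw for s in sents) == a.text


class TestTagGenes:
    def test_worked_example_order(self, gene_dictionary):
        mentions = tag_genes("CDX2 downregulates NANOG", gene_dictionary)
        assert [m.symbol for m in mentions] == ["CDX2", "NANOG"]
        assert mentions[0].span == (0, 4)

    def test_no_dictionary_words(self, gene_dictionary):
        assert tag_genes("nothing to see here", gene_dictionary) == []

    def test_synonym_maps_to_canonical_symbol(self, gene_dictionary):
        mentions = tag_genes("Oct4 activates transcription", gene_dictionary)
        assert len(mentions) == 1
        assert mentions[0].symbol == "POU5F1"
        assert mentions[0].surface == "Oct4"

    def test_long_names_match_case_insensitively(self, gene_dictionary):
        assert tag_genes("nanog was expressed", gene_dictionary)[0].symbol == "NANOG"

    def test_short_symbols_match_case_sensitively(self):
        dictionary = {"LIF": [], "GSE": ["Gse"]}
        assert tag_genes("lif signaling", dictionary) == []
        assert tag_genes("LIF signaling", dictionary)[0].symbol == "LIF"
        assert tag_genes("Gse was found", dictionary)[0].symbol == "GSE"

    def test_longest_match_wins(self):
        dictionary = {"SOX1": [], "SOX17": []}
        mentions = tag_genes("SOX17 and SOX1 differ", dictionary)
        assert [m.symbol for m in mentions] == ["SOX17", "SOX1"]

    def test_token_boundaries_prevent_substring_hits(self, gene_dictionary):
        assert tag_genes("the NANOGRAM scale", gene_dictionary) == []


class TestTagInteractionWords:
    def test_known_word_with_polarity(self, lexicon):
        mentions = tag_interaction_words("X downregulates Y", lexicon)
        assert len(mentions) == 1
        assert mentions[0].word == "downregulates"
        assert mentions[0].polarity == "repression"

    def test_no_lexicon_word(self, lexicon):
        assert tag_interaction_words("X and Y cooperate", lexicon) == []

    def test_variants_match_independently(self, lexicon):
        hits = tag_interaction_words("activate, activates and activated", lexicon)
        assert [m.word for m in hits] == ["activate", "activates", "activated"]


def brute_force_classify(genes, words):
    """Independent oracle: enumerate every ordered pair of gene mentions
    and apply the stated between-word rule directly."""
    expected = []
    for a in genes:
        for b in genes:
            if a.span >= b.span or a.span[1] > b.span[0] or a.symbol == b.symbol:
                continue
            between = sorted(
                (w for w in words if a.span[1] <= w.span[0] and w.span[1] <= b.span[0]),
                key=lambda w: w.span[0])
            if between:
                expected.append((a.symbol, between[0].word, b.symbol, 1))
            elif words:
                first = min(words, key=lambda w: w.span[0])
                expected.append((a.symbol, first.word, b.symbol, 2))
            else:
                expected.append((a.symbol, None, b.symbol, 3))
    return sorted(expected)


def random_sentence(rng, gene_dictionary, lexicon):
    symbols = rng.sample(sorted(gene_dictionary), rng.randint(0, 4))
    verbs = rng.sample(sorted(lexicon), rng.randint(0, 2))
    filler = ["signal", "complex", "pattern", "stage"]
    tokens = symbols + verbs + rng.sample(filler, rng.randint(1, 3))
    rng.shuffle(tokens)
    return " ".join(tokens) + "."


class TestClassifySentence:
    def test_worked_example_is_single_type1(self, gene_dictionary, lexicon):
        sent = "CDX2 downregulates NANOG"
        out = classify_sentence(tag_genes(sent, gene_dictionary),
                                tag_interaction_words(sent, lexicon))
        assert len(out) == 1
        bi = out[0]
        assert (bi.gene_a, bi.word, bi.gene_b, bi.type_code) == \
            ("CDX2", "downregulates", "NANOG", 1)
        assert bi.polarity == "repression"

    def test_single_gene_yields_nothing(self, gene_dictionary, lexicon):
        sent = "CDX2 is downregulated"
        out = classify_sentence(tag_genes(sent, gene_dictionary),
                                tag_interaction_words(sent, lexicon))
        assert out == []

    def test_word_before_both_genes_is_type2(self, gene_dictionary, lexicon):
        sent = "Activated signaling precedes CDX2 and NANOG"
        out = classify_sentence(tag_genes(sent, gene_dictionary),
                                tag_interaction_words(sent, lexicon))
        assert [bi.type_code for bi in out] == [2]

    def test_no_word_is_type3(self, gene_dictionary, lexicon):
        sent = "CDX2 and NANOG were detected"
        out = classify_sentence(tag_genes(sent, gene_dictionary),
                                tag_interaction_words(sent, lexicon))
        assert [bi.type_code for bi in out] == [3]

    def test_nearest_word_to_first_gene_wins(self, gene_dictionary, lexicon):
        sent = "CDX2 represses and then activates NANOG"
        out = classify_sentence(tag_genes(sent, gene_dictionary),
                                tag_interaction_words(sent, lexicon))
        assert len(out) == 1
        assert out[0].word == "represses"

    def test_never_pairs_a_symbol_with_itself(self, gene_dictionary, lexicon):
        sent = "Oct4 activates POU5F1"  # same canonical symbol both sides
        out = classify_sentence(tag_genes(sent, gene_dictionary),
                                tag_interaction_words(sent, lexicon))
        assert out == []

    def test_matches_brute_force_on_random_sentences(self, gene_dictionary, lexicon):
        rng = random.Random(17)
        for _ in range(200):
            sent = random_sentence(rng, gene_dictionary, lexicon)
            genes = tag_genes(sent, gene_dictionary)
            words = tag_interaction_words(sent, lexicon)
            got = sorted((bi.gene_a, bi.word, bi.gene_b, bi.type_code)
                         for bi in classify_sentence(genes, words))
            assert got == brute_force_classify(genes, words)


class TestExtractAbstract:
    def test_single_sentence_worked_example(self, gene_dictionary, lexicon):
        abstract = AbstractRecord("42", "CDX2 downregulates NANOG", "")
        out = extract_abstract(abstract, gene_dictionary, lexicon)
        assert len(out) == 1
        assert out[0].type_code == 1
        assert out[0].pmid == "42"

    def test_cross_sentence_pair_is_type4(self, gene_dictionary, lexicon):
        abstract = AbstractRecord(
            "7", "GATA4 was detected in one lineage.",
            "SOX7 was detected in another lineage.")
        out = extract_abstract(abstract, gene_dictionary, lexicon)
        assert len(out) == 1
        bi = out[0]
        assert bi.type_code == 4
        assert (bi.gene_a, bi.gene_b) == ("GATA4", "SOX7")  # alphabetical
        assert bi.sentence_index is None and bi.word is None

    def test_type4_not_emitted_when_pair_shares_a_sentence(self, gene_dictionary, lexicon):
        abstract = AbstractRecord(
            "8", "GATA4 and SOX7 were detected.", "SOX7 was also found alone.")
        out = extract_abstract(abstract, gene_dictionary, lexicon)
        assert all(bi.type_code != 4 for bi in out)

    def test_duplicate_sentences_are_deduplicated(self, gene_dictionary, lexicon):
        abstract = AbstractRecord(
            "9", "CDX2 downregulates NANOG.", "CDX2 downregulates NANOG.")
        out = extract_abstract(abstract, gene_dictionary, lexicon)
        assert len([bi for bi in out if bi.type_code == 1]) == 1

    def test_planted_type1_recall_and_precision_are_perfect(self, gene_dictionary, lexicon):
        planted = [PlantedInteraction("CDX2", "downregulates", "NANOG", 1, 3),
                   PlantedInteraction("LATS1", "phosphorylates", "YAP1", 1, 2),
                   PlantedInteraction("TEAD4", "activates", "GATA3", 1, 2)]
        cfg = CorpusConfig(n_relevant=20, n_background=0,
                           topic_words={"blastocyst": 0.5, "embryo": 0.5},
                           background_words={"assay": 1.0},
                           planted_interactions=planted,
                           gene_dictionary=gene_dictionary,
                           lexicon=lexicon, rng_seed=5)
        abstracts, truth, _ = make_corpus(cfg)
        found = set()
        for a in abstracts:
            for bi in extract_abstract(a, gene_dictionary, lexicon, types=(1,)):
                found.add((bi.pmid, bi.gene_a, bi.word, bi.gene_b, bi.type_code))
        expected = set(truth)
        assert expected <= found, "planted type-1 recall must be 100%"
        assert found == expected, "no spurious type-1 pairs with distractors absent"

    def test_type4_sentence_index_invariant(self):
        with pytest.raises(ValueError):
            Biointeraction("A", None, "B", 4, sentence_index=2)
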