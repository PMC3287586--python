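# litpath

Literature-mined regulatory pathways with ortholog clustering and
gene-age annotation.

`litpath` is for systems biologists who want to assemble a regulatory
pathway for a process — the motivating case is mammalian preimplantation
development, where the trophectoderm / inner-cell-mass decision is wired
through Hippo signalling (Lats ⊣ Yap–Tead4), the Cdx2 switch and the
Oct4/Sox2/Nanog pluripotency triad — directly from the literature, and
then ask how old each pathway gene is. The package chains four analyses:

1. **Abstract ranking.** Given a small training set *T* of relevant
   abstracts and a background set *B*, each word *w* gets a smoothed
   log-odds document-frequency weight

   ```
   weight(w) = log[(df_T(w)+s)/(|T|+2s)] − log[(df_B(w)+s)/(|B|+2s)]
   ```

   An abstract scores the sum of its *distinct* words' weights, and an
   empirical p-value p = (1 + #{null ≥ score}) / (N_null + 1) is computed
   against word-wise resamples of the background unigram distribution.
   The working corpus is the top-N abstracts with p below threshold
   (defaults N = 1000, p < 0.01).

2. **Biointeraction extraction.** Dictionary-based gene tagging (longest
   match, token boundaries, case-sensitive for symbols ≤ 3 characters) and
   an interaction-word lexicon with polarity. A sentence containing
   *gene A … interaction word … gene B*, in that order, is a **type 1**
   biointeraction (e.g. "CDX2 downregulates NANOG"); weaker classes are
   type 2 (word present but not between), type 3 (co-sentence, no word)
   and type 4 (co-mentioned in the abstract, never in one sentence).

3. **Curation and KGML.** Declarative rules replace hand curation:
   accepted types (default {1}), polarity → KGML relation subtype
   (activation → `activation`, repression → `inhibition`,
   phosphorylates → `phosphorylation`, …), duplicate assertions merged
   with their evidence PMIDs. Pathways serialize to byte-stable KGML,
   valid against the packaged KGML v0.7.2 DTD, and round-trip losslessly.

4. **Orthology and gene age.** Each pathway gene's seed proteins expand
   into a homolog cluster by bidirectional-best-hit (BBH) closure under a
   Smith–Waterman/BLOSUM62 score floor, absorb precomputed ortholog
   groups, and are verified seed-against-recruit. The cluster's taxon set
   determines the last common ancestor (LCA): the tip-most clade on the
   root → *Homo sapiens* lineage subtending every member taxon. Genes
   whose LCA predates Euteleostomi are labelled **ancient**, the rest
   **recent**; an ortholog in *Drosophila melanogaster* is flagged. A
   histogram bins genes by origin clade.

Every input can be generated synthetically with planted ground truth
(`litpath.synth`): topic/background corpora, protein families with known
partitions, and a pinned mini-taxonomy of the human lineage (including
Coelomata, kept deliberately as version-pinned data).

## Worked example

```python
from litpath import segment_sentences, tag_genes, tag_interaction_words, classify_sentence

sent = segment_sentences("CDX2 downregulates NANOG")[0]
bi = classify_sentence(tag_genes(sent, {"CDX2": [], "NANOG": []}),
                       tag_interaction_words(sent, {"downregulates": "repression"}))[0]
print(bi.type_code, bi.gene_a, bi.word, bi.gene_b, bi.polarity)
```

prints

```
1 CDX2 downregulates NANOG repression
```

— one type-1 biointeraction: the gene–word–gene order inside a single
sentence is the evidence class strong enough to draw the directed
inhibition edge CDX2 ⊣ NANOG. The `examples/` directory holds one
narrative script per capability (ranking, extraction, KGML, clustering,
ancestry, and the end-to-end pipeline); each prints what it computes and
what the numbers mean. The full pipeline runs from one config:

```sh
litpath run --seed 1 --out out/
```

and reports, among others, `n_type1: 29`, `n_nodes: 13`, `n_edges: 17`,
`n_ancient: 9`, `n_recent: 4` under the default synthetic study
conditions — the planted demo circuit recovered as a KGML pathway whose
nodes carry ancient/recent labels and fly-ortholog markers. Two runs with
the same seed are byte-identical.

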