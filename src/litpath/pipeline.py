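"""One-config end-to-end run: synthetic corpus -> ranking -> extraction ->
curation -> KGML -> ortholog clusters -> LCA -> annotated pathway.

The default configuration is the package's study condition: a 60/240
relevant/background corpus over a shared 40-word vocabulary in which 20
topic words are enriched 5x in the relevant class; the demo regulatory
circuit planted as type-1 sentences (multiplicity 2); a proteome of one
family per pathway gene over {human, mouse, zebrafish, fly} with i.i.d.
substitution rate 0.05 and 10% decoys.  Every stage draws its seed from
the master seed, so two runs with the same config are bitwise identical.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import ancestry, fileio, orthology, pathway, ranker, synth
from .corpus import write_corpus_tsv
from .extract import extract_abstract
from .resources import default_lexicon, demo_edge_list

__all__ = ["default_config", "default_corpus_tables", "default_planted_interactions",
           "run_pipeline"]

_SUBTYPE_WORD = {"activation": "activates", "inhibition": "represses",
                 "phosphorylation": "phosphorylates"}

_TOPIC_WORDS = [
    "blastocyst", "trophectoderm", "morula", "epiblast", "endoderm",
    "pluripotency", "lineage", "implantation", "cleavage", "cavitation",
    "totipotent", "blastomere", "compaction", "differentiation", "embryo",
    "uterus", "zygote", "oocyte", "fertilization", "reprogramming",
]
_GENERIC_WORDS = [
    "protein", "analysis", "study", "cells", "expression", "levels",
    "sequence", "localization", "values", "sample", "tissue", "signal",
    "receptor", "kinase", "mutation", "assay", "culture", "growth",
    "membrane", "nucleus",
]


def default_corpus_tables(enrichment: float = 5.0):
    """Unigram tables: a shared 40-word vocabulary, 20 topic words
    enriched ``enrichment``-fold in the relevant class."""
    vocab = _TOPIC_WORDS + _GENERIC_WORDS
    background = {w: 1.0 / len(vocab) for w in vocab}
    raw = {w: (enrichment if w in _TOPIC_WORDS else 1.0) for w in vocab}
    total = sum(raw.values())
    topic = {w: v / total for w, v in raw.items()}
    return topic, background


def default_planted_interactions(multiplicity: int = 2):
    """The demo circuit rendered as plantable type-1 interactions."""
    planted = []
    for src, subtype, tgt, _ in demo_edge_list():
        if src == tgt:
            continue  # self-loops cannot satisfy the distinct-pair rule
        word = _SUBTYPE_WORD[subtype]
        planted.append(synth.PlantedInteraction(src, word, tgt, 1, multiplicity))
    return planted


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "corpus": {"n_relevant": 60, "n_background": 240, "enrichment": 5.0,
                   "multiplicity": 2},
        "ranker": {"n_train": 10, "n_top": 50, "p_threshold": 0.01,
                   "null_size": 2000, "smoothing": 1.0},
        "proteome": {"taxa": [9606, 10090, 7955, 7227],
                     "family_size_range": [2, 4], "mutation_rate": 0.05,
                     "decoy_rate": 0.1,
                     "complete_genome_taxa": [9606, 10090, 7955, 7227]},
        "ancestry": {"focal": 9606, "reference": "Euteleostomi",
                     "outgroup": 7227},
    }


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def run_pipeline(config: Optional[Mapping | str | Path] = None,
                 outdir: str | Path = "litpath_out",
                 seed: Optional[int] = None) -> dict:
    """Run the whole pipeline; returns a summary dict (also written as JSON).

    ``config`` may be a mapping or a YAML path; missing keys fall back to
    :func:`default_config`.  ``seed`` overrides the config's master seed.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8")) or {}
    cfg = _merge(default_config(), config or {})
    if seed is not None:
        cfg["seed"] = seed
    master = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # 1. corpus with planted ground truth
    topic, background_tab = default_corpus_tables(cfg["corpus"]["enrichment"])
    lexicon = default_lexicon()
    corpus_cfg = synth.CorpusConfig(
        n_relevant=cfg["corpus"]["n_relevant"],
        n_background=cfg["corpus"]["n_background"],
        topic_words=topic, background_words=background_tab,
        planted_interactions=default_planted_interactions(cfg["corpus"]["multiplicity"]),
        lexicon=lexicon, rng_seed=master,
    )
    abstracts, ground_truth, relevant_pmids = synth.make_corpus(corpus_cfg)
    write_corpus_tsv(abstracts, outdir / "corpus.tsv")
    with open(outdir / "ground_truth.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("pmid\tgene_a\tword\tgene_b\ttype\n")
        for pmid, ga, w, gb, tc in sorted(ground_truth):
            fh.write(f"{pmid}\t{ga}\t{w or ''}\t{gb}\t{tc}\n")

    # 2. rank against the background, select the working corpus
    by_pmid = {a.pmid: a for a in abstracts}
    train_pmids = sorted(relevant_pmids)[: cfg["ranker"]["n_train"]]
    train = [by_pmid[p] for p in train_pmids]
    background = [a for a in abstracts if a.pmid not in relevant_pmids]
    table = ranker.fit_weights(train, background, cfg["ranker"]["smoothing"])
    selected = ranker.rank_and_select(
        abstracts, table, background,
        n_top=cfg["ranker"]["n_top"], p_threshold=cfg["ranker"]["p_threshold"],
        null_size=cfg["ranker"]["null_size"], rng_seed=master + 1,
        exclude_pmids=train_pmids)
    fileio.write_ranked_tsv(selected, outdir / "ranked.tsv")

    # 3. extract biointeractions from the working corpus
    dictionary = corpus_cfg.gene_dictionary
    interactions = []
    for r in selected:
        interactions.extend(extract_abstract(by_pmid[r.pmid], dictionary, lexicon))
    fileio.write_interactions_tsv(interactions, outdir / "interactions.tsv")

    # 4. curate (type 1 only) and serialize KGML
    graph = pathway.curate(interactions, pathway.CurationRules())
    kgml = pathway.write_kgml(graph, title="synthetic preimplantation demo")
    (outdir / "pathway.kgml").write_bytes(kgml)

    # 5. proteome + per-gene ortholog clusters
    genes = sorted(graph.nodes)
    prot_cfg_raw = cfg["proteome"]
    prot_cfg = synth.ProteomeConfig(
        taxa=list(prot_cfg_raw["taxa"]), families=len(genes),
        family_size_range=tuple(prot_cfg_raw["family_size_range"]),
        mutation_rate=prot_cfg_raw["mutation_rate"],
        decoy_rate=prot_cfg_raw["decoy_rate"],
        complete_genome_taxa=frozenset(prot_cfg_raw["complete_genome_taxa"]),
        rng_seed=master + 2)
    records, partition = synth.make_proteome(prot_cfg)
    fileio.write_proteome(records, outdir / "proteome.fasta", outdir / "proteome_meta.tsv")
    db = orthology.ProteinDatabase(records)
    min_score = orthology.calibrate_min_score(db, partition)

    fam_of_gene = {gene: f"F{i + 1:03d}" for i, gene in enumerate(genes)}
    seed_map = {}
    for gene, fam in fam_of_gene.items():
        seeds = [s for s in (f"{fam}_9606", f"{fam}_10090") if s in partition[fam]]
        seed_map[gene] = seeds
    fileio.write_seed_map(seed_map, outdir / "seeds.tsv")

    # KO-style groups covering every second family (partial partition)
    groups = {fam: sorted(members) for i, (fam, members) in
              enumerate(sorted(partition.items())) if i % 2 == 0}
    fileio.write_groups_tsv(groups, outdir / "groups.tsv")

    clusters_dir = outdir / "clusters"
    clusters_dir.mkdir(exist_ok=True)
    clusters = {}
    for gene in genes:
        seeds = seed_map[gene]
        members = orthology.seedlinkage_expand(seeds, db, prot_cfg.taxa, min_score)
        provenance = {m: ("seed" if m in seeds else "seedlinkage") for m in members}
        unioned = orthology.ko_union(members, groups, seeds)
        for m in unioned - members:
            provenance[m] = "ko_union"
        cluster = orthology.SeedCluster(
            gene_symbol=gene, seeds=tuple(seeds), members=frozenset(unioned),
            provenance=provenance)
        cluster = orthology.verify_cluster(cluster, db, min_score)
        clusters[gene] = cluster
        fileio.write_cluster_tsv(cluster, db, clusters_dir / f"{gene}.tsv")

    stats = orthology.cluster_stats(list(clusters.values()), db)

    # 6. LCA + ancestry annotation
    tree = synth.make_taxonomy()
    anc_cfg = cfg["ancestry"]
    cluster_taxa = {gene: {db.record(m).taxid for m in cl.members}
                    for gene, cl in clusters.items()}
    results = ancestry.assign_ages(cluster_taxa, tree, focal=anc_cfg["focal"],
                                   reference=anc_cfg["reference"],
                                   outgroup=anc_cfg["outgroup"])
    fileio.write_lca_tsv(results, outdir / "lca.tsv")
    lineage = ancestry.focal_lineage(tree, anc_cfg["focal"])
    counts = ancestry.bin_by_clade(results, lineage, tree)
    fileio.write_histogram_tsv(counts, outdir / "histogram.tsv")

    annotated = pathway.annotate_ancestry(graph, results)
    (outdir / "annotated.kgml").write_bytes(
        pathway.write_kgml(annotated, title="synthetic preimplantation demo"))

    summary = {
        "seed": master,
        "n_abstracts": len(abstracts),
        "n_selected": len(selected),
        "n_interactions": len(interactions),
        "n_type1": sum(bi.type_code == 1 for bi in interactions),
        "n_nodes": len(graph.nodes),
        "n_edges": len(graph.edges()),
        "n_clusters": len(clusters),
        "cluster_size_min": stats.size_min,
        "cluster_size_max": stats.size_max,
        "sp_fraction": round(stats.sp_fraction, 4),
        "complete_genome_fraction": round(stats.complete_genome_fraction, 4),
        "n_ancient": sum(r.age_label == "ancient" for r in results.values()),
        "n_recent": sum(r.age_label == "recent" for r in results.values()),
        "n_fly_orthologs": sum(r.fly_ortholog for r in results.values()),
        "taxonomy_checksum": tree.checksum(),
        "histogram": counts,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return summary
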