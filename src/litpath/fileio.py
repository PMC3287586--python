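"""Readers and writers for the pipeline's on-disk formats.

Proteomes travel as FASTA (wrapped at 60 columns, via Biopython) with a
sidecar TSV ``seq_id taxid source_db complete_genome``; everything else is
plain TSV with a header line.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .extract import Biointeraction
from .orthology import ProteinRecord, SeedCluster
from .ancestry import LCAResult
from .ranker import RankedAbstract

__all__ = [
    "write_proteome", "read_proteome",
    "write_interactions_tsv", "read_interactions_tsv",
    "write_ranked_tsv", "read_ranked_tsv",
    "read_groups_tsv", "write_groups_tsv",
    "write_cluster_tsv", "write_lca_tsv", "write_histogram_tsv",
    "read_seed_map", "write_seed_map",
]


def write_proteome(records: Sequence[ProteinRecord], fasta_path: str | Path,
                   meta_path: str | Path) -> None:
    seqrecords = [SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records]
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seqrecords, fh, "fasta")
    with open(meta_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("seq_id\ttaxid\tsource_db\tcomplete_genome\n")
        for r in records:
            fh.write(f"{r.seq_id}\t{r.taxid}\t{r.source_db}\t{int(r.complete_genome)}\n")


def read_proteome(fasta_path: str | Path, meta_path: str | Path) -> list[ProteinRecord]:
    meta: dict[str, tuple[int, str, bool]] = {}
    lines = Path(meta_path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{meta_path} line {lineno}: expected 4 fields")
        meta[parts[0]] = (int(parts[1]), parts[2], parts[3] == "1")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise FormatError(f"{fasta_path}: {rec.id} missing from sidecar {meta_path}")
        taxid, source_db, complete = meta[rec.id]
        records.append(ProteinRecord(seq_id=rec.id, taxid=taxid, sequence=str(rec.seq),
                                     source_db=source_db, complete_genome=complete))
    return records


_INTERACTION_HEADER = "pmid\tsentence_index\tgene_a\tword\tgene_b\ttype\tpolarity"


def write_interactions_tsv(interactions: Iterable[Biointeraction], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_INTERACTION_HEADER + "\n")
        for bi in interactions:
            si = "" if bi.sentence_index is None else str(bi.sentence_index)
            fh.write(f"{bi.pmid or ''}\t{si}\t{bi.gene_a}\t{bi.word or ''}\t"
                     f"{bi.gene_b}\t{bi.type_code}\t{bi.polarity}\n")


def read_interactions_tsv(path: str | Path) -> list[Biointeraction]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != _INTERACTION_HEADER:
        raise FormatError(f"{path}: missing interactions header")
    out = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise FormatError(f"{path} line {lineno}: expected 7 fields")
        pmid, si, ga, word, gb, tc, pol = parts
        out.append(Biointeraction(
            gene_a=ga, word=word or None, gene_b=gb, type_code=int(tc),
            pmid=pmid or None, sentence_index=int(si) if si else None, polarity=pol))
    return out


def write_ranked_tsv(ranked: Sequence[RankedAbstract], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tpmid\tscore\tp_value\n")
        for r in ranked:
            fh.write(f"{r.rank}\t{r.pmid}\t{r.score:.6f}\t{r.p_value:.6g}\n")


def read_ranked_tsv(path: str | Path) -> list[RankedAbstract]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        rank, pmid, score, p = line.split("\t")
        out.append(RankedAbstract(pmid=pmid, score=float(score), p_value=float(p),
                                  rank=int(rank)))
    return out


def read_groups_tsv(path: str | Path) -> dict[str, set[str]]:
    """Ortholog groups TSV: ``group_id<TAB>seq_id``."""
    groups: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("group_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path} line {lineno}: expected 'group_id<TAB>seq_id'")
        groups.setdefault(parts[0], set()).add(parts[1])
    return groups


def write_groups_tsv(groups: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("group_id\tseq_id\n")
        for gid in sorted(groups):
            for sid in sorted(groups[gid]):
                fh.write(f"{gid}\t{sid}\n")


def write_cluster_tsv(cluster: SeedCluster, db, path: str | Path) -> None:
    """Per-cluster members: ``seq_id taxid provenance`` (plus removed rows)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("seq_id\ttaxid\tprovenance\n")
        for sid in sorted(cluster.members):
            prov = cluster.provenance.get(sid, "seedlinkage")
            fh.write(f"{sid}\t{db.record(sid).taxid}\t{prov}\n")
        for sid in sorted(cluster.removed):
            fh.write(f"{sid}\t{db.record(sid).taxid}\tremoved\n")


def write_lca_tsv(results: Mapping[str, LCAResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tlca_taxid\tlca_name\tage_label\tfly_ortholog\tn_taxa\n")
        for gene in sorted(results):
            r = results[gene]
            fh.write(f"{gene}\t{r.lca_taxid}\t{r.lca_name}\t{r.age_label}\t"
                     f"{int(r.fly_ortholog)}\t{len(r.cluster_taxa)}\n")


def write_histogram_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("clade\tn_genes\n")
        for name, n in counts.items():
            fh.write(f"{name}\t{n}\n")


def read_seed_map(path: str | Path) -> dict[str, list[str]]:
    """Static gene-symbol -> seed seq_id mapping TSV (symbol, then seed ids)."""
    mapping: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        symbol, *seed_ids = line.split("\t")
        if not seed_ids:
            raise FormatError(f"{path} line {lineno}: symbol {symbol} has no seeds")
        mapping[symbol] = seed_ids
    return mapping


def write_seed_map(mapping: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for symbol in sorted(mapping):
            fh.write("\t".join([symbol, *mapping[symbol]]) + "\n")
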