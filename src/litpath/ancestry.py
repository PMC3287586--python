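"""Gene-age assignment: LCA on the human lineage, ancient/recent labels,
outgroup-ortholog flags, and origin-clade histograms.

Each gene's ortholog cluster yields a set of taxon IDs.  The gene's LCA is
the tip-most clade on the focal (root -> Homo sapiens) lineage that is an
ancestor-or-self of every cluster taxon.  A gene is *ancient* when its LCA
falls strictly rootward of a reference clade — Euteleostomi, the
bony-vertebrate clade, by default — and *recent* when the LCA is
Euteleostomi itself or tipward of it.  An ortholog in the outgroup
(Drosophila melanogaster, taxid 7227, by default) is flagged separately.

The taxonomy is version-pinned data: LCA result sets carry the tree's
checksum, because clade bins such as Coelomata exist only in particular
taxonomy versions.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigurationError, InputError
from .taxonomy import TaxonomyTree, load_taxonomy, write_taxdump, write_taxonomy_json

__all__ = ["TaxonomyTree", "LCAResult", "load_taxonomy", "write_taxdump",
           "write_taxonomy_json", "focal_lineage", "lca_on_lineage",
           "classify_age", "flag_outgroup_ortholog", "bin_by_clade",
           "assign_ages", "DEFAULT_REFERENCE_CLADE", "DEFAULT_OUTGROUP"]

DEFAULT_REFERENCE_CLADE = "Euteleostomi"
DEFAULT_OUTGROUP = 7227  # Drosophila melanogaster


@dataclass(frozen=True)
class LCAResult:
    gene_symbol: str
    lca_taxid: int
    lca_name: str
    age_label: str  # ancient | recent
    fly_ortholog: bool
    cluster_taxa: frozenset[int]
    taxonomy_checksum: Optional[str] = None


def focal_lineage(tree: TaxonomyTree, focal: int) -> list[int]:
    """Parent chain from the root to the focal taxon, inclusive, root first."""
    if focal not in tree.nodes:
        raise InputError(f"focal taxid {focal} not in taxonomy")
    return tree.ancestors(focal)


def lca_on_lineage(cluster_taxa: Iterable[int], tree: TaxonomyTree,
                   lineage: Sequence[int]) -> int:
    """Tip-most lineage clade subtending every cluster taxon.

    Equals the deepest element of the intersection of all members'
    ancestor chains restricted to the lineage.  A cluster taxid that *is*
    a lineage node counts as subtended by itself.
    """
    taxa = set(cluster_taxa)
    if not taxa:
        raise InputError("lca_on_lineage: empty cluster taxon set")
    for taxid in taxa:
        if taxid not in tree.nodes:
            raise InputError(f"cluster taxid {taxid} not in taxonomy")
    lca = lineage[0]
    for clade in lineage:  # root -> tip
        if all(tree.is_ancestor(clade, t) for t in taxa):
            lca = clade
        else:
            break
    return lca


def classify_age(lca_taxid: int, lineage: Sequence[int], tree: TaxonomyTree,
                 reference: str = DEFAULT_REFERENCE_CLADE) -> str:
    """Ancient iff the LCA lies strictly rootward of the reference clade."""
    names = [tree.name(t) for t in lineage]
    if reference not in names:
        raise ConfigurationError(f"reference clade {reference!r} not on the focal lineage")
    if lca_taxid not in lineage:
        raise InputError(f"LCA taxid {lca_taxid} is not on the focal lineage")
    return "ancient" if lineage.index(lca_taxid) < names.index(reference) else "recent"


def flag_outgroup_ortholog(cluster_taxa: Iterable[int],
                           outgroup: int = DEFAULT_OUTGROUP) -> bool:
    """True iff the outgroup taxon contributed a cluster member."""
    return outgroup in set(cluster_taxa)


def assign_ages(
    cluster_taxa_by_gene: Mapping[str, Iterable[int]],
    tree: TaxonomyTree,
    focal: int = 9606,
    reference: str = DEFAULT_REFERENCE_CLADE,
    outgroup: int = DEFAULT_OUTGROUP,
) -> dict[str, LCAResult]:
    """Full per-gene age assignment over a set of clusters.

    Genes with an empty taxon set produce no result (they propagate as
    ``unassigned`` in pathway annotation).
    """
    lineage = focal_lineage(tree, focal)
    checksum = tree.checksum()
    results: dict[str, LCAResult] = {}
    for gene in sorted(cluster_taxa_by_gene):
        taxa = frozenset(cluster_taxa_by_gene[gene])
        if not taxa:
            continue
        lca = lca_on_lineage(taxa, tree, lineage)
        results[gene] = LCAResult(
            gene_symbol=gene,
            lca_taxid=lca,
            lca_name=tree.name(lca),
            age_label=classify_age(lca, lineage, tree, reference),
            fly_ortholog=flag_outgroup_ortholog(taxa, outgroup),
            cluster_taxa=taxa,
            taxonomy_checksum=checksum,
        )
    return results


def bin_by_clade(results: Mapping[str, LCAResult] | Sequence[LCAResult],
                 lineage: Sequence[int], tree: TaxonomyTree,
                 clade_whitelist: Optional[Sequence[str]] = None) -> dict[str, int]:
    """Histogram of gene origins over the lineage clades, root first.

    Clades with zero genes are retained; totals equal the number of genes
    with clusters.  ``clade_whitelist`` restricts the bins (for figure-style
    summaries); genes whose LCA falls outside the whitelist are counted in
    the nearest rootward whitelisted clade.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    names = [tree.name(t) for t in lineage]
    if clade_whitelist:
        keep = [n for n in names if n in clade_whitelist]
    else:
        keep = names
    counts = {name: 0 for name in keep}
    for res in results:
        if res.lca_taxid not in lineage:
            raise InputError(f"{res.gene_symbol}: LCA {res.lca_taxid} not on lineage")
        name = tree.name(res.lca_taxid)
        if name not in counts:  # whitelisted binning: roll rootward
            idx = names.index(name)
            rootward = [n for n in names[:idx] if n in counts]
            if not rootward:
                raise InputError(f"{res.gene_symbol}: no whitelisted clade rootward of {name}")
            name = rootward[-1]
        counts[name] += 1
    return counts


def plot_histogram(counts: Mapping[str, int], path: str | Path) -> Path:
    """Bar-chart export of an origin-clade histogram (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(counts)), 3.2))
    names = list(counts)
    ax.bar(range(len(names)), [counts[n] for n in names], color="#6a7fb5")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("number of genes")
    ax.set_xlabel("clade of origin (root to tip)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
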