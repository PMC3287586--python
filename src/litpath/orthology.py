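"""Seed-based homolog clustering: BBH expansion, ortholog-group union,
similarity verification.

A *seed* is a curated protein (the human and mouse products of a pathway
gene).  Clustering proceeds in three stages, mirroring the classic
seed-linkage scheme:

1. **BBH closure** — starting from the seeds, a candidate from another
   taxon joins when it is the best hit of a member and that member's taxon
   returns the favour (bidirectional best hit), iterated to a fixed point;
2. **ortholog-group union** — members of any precomputed ortholog group
   containing a seed are pulled in (one pass, after expansion);
3. **verification** — every recruited non-seed must align to at least one
   seed above a score floor; failures are moved to the ``removed`` set
   (seeds are never removed).

Similarity is a deterministic Smith-Waterman local alignment with
BLOSUM62, gap open 11 / extend 1, standing in for a BLAST-style search;
an external tabular-output command can be hooked in instead.  Score
floors are calibrated on labelled data (midpoint between within-family
and unrelated score ranges), never hard-coded.
"""
from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import InputError

__all__ = ["ProteinRecord", "SeedCluster", "ProteinDatabase", "similarity",
           "best_hit", "seedlinkage_expand", "ko_union", "verify_cluster",
           "cluster_stats", "calibrate_min_score", "ClusterStats",
           "external_similarity_hook"]

_VALID_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class ProteinRecord:
    seq_id: str
    taxid: int
    sequence: str
    source_db: str = "tr"  # sp | tr
    complete_genome: bool = False

    def __post_init__(self):
        if not self.sequence or not _VALID_AA.match(self.sequence):
            raise InputError(
                f"protein {self.seq_id}: sequence empty or outside the amino-acid alphabet")
        if self.source_db not in ("sp", "tr"):
            raise InputError(f"protein {self.seq_id}: source_db must be 'sp' or 'tr'")


@dataclass(frozen=True)
class SeedCluster:
    """A seed protein set plus recruited homologs with provenance."""

    gene_symbol: str
    seeds: tuple[str, ...]
    members: frozenset[str]
    provenance: Mapping[str, str] = field(default_factory=dict)  # seq_id -> seed|seedlinkage|ko_union
    removed: frozenset[str] = frozenset()

    def __post_init__(self):
        if not set(self.seeds) <= set(self.members):
            raise InputError(f"cluster {self.gene_symbol}: seeds must be members")
        if set(self.members) & set(self.removed):
            raise InputError(f"cluster {self.gene_symbol}: members and removed overlap")

    @property
    def removed_fraction(self) -> float:
        n_recruited = len(self.members | self.removed) - len(self.seeds)
        return len(self.removed) / n_recruited if n_recruited else 0.0


@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def similarity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Smith-Waterman local alignment score (BLOSUM62, gap 11/1).

    Symmetric and deterministic; ``similarity(a, a)`` is the self-alignment
    score (the sum of diagonal substitution values over the sequence).
    """
    return float(_aligner().score(a.sequence, b.sequence))


def external_similarity_hook(command_template: str):
    """Build a similarity function backed by an external aligner.

    ``command_template`` is formatted with ``query=``/``subject=`` FASTA
    paths and must print a single tab-separated line whose last column is
    the score (BLAST ``-outfmt 6`` convention).
    """
    import tempfile

    def sim(a: ProteinRecord, b: ProteinRecord) -> float:
        with tempfile.TemporaryDirectory() as tmp:
            qpath, spath = f"{tmp}/q.fa", f"{tmp}/s.fa"
            for path, rec in ((qpath, a), (spath, b)):
                with open(path, "w") as fh:
                    fh.write(f">{rec.seq_id}\n{rec.sequence}\n")
            out = subprocess.run(command_template.format(query=qpath, subject=spath),
                                 shell=True, capture_output=True, text=True, check=True)
            line = out.stdout.strip().splitlines()
            return float(line[0].split("\t")[-1]) if line else 0.0

    return sim


class ProteinDatabase:
    """An in-memory protein set with taxon grouping and cached similarity."""

    def __init__(self, records: Iterable[ProteinRecord], similarity_fn=similarity):
        self._records: dict[str, ProteinRecord] = {}
        self.by_taxon: dict[int, list[str]] = {}
        self._sim = similarity_fn
        self._cache: dict[tuple[str, str], float] = {}
        for rec in records:
            if rec.seq_id in self._records:
                raise InputError(f"duplicate seq_id {rec.seq_id}")
            self._records[rec.seq_id] = rec
            self.by_taxon.setdefault(rec.taxid, []).append(rec.seq_id)
        for ids in self.by_taxon.values():
            ids.sort()

    def record(self, seq_id: str) -> ProteinRecord:
        if seq_id not in self._records:
            raise InputError(f"unknown seq_id {seq_id}")
        return self._records[seq_id]

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def score(self, id_a: str, id_b: str) -> float:
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        if key not in self._cache:
            self._cache[key] = self._sim(self.record(key[0]), self.record(key[1]))
        return self._cache[key]


def best_hit(query: str | ProteinRecord, db: ProteinDatabase, taxid: int,
             min_score: float = 0.0) -> Optional[str]:
    """Highest-scoring record of one taxon, or None below the floor.

    Ties break by ascending seq_id.
    """
    query_id = query.seq_id if isinstance(query, ProteinRecord) else query
    best_id, best_score = None, None
    for cand in db.by_taxon.get(taxid, []):
        s = db.score(query_id, cand)
        if s < min_score:
            continue
        if best_score is None or s > best_score:
            best_id, best_score = cand, s
    return best_id


def seedlinkage_expand(seeds: Sequence[str], db: ProteinDatabase,
                       taxa: Sequence[int], min_score: float = 0.0) -> set[str]:
    """Closure of the seed set under bidirectional best hits.

    For each member and each taxon, the taxon's best hit ``h`` joins iff the
    best hit of ``h`` back into the member's taxon is already a member.
    Iterates to a fixed point; deterministic under the tie rules.
    """
    members = set(seeds)
    for s in seeds:
        db.record(s)  # validate presence
    changed = True
    while changed:
        changed = False
        for m in sorted(members):
            m_tax = db.record(m).taxid
            for t in taxa:
                h = best_hit(m, db, t, min_score)
                if h is None or h in members:
                    continue
                back = best_hit(h, db, m_tax, min_score)
                if back in members:
                    members.add(h)
                    changed = True
    return members


def ko_union(members: set[str], ortholog_groups: Mapping[str, Iterable[str]],
             seeds: Sequence[str]) -> set[str]:
    """Union members with every ortholog group containing a seed.

    ``ortholog_groups`` must be a (possibly partial) partition; overlapping
    groups are an input error.  Idempotent.
    """
    assigned: dict[str, str] = {}
    for gid, ids in ortholog_groups.items():
        for sid in ids:
            if sid in assigned and assigned[sid] != gid:
                raise InputError(
                    f"ortholog groups are not a partition: {sid} in {assigned[sid]} and {gid}")
            assigned[sid] = gid
    out = set(members)
    seed_set = set(seeds)
    for gid, ids in ortholog_groups.items():
        ids = set(ids)
        if ids & seed_set:
            out |= ids
    return out


def verify_cluster(cluster: SeedCluster, db: ProteinDatabase,
                   min_verify_score: float) -> SeedCluster:
    """Discard recruited members that no seed supports.

    Every non-seed member must reach ``min_verify_score`` against at least
    one seed; failures move to ``removed``.  Seeds are never removed.
    """
    removed = set(cluster.removed)
    kept = set()
    for member in cluster.members:
        if member in cluster.seeds:
            kept.add(member)
            continue
        if any(db.score(member, s) >= min_verify_score for s in cluster.seeds):
            kept.add(member)
        else:
            removed.add(member)
    return replace(cluster, members=frozenset(kept), removed=frozenset(removed))


@dataclass(frozen=True)
class ClusterStats:
    table: pd.DataFrame  # per-cluster: gene, size, sp_fraction, complete_fraction
    sp_fraction: float  # pooled over all member sequences
    complete_genome_fraction: float
    size_min: int
    size_max: int


def cluster_stats(clusters: Sequence[SeedCluster], db: ProteinDatabase) -> ClusterStats:
    """Per-cluster sizes plus pooled Swiss-Prot / complete-genome fractions."""
    rows = []
    n_total = n_sp = n_complete = 0
    for cluster in clusters:
        recs = [db.record(m) for m in sorted(cluster.members)]
        size = len(recs)
        sp = sum(r.source_db == "sp" for r in recs)
        complete = sum(r.complete_genome for r in recs)
        rows.append({"gene": cluster.gene_symbol, "size": size,
                     "sp_fraction": sp / size if size else 0.0,
                     "complete_fraction": complete / size if size else 0.0})
        n_total += size
        n_sp += sp
        n_complete += complete
    table = pd.DataFrame(rows, columns=["gene", "size", "sp_fraction", "complete_fraction"])
    return ClusterStats(
        table=table,
        sp_fraction=n_sp / n_total if n_total else 0.0,
        complete_genome_fraction=n_complete / n_total if n_total else 0.0,
        size_min=int(table["size"].min()) if len(table) else 0,
        size_max=int(table["size"].max()) if len(table) else 0,
    )


def calibrate_min_score(db: ProteinDatabase,
                        partition: Mapping[str, Iterable[str]]) -> float:
    """Score floor from a labelled sample: the margin midpoint.

    Computes all within-family and cross/decoy pair scores and returns the
    midpoint between the lowest within-family score and the highest
    unrelated score (falling back to the midpoint of the means if the two
    ranges overlap).
    """
    family_of: dict[str, str] = {}
    for fam, ids in partition.items():
        for sid in ids:
            family_of[sid] = fam
    ids = sorted(r.seq_id for r in db)
    within, between = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = db.score(a, b)
            if family_of.get(a) is not None and family_of.get(a) == family_of.get(b):
                within.append(s)
            else:
                between.append(s)
    if not within or not between:
        raise InputError("calibration needs both within-family and unrelated pairs")
    lo, hi = min(within), max(between)
    if lo > hi:
        return (lo + hi) / 2
    return (sum(within) / len(within) + sum(between) / len(between)) / 2
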