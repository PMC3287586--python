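"""Orthology tests: alignment scoring, BBH closure, KO union, verification."""
import random

import pytest

from litpath.errors import InputError
from litpath.orthology import (ProteinDatabase, ProteinRecord, SeedCluster,
                               best_hit, calibrate_min_score, cluster_stats,
                               ko_union, seedlinkage_expand, similarity,
                               verify_cluster)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rec(seq_id, sequence, taxid=9606, **kw):
    return ProteinRecord(seq_id=seq_id, taxid=taxid, sequence=sequence, **kw)


def random_seq(rng, n=60):
    return "".join(rng.choice(AA) for _ in range(n))


class TestSimilarity:
    def test_self_score_is_sum_of_diagonal_substitution_values(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        expected = sum(blosum[c, c] for c in seq)
        assert similarity(rec("a", seq), rec("b", seq)) == pytest.approx(expected)

    def test_symmetry_on_random_pairs(self):
        rng = random.Random(1)
        for _ in range(100):
            a = rec("a", random_seq(rng, 40))
            b = rec("b", random_seq(rng, 50))
            assert similarity(a, b) == similarity(b, a)

    def test_invalid_alphabet_is_an_input_error(self):
        with pytest.raises(InputError):
            rec("bad", "MKTA*JU")

    def test_family_pairs_outscore_decoy_pairs(self, protein_db, proteome_fixture):
        _, _, partition = proteome_fixture
        family_of = {sid: fam for fam, ids in partition.items() for sid in ids}
        ids = sorted(r.seq_id for r in protein_db)
        within, across = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                s = protein_db.score(a, b)
                same = family_of.get(a) is not None and family_of.get(a) == family_of.get(b)
                (within if same else across).append(s)
        assert min(within) > max(across)


class TestBestHit:
    def test_exact_copy_is_its_own_best_hit(self):
        db = ProteinDatabase([rec("q", "MKTAYIAKQRQISFVK", 9606),
                              rec("c", "MKTAYIAKQRQISFVK", 10090)])
        assert best_hit("q", db, 10090) == "c"

    def test_below_floor_returns_none(self):
        rng = random.Random(2)
        db = ProteinDatabase([rec("q", random_seq(rng), 9606),
                              rec("x", random_seq(rng), 10090)])
        assert best_hit("q", db, 10090, min_score=1e6) is None

    def test_empty_taxon_returns_none(self):
        db = ProteinDatabase([rec("q", "MKTAYIAK", 9606)])
        assert best_hit("q", db, 10090) is None

    def test_agrees_with_exhaustive_scan(self, protein_db, calibrated_floor):
        for query in sorted(r.seq_id for r in protein_db):
            for taxid in sorted(protein_db.by_taxon):
                got = best_hit(query, protein_db, taxid, calibrated_floor)
                candidates = [(protein_db.score(query, c), c)
                              for c in protein_db.by_taxon[taxid]]
                eligible = [(s, c) for s, c in candidates if s >= calibrated_floor]
                # tie-break: highest score, then ascending seq_id
                expected = None
                if eligible:
                    top = max(s for s, _ in eligible)
                    expected = min(c for s, c in eligible if s == top)
                assert got == expected


class TestSeedlinkageExpand:
    def test_seeds_only_database_is_a_fixed_point(self):
        db = ProteinDatabase([rec("s1", "MKTAYIAK", 9606)])
        assert seedlinkage_expand(["s1"], db, [9606]) == {"s1"}

    def test_identical_family_across_taxa_is_fully_recovered(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        taxa = [9606, 10090, 7955, 7227, 8364]
        db = ProteinDatabase([rec(f"m{t}", seq, t) for t in taxa])
        members = seedlinkage_expand(["m9606"], db, taxa)
        assert members == {f"m{t}" for t in taxa}

    def test_planted_families_recovered_exactly(self, protein_db, proteome_fixture,
                                                calibrated_floor):
        config, _, partition = proteome_fixture
        for fam, truth in sorted(partition.items()):
            seeds = [f"{fam}_9606"]
            members = seedlinkage_expand(seeds, protein_db, config.taxa,
                                         calibrated_floor)
            assert members == truth

    def test_expansion_is_a_superset_of_seeds_and_a_fixed_point(
            self, protein_db, proteome_fixture, calibrated_floor):
        config, _, partition = proteome_fixture
        seeds = ["F001_9606", "F001_10090"]
        members = seedlinkage_expand(seeds, protein_db, config.taxa, calibrated_floor)
        assert set(seeds) <= members
        again = seedlinkage_expand(sorted(members), protein_db, config.taxa,
                                   calibrated_floor)
        assert again == members


class TestKOUnion:
    def test_groups_without_seeds_change_nothing(self):
        assert ko_union({"s", "a"}, {"g1": {"x", "y"}}, ["s"]) == {"s", "a"}

    def test_group_containing_seed_is_absorbed(self):
        assert ko_union({"s"}, {"g1": {"s", "x"}}, ["s"]) == {"s", "x"}

    def test_idempotent(self):
        rng = random.Random(3)
        ids = [f"p{i}" for i in range(30)]
        groups = {}
        pool = ids[:]
        gi = 0
        while pool:
            take = min(len(pool), rng.randint(1, 5))
            groups[f"g{gi}"] = {pool.pop() for _ in range(take)}
            gi += 1
        members = set(rng.sample(ids, 5))
        seeds = sorted(members)[:2]
        once = ko_union(members, groups, seeds)
        assert ko_union(once, groups, seeds) == once

    def test_overlapping_groups_are_an_input_error(self):
        with pytest.raises(InputError, match="partition"):
            ko_union({"s"}, {"g1": {"s", "x"}, "g2": {"x", "y"}}, ["s"])


class TestVerifyCluster:
    def test_identical_members_remove_nothing(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        db = ProteinDatabase([rec("s", seq, 9606), rec("m", seq, 10090)])
        cluster = SeedCluster("G", ("s",), frozenset({"s", "m"}))
        out = verify_cluster(cluster, db, min_verify_score=10)
        assert out.removed == frozenset()
        assert out.removed_fraction == 0.0

    def test_injected_decoy_is_removed_and_seed_never_is(
            self, protein_db, proteome_fixture, calibrated_floor):
        _, records, partition = proteome_fixture
        decoys = sorted(r.seq_id for r in records if r.seq_id.startswith("DEC"))
        assert decoys, "fixture must contain decoys"
        truth = partition["F002"]
        cluster = SeedCluster("G", ("F002_9606",),
                              frozenset(truth | {decoys[0]}))
        out = verify_cluster(cluster, protein_db, calibrated_floor)
        assert decoys[0] in out.removed
        assert "F002_9606" in out.members
        assert out.members == frozenset(truth)

    def test_removed_fraction_arithmetic(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        rng = random.Random(4)
        db = ProteinDatabase([rec("s", seq, 9606), rec("m", seq, 10090),
                              rec("junk", random_seq(rng), 7227)])
        cluster = SeedCluster("G", ("s",), frozenset({"s", "m", "junk"}))
        out = verify_cluster(cluster, db, min_verify_score=50)
        assert out.removed == frozenset({"junk"})
        assert out.removed_fraction == pytest.approx(1 / 2)

    def test_members_plus_removed_conserved(self, protein_db, proteome_fixture,
                                            calibrated_floor):
        _, records, partition = proteome_fixture
        decoys = sorted(r.seq_id for r in records if r.seq_id.startswith("DEC"))
        before = frozenset(partition["F003"] | set(decoys[:2]))
        cluster = SeedCluster("G", ("F003_9606",), before)
        out = verify_cluster(cluster, protein_db, calibrated_floor)
        assert out.members | out.removed == before
        assert not (out.members & out.removed)


class TestClusterStats:
    def test_single_all_sp_complete_cluster(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        db = ProteinDatabase([
            rec("a", seq, 9606, source_db="sp", complete_genome=True),
            rec("b", seq, 10090, source_db="sp", complete_genome=True)])
        stats = cluster_stats([SeedCluster("G", ("a",), frozenset({"a", "b"}))], db)
        assert stats.sp_fraction == 1.0
        assert stats.complete_genome_fraction == 1.0
        assert (stats.size_min, stats.size_max) == (2, 2)

    def test_empty_cluster_list(self):
        db = ProteinDatabase([])
        stats = cluster_stats([], db)
        assert len(stats.table) == 0 and stats.sp_fraction == 0.0

    def test_pooled_fraction_is_weighted_mean_of_per_cluster(self, protein_db,
                                                             proteome_fixture):
        _, _, partition = proteome_fixture
        clusters = [SeedCluster(fam, (f"{fam}_9606",), frozenset(ids))
                    for fam, ids in sorted(partition.items())]
        stats = cluster_stats(clusters, protein_db)
        sizes = stats.table["size"]
        weighted = (stats.table["sp_fraction"] * sizes).sum() / sizes.sum()
        assert stats.sp_fraction == pytest.approx(weighted)


def test_calibrated_floor_separates_the_fixture(protein_db, proteome_fixture,
                                                calibrated_floor):
    _, _, partition = proteome_fixture
    family_of = {sid: fam for fam, ids in partition.items() for sid in ids}
    ids = sorted(r.seq_id for r in protein_db)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = protein_db.score(a, b)
            same = family_of.get(a) is not None and family_of.get(a) == family_of.get(b)
            assert (s >= calibrated_floor) == same
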