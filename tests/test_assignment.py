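"""Exact-match assignment and dual-flavor counting vs brute-force oracles."""

import numpy as np
import pytest

import homeologdiv as hd
from homeologdiv.assign import brute_force_hits, partition_reads
from homeologdiv.catalogue import GeneModel, HybridCatalogue
from homeologdiv.simulate import ReadRecord


def _reads(seqs):
    return [ReadRecord(f"r{i}", s, "") for i, s in enumerate(seqs)]


class TestIndex:
    def test_single_gene_substring_hit(self):
        cat = HybridCatalogue(genes=[GeneModel("g1", "N", 8, "ACGTACGT")])
        idx = hd.index_transcripts(cat, 4)
        assert idx.query("GTAC") == {"g1"}

    def test_absent_kmer_gives_empty_set(self):
        cat = HybridCatalogue(genes=[GeneModel("g1", "N", 8, "AAAAAAAA")])
        idx = hd.index_transcripts(cat, 4)
        assert idx.query("CCCC") == frozenset()

    def test_missing_sequences_rejected(self):
        cat = HybridCatalogue(genes=[GeneModel("g1", "N", 8)])
        with pytest.raises(ValueError):
            hd.index_transcripts(cat, 4)

    def test_query_length_mismatch_rejected(self):
        cat = HybridCatalogue(genes=[GeneModel("g1", "N", 8, "ACGTACGT")])
        idx = hd.index_transcripts(cat, 4)
        with pytest.raises(ValueError):
            idx.query("ACGTA")

    def test_equals_brute_force_on_random_queries(self):
        # long reads exercise the seed-and-verify path (k caps at 31)
        cat = hd.build_catalogue(8, 2, 2, 3, 0.05, 200, seed=3)
        idx = hd.index_transcripts(cat, 50)
        rng = np.random.default_rng(4)
        gmap = cat.gene_map
        ids = cat.gene_ids
        for _ in range(1000):
            seq = gmap[ids[rng.integers(len(ids))]].sequence
            st = rng.integers(0, len(seq) - 50 + 1)
            q = seq[st:st + 50]
            assert idx.query(q) == brute_force_hits(q, cat)


class TestAssign:
    def test_singleton_read_maps_uniquely(self, small_catalogue):
        gid = [g.gene_id for g in small_catalogue.genes
               if g.gene_id.startswith("S")][0]
        reads = hd.simulate_reads(small_catalogue, {gid: 5}, 100, 0.0, seed=1)
        idx = hd.index_transcripts(small_catalogue, 100)
        for h in hd.assign_reads(reads, idx):
            assert h.hits == {gid} and not h.multimapped and h.chosen == gid

    def test_identity_group_read_multimaps(self, small_catalogue):
        grp = small_catalogue.identity_groups[0]
        reads = hd.simulate_reads(small_catalogue, {grp[0]: 5}, 100, 0.0, seed=2)
        idx = hd.index_transcripts(small_catalogue, 100)
        for h in hd.assign_reads(reads, idx):
            assert set(grp) <= h.hits and h.multimapped and h.chosen in h.hits

    def test_error_free_hits_contain_true_origin(self):
        cat = hd.build_catalogue(50, 0, 2, 0, 0.07, 500, seed=5)
        expr = {g: 100 for g in cat.gene_ids}
        reads = hd.simulate_reads(cat, expr, 100, 0.0, seed=6)
        idx = hd.index_transcripts(cat, 100)
        hitsets = hd.assign_reads(reads, idx)
        assert len(hitsets) == 10_000
        for r, h in zip(reads, hitsets):
            assert r.origin_gene in h.hits

    def test_chosen_deterministic_under_seed(self, small_catalogue):
        grp = small_catalogue.identity_groups[0]
        reads = hd.simulate_reads(small_catalogue, {grp[0]: 50}, 100, 0.0, seed=3)
        idx = hd.index_transcripts(small_catalogue, 100)
        c1 = [h.chosen for h in hd.assign_reads(reads, idx, seed=9)]
        c2 = [h.chosen for h in hd.assign_reads(reads, idx, seed=9)]
        assert c1 == c2


class TestCounting:
    def test_full_counts_unique_reads_only(self):
        genes = [GeneModel("x", "N", 10, "AAAACCCCCC"),
                 GeneModel("y", "N", 10, "CCCCCCGGGG")]
        cat = HybridCatalogue(genes=genes)
        idx = hd.index_transcripts(cat, 6)
        # 3 unique to x, 2 multimapped (CCCCCC occurs in both genes)
        reads = _reads(["AAAACC", "AAACCC", "AACCCC"] + ["CCCCCC"] * 2)
        hitsets = hd.assign_reads(reads, idx)
        counts = hd.count_full(hitsets, cat)
        assert counts["x"] == 3 and counts["y"] == 0

    def test_all_multimapped_gives_zero_full_counts(self, small_catalogue):
        grp = small_catalogue.identity_groups[1]
        reads = hd.simulate_reads(small_catalogue, {grp[0]: 7}, 100, 0.0, seed=4)
        idx = hd.index_transcripts(small_catalogue, 100)
        hitsets = hd.assign_reads(reads, idx)
        assert hd.count_full(hitsets, small_catalogue).sum() == 0
        dup = hd.count_duplicated(hitsets, small_catalogue.identity_groups)
        assert dup.sum() == 7

    def test_cross_boundary_multimapper_discarded(self):
        # shared 6-mer between a group member and an unrelated gene
        shared = "ACGTAC"
        genes = [GeneModel("g1", "A", 12, "TTTT" + shared + "GG"),
                 GeneModel("g2", "A", 12, "TTTT" + shared + "GG"),
                 GeneModel("out", "N", 10, "CC" + shared + "CC")]
        cat = HybridCatalogue(genes=genes, identity_groups=[["g1", "g2"]])
        idx = hd.index_transcripts(cat, 6)
        hitsets = hd.assign_reads(_reads([shared]), idx)
        assert hitsets[0].hits == {"g1", "g2", "out"}
        dup = hd.count_duplicated(hitsets, cat.identity_groups)
        assert dup.sum() == 0
        part = partition_reads(hitsets, cat.identity_groups)
        assert part["discarded"] == 1

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            hd.count_duplicated([], [["a", "b"], ["b", "c"]])

    def test_counts_seed_independent(self, small_catalogue):
        expr = {g: 20 for g in small_catalogue.gene_ids}
        reads = hd.simulate_reads(small_catalogue, expr, 100, 0.005, seed=5)
        idx = hd.index_transcripts(small_catalogue, 100)
        h1 = hd.assign_reads(reads, idx, seed=1)
        h2 = hd.assign_reads(reads, idx, seed=2)
        assert hd.count_full(h1, small_catalogue).equals(
            hd.count_full(h2, small_catalogue))
        assert hd.count_duplicated(h1, small_catalogue.identity_groups).equals(
            hd.count_duplicated(h2, small_catalogue.identity_groups))


class TestPartitionAndPooling:
    def test_partition_sums_to_read_total(self, small_catalogue):
        expr = {g: 30 for g in small_catalogue.gene_ids}
        reads = hd.simulate_reads(small_catalogue, expr, 100, 0.01, seed=6)
        idx = hd.index_transcripts(small_catalogue, 100)
        hitsets = hd.assign_reads(reads, idx)
        part = partition_reads(hitsets, small_catalogue.identity_groups)
        assert part.sum() == len(reads)
        # partition classes tally with the two count flavors
        assert part["unique"] == hd.count_full(hitsets, small_catalogue).sum()
        assert part["within_group"] == hd.count_duplicated(
            hitsets, small_catalogue.identity_groups).sum()

    def test_zero_divergence_pair_pools_exactly(self):
        # identical homeologs: no unique reads; pooling the pair as an
        # identity group recovers the true fragment total exactly
        cat = hd.build_catalogue(3, 0, 2, 0, divergence=0.0,
                                 length_sampler=300, seed=7)
        a, b = cat.pairs[0]
        reads = hd.simulate_reads(cat, {a: 40, b: 25}, 100, 0.0, seed=8)
        idx = hd.index_transcripts(cat, 100)
        hitsets = hd.assign_reads(reads, idx)
        full = hd.count_full(hitsets, cat)
        assert full[a] == 0 and full[b] == 0
        dup = hd.count_duplicated(hitsets, [[a, b]], ["pool"])
        assert dup["pool"] == 65

    def test_brute_force_equivalence_over_seeds(self):
        # exhaustive-scan recount oracle on small random instances
        for seed in range(25):
            rng = np.random.default_rng(seed)
            cat = hd.build_catalogue(
                n_pairs=int(rng.integers(2, 6)),
                n_identity_groups=int(rng.integers(0, 3)),
                group_size=2,
                n_singletons=int(rng.integers(0, 4)),
                divergence=float(rng.uniform(0, 0.15)),
                length_sampler=120, seed=seed + 1000)
            expr = {g: int(rng.integers(0, 15)) for g in cat.gene_ids}
            reads = hd.simulate_reads(cat, expr, 60, 0.02, seed=seed + 2000)
            idx = hd.index_transcripts(cat, 60)
            hitsets = hd.assign_reads(reads, idx)
            full = hd.count_full(hitsets, cat)
            dup = hd.count_duplicated(hitsets, cat.identity_groups)

            # oracle: brute-force substring scan, then re-derive both flavors
            bf_full = dict.fromkeys(cat.gene_ids, 0)
            bf_dup = {f"IDG{i + 1:04d}": 0
                      for i in range(len(cat.identity_groups))}
            members = [set(g) for g in cat.identity_groups]
            for r in reads:
                hits = brute_force_hits(r.sequence, cat)
                if len(hits) == 1:
                    (g,) = hits
                    bf_full[g] += 1
                elif len(hits) > 1:
                    for i, m in enumerate(members):
                        if hits <= m:
                            bf_dup[f"IDG{i + 1:04d}"] += 1
                            break
            assert full.to_dict() == bf_full
            assert dup.to_dict() == bf_dup
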