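import numpy as np
import pytest

from condfdr.clump import (
    Locus,
    OverlapReport,
    assign_blocks,
    build_adjacency,
    greedy_lead_selection,
    novelty_filter,
    overlap_loci,
    read_ld,
)


ABC = {"A": 1e-4, "B": 1e-3, "C": 5e-3}
ABC_ADJ = build_adjacency([("A", "B", 0.5), ("B", "C", 0.1)])


class TestGreedyLeadSelection:
    def test_hand_simulated_greedy_pass(self):
        leads = greedy_lead_selection(ABC, ABC_ADJ)
        assert leads == ["A", "C"]  # B pruned by A (r2 = 0.5 > 0.2)

    def test_no_edges_every_snp_leads(self):
        leads = greedy_lead_selection(ABC, build_adjacency([]))
        assert set(leads) == set(ABC)

    def test_boundary_r2_not_pruned(self):
        adj = build_adjacency([("A", "B", 0.2)])
        leads = greedy_lead_selection({"A": 1e-4, "B": 1e-3}, adj)
        assert leads == ["A", "B"]  # the rule is strictly > 0.2

    def test_first_lead_is_global_minimum(self):
        rng = np.random.default_rng(0)
        snps = {f"rs{i}": float(rng.uniform(1e-5, 1e-2)) for i in range(50)}
        edges = [
            (f"rs{i}", f"rs{j}", float(rng.uniform()))
            for i in range(50)
            for j in range(i + 1, 50)
            if rng.random() < 0.1
        ]
        leads = greedy_lead_selection(snps, build_adjacency(edges))
        assert leads[0] == min(snps, key=lambda s: (snps[s], s))

    def test_leads_pairwise_unlinked_on_random_graphs(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            snps = {f"rs{i}": float(rng.uniform(1e-5, 1e-2)) for i in range(60)}
            edges = [
                (f"rs{i}", f"rs{j}", float(rng.uniform()))
                for i in range(60)
                for j in range(i + 1, 60)
                if rng.random() < 0.15
            ]
            adj = build_adjacency(edges)
            leads = greedy_lead_selection(snps, adj)
            for a in leads:
                for b in leads:
                    if a != b:
                        assert adj.get(a, {}).get(b, 0.0) <= 0.2

    def test_cfdr_tie_broken_by_nominal_p_then_rsid(self):
        snps = {"rsB": 1e-3, "rsA": 1e-3}
        leads = greedy_lead_selection(
            snps, build_adjacency([]), p_nominal={"rsB": 1e-6, "rsA": 1e-5}
        )
        assert leads == ["rsB", "rsA"]
        leads = greedy_lead_selection(snps, build_adjacency([]))
        assert leads == ["rsA", "rsB"]


class TestAssignBlocks:
    def test_hand_assignment_continuation(self):
        leads = greedy_lead_selection(ABC, ABC_ADJ)
        loci = assign_blocks(leads, ABC, ABC_ADJ)
        by_lead = {l.lead: l.members for l in loci}
        assert by_lead == {"A": {"A", "B"}, "C": {"C"}}

    def test_singleton_locus(self):
        loci = assign_blocks(["A"], {"A": 1e-4}, build_adjacency([]))
        assert len(loci) == 1 and loci[0].members == {"A"}

    def test_multi_lead_snp_joins_max_r2_lead(self):
        adj = build_adjacency([("X", "L1", 0.3), ("X", "L2", 0.6), ("L1", "L2", 0.1)])
        loci = assign_blocks(
            ["L1", "L2"], {"L1": 1e-5, "L2": 1e-4, "X": 1e-3}, adj
        )
        by_lead = {l.lead: l.members for l in loci}
        assert "X" in by_lead["L2"]

    def test_partition_of_significant_snps(self):
        rng = np.random.default_rng(3)
        snps = {f"rs{i}": float(rng.uniform(1e-5, 1e-2)) for i in range(40)}
        edges = [
            (f"rs{i}", f"rs{j}", float(rng.uniform(0.25, 1.0)))
            for i in range(40)
            for j in range(i + 1, 40)
            if rng.random() < 0.2
        ]
        adj = build_adjacency(edges)
        leads = greedy_lead_selection(snps, adj)
        loci = assign_blocks(leads, snps, adj)
        all_members = [m for l in loci for m in l.members]
        assert sorted(all_members) == sorted(snps)  # each SNP exactly once

    def test_genomic_numbering(self):
        info = {"A": ("2", 500), "C": ("1", 100)}
        loci = assign_blocks(
            ["A", "C"], {"A": 1e-5, "C": 1e-3}, build_adjacency([]), snp_info=info
        )
        assert [(l.locus_id, l.lead) for l in loci] == [(1, "C"), (2, "A")]

    def test_min_cfdr_over_members(self):
        leads = greedy_lead_selection(ABC, ABC_ADJ)
        loci = assign_blocks(leads, ABC, ABC_ADJ)
        locus_a = next(l for l in loci if l.lead == "A")
        assert locus_a.min_cfdr == 1e-4

    def test_determinism_identical_outputs(self):
        rng = np.random.default_rng(4)
        snps = {f"rs{i}": float(rng.uniform(1e-5, 1e-2)) for i in range(30)}
        edges = [("rs1", "rs2", 0.9), ("rs3", "rs4", 0.5)]
        adj = build_adjacency(edges)
        runs = [
            assign_blocks(greedy_lead_selection(snps, adj), snps, adj)
            for _ in range(2)
        ]
        assert [(l.lead, sorted(l.members)) for l in runs[0]] == [
            (l.lead, sorted(l.members)) for l in runs[1]
        ]


class TestOverlapAndNovelty:
    def _locus(self, i, members, genes=()):
        return Locus(
            locus_id=i, lead=sorted(members)[0], members=set(members),
            min_cfdr=1e-3, genes=set(genes),
        )

    def test_shared_rsid_overlaps(self):
        rep = overlap_loci([self._locus(1, {"rs1"})], [self._locus(1, {"rs1"})])
        assert rep.pairs == [(1, 1)]

    def test_shared_gene_overlaps(self):
        rep = overlap_loci(
            [self._locus(1, {"rs1"}, {"G1"})], [self._locus(1, {"rs2"}, {"G1"})]
        )
        assert rep.pairs == [(1, 1)]

    def test_union_count_hand_example(self):
        a = [self._locus(1, {"rs1"}, {"G1"}), self._locus(2, {"rs2"}),
             self._locus(3, {"rs3"})]
        b = [self._locus(1, {"rs9"}, {"G1"}), self._locus(2, {"rs8"})]
        rep = overlap_loci(a, b)
        assert len(rep.pairs) == 1
        assert rep.union_count == 4

    def test_empty_known_all_novel(self):
        loci = [self._locus(i, {f"rs{i}"}) for i in range(5)]
        out = novelty_filter(loci, set(), set())
        assert all(l.novelty == "novel" for l in out)

    def test_known_rsid_is_replication(self):
        (out,) = novelty_filter([self._locus(1, {"rs1", "rs2"})], {"rs2"}, set())
        assert out.novelty == "replication"

    def test_known_gene_hand_count(self):
        loci = [
            self._locus(i, {f"rs{i}"}, {f"G{i}"}) for i in range(10)
        ]
        out = novelty_filter(loci, set(), {"G0", "G1", "G2", "G3"})
        assert sum(l.novelty == "novel" for l in out) == 6


class TestLDFile:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("SNP_A\tSNP_B\tR2\nrs1\trs2\t0.5\n")
        adj = read_ld(path)
        assert adj["rs1"]["rs2"] == 0.5 and adj["rs2"]["rs1"] == 0.5

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency([("rs1", "rs2", 1.5)])

    def test_inter_chromosomal_edge_rejected(self):
        with pytest.raises(ValueError, match="intra-chromosomal"):
            build_adjacency(
                [("rs1", "rs2", 0.5)], chrom_of={"rs1": "1", "rs2": "2"}
            )
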