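"""Isoform filtering, tandem arrays, synteny chaining, copy retention."""

import collections

import numpy as np
import pytest

from panfam.duplication import (
    GeneModel,
    _chain_once,
    assign_ranks,
    attribute_duplication_origin,
    chain_collinear_blocks,
    classify_copy_retention,
    detect_tandem_arrays,
    filter_isoforms,
)
from panfam.pangene import SimilarityEdge

from oracles import greedy_blocks_oracle, longest_chain_oracle


def _gene(gid, chrom="c1", start=1, genome="GA", cds="ATG", locus=None):
    return GeneModel(gid, genome, chrom, start, start + max(len(cds), 1) - 1,
                     locus_id=locus or gid, cds=cds)


def _ranked_row(n, genome="GA", chrom="c1", prefix="g"):
    return assign_ranks([
        _gene(f"{prefix}{i}", chrom=chrom, start=1 + i * 100, genome=genome)
        for i in range(n)])


class TestFilterIsoforms:
    def test_longest_cds_retained(self):
        genes = [_gene("g1", cds="A" * 900, locus="L1"),
                 _gene("g1b", cds="A" * 600, locus="L1")]
        kept = filter_isoforms(genes)
        assert [g.gene_id for g in kept] == ["g1"]

    def test_tie_broken_by_smallest_id(self):
        genes = [_gene("g2", cds="AAA", locus="L1"),
                 _gene("g1", cds="CCC", locus="L1")]
        assert [g.gene_id for g in filter_isoforms(genes)] == ["g1"]

    def test_no_isoforms_identity(self):
        genes = [_gene("g1", start=1), _gene("g2", start=200)]
        kept = filter_isoforms(genes)
        assert {g.gene_id for g in kept} == {"g1", "g2"}

    def test_recovers_simulated_unique_loci(self, truth):
        for genome in truth.genomes[:3]:
            kept = filter_isoforms(genome.genes)
            loci = {g.locus_id for g in genome.genes}
            assert len(kept) == len(loci)
            assert all(not g.gene_id.endswith("i") for g in kept)


class TestDetectTandemArrays:
    def _edges(self, pairs):
        return [SimilarityEdge(a, b, 200, 1e-50) for a, b in pairs]

    def test_adjacent_similar_genes_form_one_array(self):
        genes = _ranked_row(13)
        edges = self._edges([("g10", "g11"), ("g11", "g12"), ("g10", "g12")])
        arrays = detect_tandem_arrays(genes, edges, max_rank_gap=1)
        assert len(arrays) == 1
        assert arrays[0].members == ["g10", "g11", "g12"]

    def test_cross_chromosome_pairs_never_cluster(self):
        genes = assign_ranks([_gene("a", chrom="c1"), _gene("b", chrom="c2")])
        arrays = detect_tandem_arrays(genes, self._edges([("a", "b")]),
                                      max_rank_gap=10)
        assert arrays == []

    def test_rank_gap_cutoff_is_sharp(self):
        """Similar genes at ranks 5 and 12: linked at cutoff 7, not at 5."""
        genes = _ranked_row(15)
        edges = self._edges([("g5", "g12")])
        assert detect_tandem_arrays(genes, edges, max_rank_gap=5) == []
        arrays = detect_tandem_arrays(genes, edges, max_rank_gap=7)
        assert [a.members for a in arrays] == [["g5", "g12"]]

    def test_single_linkage_matches_exhaustive_pairing(self):
        """Clusters equal the transitive closure of near similar pairs."""
        rng = np.random.default_rng(4)
        genes = _ranked_row(30)
        ids = [g.gene_id for g in genes]
        pair_idx = {tuple(sorted((ids[i], ids[j])))
                    for i in range(30) for j in range(30)
                    if i != j and rng.random() < 0.1}
        edges = self._edges(sorted(pair_idx))
        cutoff = 4
        arrays = detect_tandem_arrays(genes, edges, max_rank_gap=cutoff)
        # oracle: repeated merging over explicit pair list
        clusters = [{g} for g in ids]
        rank = {g.gene_id: g.rank for g in genes}
        merged = True
        while merged:
            merged = False
            for a, b in pair_idx:
                if abs(rank[a] - rank[b]) > cutoff:
                    continue
                ca = next(c for c in clusters if a in c)
                cb = next(c for c in clusters if b in c)
                if ca is not cb:
                    clusters.remove(ca)
                    clusters.remove(cb)
                    clusters.append(ca | cb)
                    merged = True
        expected = {frozenset(c) for c in clusters if len(c) > 1}
        assert {frozenset(a.members) for a in arrays} == expected

    def test_arrays_are_disjoint(self, truth):
        genes = [g for gm in truth.genomes for g in filter_isoforms(gm.genes)]
        arrays = detect_tandem_arrays(genes, truth.edges)
        seen = set()
        for a in arrays:
            assert not (set(a.members) & seen)
            seen |= set(a.members)

    def test_recovers_implanted_arrays(self, truth):
        genes = [g for gm in truth.genomes for g in filter_isoforms(gm.genes)]
        arrays = detect_tandem_arrays(genes, truth.edges, max_rank_gap=5)
        assert {frozenset(a.members) for a in arrays} == \
            {frozenset(a.members) for a in truth.tandem_truth}

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError, match="evalue_cut"):
            detect_tandem_arrays([], [], evalue_cut=0.0)


class TestChainCollinearBlocks:
    def _pair(self, n, perm_b=None, genome_b="GB"):
        ga = _ranked_row(n, genome="GA", prefix="a")
        order = perm_b if perm_b is not None else range(n)
        gb = assign_ranks([
            _gene(f"b{i}", chrom="c1", start=1 + order[i] * 100, genome=genome_b)
            for i in range(n)])
        edges = [SimilarityEdge(f"a{i}", f"b{i}", 300, 1e-80) for i in range(n)]
        return edges, ga, gb

    def test_identical_order_one_same_block(self):
        edges, ga, gb = self._pair(10)
        blocks = chain_collinear_blocks(edges, ga, gb)
        assert len(blocks) == 1
        assert blocks[0].score == 10 and blocks[0].orientation == "same"

    def test_minimum_block_size_five(self):
        edges, ga, gb = self._pair(4)
        assert chain_collinear_blocks(edges, ga, gb, min_block=5) == []

    def test_reversed_order_is_inverted(self):
        edges, ga, gb = self._pair(8, perm_b=list(range(7, -1, -1)))
        blocks = chain_collinear_blocks(edges, ga, gb)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_evalue_cutoff_applied(self):
        edges, ga, gb = self._pair(10)
        weak = [SimilarityEdge(e.gene_a, e.gene_b, 50, 1e-5) for e in edges]
        assert chain_collinear_blocks(weak, ga, gb) == []

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            chain_collinear_blocks([], [], [], max_gaps=-1)
        with pytest.raises(ValueError):
            chain_collinear_blocks([], [], [], min_block=1)

    def test_matches_exhaustive_chain_oracle_on_random_instances(self):
        """Greedy longest-first blocks equal the brute-force enumeration
        for 100 random scatters of <= 20 anchors."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 21))
            perm = list(rng.permutation(n))
            edges, ga, gb = self._pair(n, perm_b=perm)
            u, s = 1, 5
            blocks = chain_collinear_blocks(edges, ga, gb, max_gaps=u,
                                            min_block=s)
            pts = [(i, perm[i], i) for i in range(n)]
            expected = greedy_blocks_oracle(pts, u, s)
            got = [(b.orientation,
                    tuple(int(x[0][1:]) for x in b.anchors)) for b in blocks]
            assert got == expected, seed
            assert all(b.score >= s for b in blocks)

    def test_chain_dp_equals_oracle_directly(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(4, 15))
            pts = [(i, int(p), i) for i, p in enumerate(rng.permutation(n))]
            for inverted in (False, True):
                assert _chain_once(pts, 1, inverted) == \
                    longest_chain_oracle(pts, 1, inverted)


class TestCopyRetention:
    def test_counts_distinct_blocks(self, truth):
        ga = filter_isoforms(truth.genomes[0].genes)
        gb = filter_isoforms(truth.outgroup.genes)
        blocks = chain_collinear_blocks(truth.anchor_edges, ga, gb)
        retention = classify_copy_retention(blocks, gb)
        for og_gene, copies in truth.retention_truth.items():
            assert retention[og_gene] == copies

    def test_gene_without_anchor_gets_zero(self):
        gb = _ranked_row(3, genome="VVI", prefix="v")
        assert classify_copy_retention([], gb) == {"v0": 0, "v1": 0, "v2": 0}

    def test_retention_invariant_to_block_order(self, truth):
        ga = filter_isoforms(truth.genomes[0].genes)
        gb = filter_isoforms(truth.outgroup.genes)
        blocks = chain_collinear_blocks(truth.anchor_edges, ga, gb)
        assert classify_copy_retention(blocks, gb) == \
            classify_copy_retention(blocks[::-1], gb)

    def test_stochastic_fraction_recovery(self):
        """600 fully triplicated ancestors with retention probabilities
        (0.2, 0.3, 0.5): recovered class fractions within +-0.05 of truth."""
        from panfam.simulate import SimConfig, simulate_pangenome
        cfg = SimConfig(n_genomes=4, group_sizes=(1, 1, 1, 1), n_oggs=4,
                        tandem_arrays=(), n_background_genes=0,
                        wgt_fraction=1.0, n_outgroup_genes=600, seed=23)
        truth = simulate_pangenome(cfg)
        ga = filter_isoforms(truth.genomes[0].genes)
        gb = filter_isoforms(truth.outgroup.genes)
        blocks = chain_collinear_blocks(truth.anchor_edges, ga, gb)
        retention = classify_copy_retention(blocks, gb)
        n = len(truth.retention_truth)
        rec = collections.Counter(retention[g] for g in truth.retention_truth)
        tru = collections.Counter(truth.retention_truth.values())
        for c in (1, 2, 3):
            assert abs(rec[c] / n - tru[c] / n) <= 0.05


class TestOriginAttribution:
    def test_array_member_is_td(self):
        genes = _ranked_row(3)
        arrays = detect_tandem_arrays(
            genes, [SimilarityEdge("g0", "g1", 200, 1e-50)], max_rank_gap=1)
        origins = attribute_duplication_origin(genes, arrays, [], {}, set())
        assert origins["g0"] == origins["g1"] == "TD"
        assert origins["g2"] == "none"

    def test_unknown_array_member_rejected(self):
        genes = _ranked_row(2)
        from panfam.duplication import TandemArray
        arr = TandemArray("x", "GA", "c1", ["g0", "ghost"])
        with pytest.raises(ValueError, match="ghost"):
            attribute_duplication_origin(genes, [arr], [], {}, set())

    def test_simulated_origin_labels_match_truth(self, truth):
        genes = [g for gm in truth.genomes for g in filter_isoforms(gm.genes)]
        arrays = detect_tandem_arrays(genes, truth.edges)
        ga = filter_isoforms(truth.genomes[0].genes)
        gb = filter_isoforms(truth.outgroup.genes)
        blocks = chain_collinear_blocks(truth.anchor_edges, ga, gb)
        retention = classify_copy_retention(blocks, gb)
        origins = attribute_duplication_origin(
            genes, arrays, blocks, retention, {g.gene_id for g in gb})
        td_truth = {m for a in truth.tandem_truth for m in a.members}
        wgt_truth = {b for (a, b) in truth.kaks_truth
                     if truth.retention_truth[a] >= 2}
        assert {g for g, o in origins.items() if o in ("TD", "both")} == td_truth
        assert {g for g, o in origins.items() if o in ("WGT", "both")} == wgt_truth
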