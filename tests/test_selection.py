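"""NG86 Ka/Ks: oracle equivalence, worked cases, invariants, strata."""

import math
from itertools import product

import numpy as np
import pytest

from panfam.codons import SENSE_CODONS, pairwise_differences, syn_site_count
from panfam.selection import (
    CodonAlignment,
    KaKsResult,
    back_translate,
    classify_selection,
    ng86_pair,
    summarize_strata,
)

from oracles import ng86_differences_oracle, ng86_sites_oracle


def _result(ratio):
    return KaKsResult("a", "b", 1, 2, 0, 0, 0, 0, None, None, ratio)


class TestSiteAndDifferenceCounting:
    def test_site_counts_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            assert syn_site_count(codon) == pytest.approx(
                ng86_sites_oracle(codon), abs=1e-12)

    def test_differences_match_pathway_oracle_for_all_near_pairs(self):
        """Every sense-codon pair with <= 2 differences matches the
        exhaustive pathway-enumeration oracle to 1e-12."""
        for ca, cb in product(SENSE_CODONS, repeat=2):
            ndiff = sum(a != b for a, b in zip(ca, cb))
            if ndiff > 2:
                continue
            sd, nd = pairwise_differences(ca, cb)
            esd, end_ = ng86_differences_oracle(ca, cb)
            assert sd == pytest.approx(esd, abs=1e-12), (ca, cb)
            assert nd == pytest.approx(end_, abs=1e-12), (ca, cb)

    def test_triple_difference_pairs_match_oracle(self):
        rng = np.random.default_rng(0)
        codons = list(SENSE_CODONS)
        checked = 0
        while checked < 200:
            ca = codons[rng.integers(len(codons))]
            cb = codons[rng.integers(len(codons))]
            sd, nd = pairwise_differences(ca, cb)
            esd, end_ = ng86_differences_oracle(ca, cb)
            assert (sd, nd) == pytest.approx((esd, end_), abs=1e-12)
            checked += 1


class TestNg86Pair:
    def test_identical_sequences(self):
        cds = "ATGGCTAAA" * 30
        r = ng86_pair(CodonAlignment(cds, cds))
        assert r.Sd == r.Nd == 0
        assert r.Ka == 0 and r.Ks == 0
        assert r.ratio is None and r.selection_class == "undefined"

    def test_phe_leu_single_codon_worked_case(self):
        """TTT vs TTA: one nonsynonymous difference; sites averaged over
        both codons (TTT: 1/3 synonymous site; TTA: 2/3, via CTA and TTG)."""
        r = ng86_pair(CodonAlignment("TTT", "TTA"))
        assert r.S_sites == pytest.approx(0.5, abs=1e-12)
        assert r.N_sites == pytest.approx(2.5, abs=1e-12)
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        assert r.pN == pytest.approx(0.4, abs=1e-12)
        assert r.Ka == pytest.approx(-0.75 * math.log(7 / 15), abs=1e-12)
        assert r.Ks == pytest.approx(0.0, abs=1e-12)
        assert r.ratio is None  # Ks = 0 reported as undefined, not positive

    def test_matches_biopython_ng86_reference(self):
        """Cross-check dN/dS against the independent Biopython estimator.

        Restricted to codons with no stop-codon single-nt neighbours, where
        the stop-excluding site convention and Biopython's coincide.
        """
        pytest.importorskip("Bio.codonalign")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from panfam.codons import STOP_CODONS, codon_neighbors
        rng = np.random.default_rng(3)
        codons = [c for c in SENSE_CODONS
                  if not any(alt in STOP_CODONS for _, alt in codon_neighbors(c))]
        for _ in range(20):
            a = "".join(codons[i] for i in rng.integers(len(codons), size=40))
            b_codons = [a[i:i + 3] for i in range(0, len(a), 3)]
            for _ in range(4):  # a few substitutions
                k = rng.integers(len(b_codons))
                b_codons[k] = codons[rng.integers(len(codons))]
            b = "".join(b_codons)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            r = ng86_pair(CodonAlignment(a, b))
            if r.Ka is not None and dn >= 0:
                assert r.Ka == pytest.approx(dn, abs=1e-9)
            if r.Ks is not None and ds >= 0:
                assert r.Ks == pytest.approx(ds, abs=1e-9)

    def test_symmetry(self):
        a = "ATGGCTAAATTTCCCGGG"
        b = "ATGGCGAAATTACCAGGG"
        r1 = ng86_pair(CodonAlignment(a, b))
        r2 = ng86_pair(CodonAlignment(b, a))
        for f in ("S_sites", "N_sites", "Sd", "Nd", "Ka", "Ks"):
            assert getattr(r1, f) == getattr(r2, f)

    def test_sites_sum_to_three_per_codon_column(self):
        rng = np.random.default_rng(5)
        codons = list(SENSE_CODONS)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            a = "".join(codons[i] for i in rng.integers(len(codons), size=n))
            b = "".join(codons[i] for i in rng.integers(len(codons), size=n))
            r = ng86_pair(CodonAlignment(a, b))
            assert r.S_sites + r.N_sites == pytest.approx(3 * n, abs=1e-9)

    def test_concatenation_additivity(self):
        a1, b1 = "ATGGCTAAA", "ATGGCGAAG"
        a2, b2 = "TTTCCCGGG", "TTCCCAGGA"
        r1 = ng86_pair(CodonAlignment(a1, b1))
        r2 = ng86_pair(CodonAlignment(a2, b2))
        r = ng86_pair(CodonAlignment(a1 + a2, b1 + b2))
        for f in ("S_sites", "N_sites", "Sd", "Nd"):
            assert getattr(r, f) == pytest.approx(
                getattr(r1, f) + getattr(r2, f), abs=1e-12)

    def test_synonymous_only_pair_has_zero_ka(self):
        # one GCT->GCC (Ala) change among ten codons: purely synonymous
        a = "GCT" * 10
        b = "GCC" + "GCT" * 9
        r = ng86_pair(CodonAlignment(a, b))
        assert r.Nd == 0 and r.Ka == 0.0
        assert r.Ks > 0
        assert r.ratio == 0.0 and r.selection_class == "purifying"

    def test_gap_and_ambiguous_columns_excluded(self):
        r_full = ng86_pair(CodonAlignment("ATGGCT", "ATGGCG"))
        r_gap = ng86_pair(CodonAlignment("ATG---GCT", "ATGAAAGCG"))
        r_amb = ng86_pair(CodonAlignment("ATGANAGCT", "ATGAAAGCG"))
        assert r_gap.S_sites == r_full.S_sites
        assert r_amb.S_sites == r_full.S_sites

    def test_internal_stop_is_an_error(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_pair(CodonAlignment("ATGTAAGCT", "ATGAAAGCT"))


class TestBackTranslate:
    def test_gap_threading(self):
        ca = back_translate("M-A", "MKA", "ATGGCT", "ATGAAAGCT")
        assert ca.seq_a == "ATG---GCT"
        assert ca.seq_b == "ATGAAAGCT"

    def test_identical_pair(self):
        ca = back_translate("MA", "MA", "ATGGCT", "ATGGCT")
        assert ca.seq_a == ca.seq_b == "ATGGCT"

    def test_terminal_stop_trimmed(self):
        ca = back_translate("MA", "MA", "ATGGCTTAA", "ATGGCT")
        assert ca.seq_a == "ATGGCT"

    def test_length_mismatch_names_gene(self):
        with pytest.raises(ValueError, match="geneX"):
            back_translate("MA", "MA", "ATGGCTAAA", "ATGGCT", gene_a="geneX")

    def test_round_trip_through_evolved_pairs(self, truth):
        """Translation of the back-translated alignment reproduces the
        protein alignment for simulator-evolved ortholog pairs."""
        from panfam.codons import translate_cds
        g0 = {g.gene_id: g for g in truth.genomes[0].genes}
        vvi = {g.gene_id: g for g in truth.outgroup.genes}
        pairs = list(truth.kaks_truth)[:50]
        for og, tgt in pairs:
            a, b = vvi[og], g0[tgt]
            ca = back_translate(a.protein, b.protein, a.cds, b.cds, og, tgt)
            assert translate_cds(ca.seq_a) == a.protein
            assert translate_cds(ca.seq_b) == b.protein


class TestClassifyAndStrata:
    @pytest.mark.parametrize("ratio, expected", [
        (0.219, "purifying"),     # wild-group average: below 1
        (0.194, "purifying"),
        (1.7, "positive"),
        (None, "undefined"),
    ])
    def test_selection_classes(self, ratio, expected):
        assert classify_selection(_result(ratio)) == expected

    def test_exact_neutral_with_zero_tolerance(self):
        assert classify_selection(_result(1.0), tol=0.0) == "neutral"

    def test_single_stratum_mean(self):
        results = [
            KaKsResult("v1", "G00_x", 1, 2, 0, 0, 0, 0, 0.1, 0.05, 0.5),
            KaKsResult("v2", "G00_y", 1, 2, 0, 0, 0, 0, 0.1, 0.05, 0.5),
        ]
        table = summarize_strata(results, {"v1": 1, "v2": 1}, {"G00": "WDR"})
        cell = table[(table.group == "WDR") & (table.copy_class == 1)]
        assert cell.iloc[0]["mean"] == pytest.approx(0.5)
        assert cell.iloc[0]["n"] == 2

    def test_empty_stratum_emitted_blank(self):
        results = [KaKsResult("v1", "G00_x", 1, 2, 0, 0, 0, 0, 0.1, 0.05, 0.5)]
        table = summarize_strata(results, {"v1": 1, "v2": 3}, {"G00": "WDR"})
        empty = table[(table.group == "WDR") & (table.copy_class == 3)]
        assert empty.iloc[0]["n"] == 0
        assert np.isnan(empty.iloc[0]["mean"])

    def test_stratum_mean_ordering_recovered_from_simulator(self, truth):
        """Mean Ka/Ks per retention stratum preserves the simulated target
        ordering (single < double < triple retention targets)."""
        g0 = {g.gene_id: g for g in truth.genomes[0].genes}
        vvi = {g.gene_id: g for g in truth.outgroup.genes}
        results = []
        for (og, tgt) in truth.kaks_truth:
            a, b = vvi[og], g0[tgt]
            results.append(ng86_pair(
                CodonAlignment(a.cds, b.cds), og, tgt))
        table = summarize_strata(results, truth.retention_truth,
                                 {"G00": "WDR"}, genome_of={
                                     g: "G00" for g in g0})
        means = {int(r.copy_class): r.mean for r in table.itertuples()
                 if r.group == "WDR" and r.n > 0}
        assert means[1] < means[2] < means[3]
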