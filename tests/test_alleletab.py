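"""Placement rescue, similarity filtering, paralog resolution, table build."""

import numpy as np
import pytest

from haplotab import alleletab, homology
from haplotab.alleletab import AllelePair
from haplotab.ioformats import GeneModel, PlacementInterval


def _pl(gid, chrom, s, e):
    return PlacementInterval(gid, chrom, s, e, 1.0)


class TestPlacement:
    def test_exact_substring(self):
        rng = np.random.default_rng(2)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        cds = ref[5000:5900]
        idx = alleletab.build_reference_index({"chr1": ref})
        gene = GeneModel("g1", "A", "c_A", "+", [(0, 900)], cds)
        p = alleletab.place_on_reference(gene, idx)
        assert p is not None
        assert (p.ref_chrom, p.ref_start, p.ref_end) == ("chr1", 5000, 5900)
        assert p.identity == 1.0

    def test_substitutions_recover_hull(self):
        rng = np.random.default_rng(11)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        start, end = 8000, 8900
        cds = list(ref[start:end])
        for pos in rng.choice(900, size=9, replace=False):  # 1% divergence
            cds[pos] = "ACGT"[(("ACGT".index(cds[pos])) + 1) % 4]
        gene = GeneModel("g1", "A", "c_A", "+", [(0, 900)], "".join(cds))
        idx = alleletab.build_reference_index({"chr1": ref})
        p = alleletab.place_on_reference(gene, idx)
        assert p is not None
        assert abs(p.ref_start - start) <= idx.k and abs(p.ref_end - end) <= idx.k

    def test_minus_strand_gene_placed(self):
        from haplotab._kmers import revcomp

        rng = np.random.default_rng(4)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        cds = revcomp(ref[3000:3600])
        gene = GeneModel("g1", "A", "c_A", "-", [(0, 600)], cds)
        idx = alleletab.build_reference_index({"chr1": ref})
        p = alleletab.place_on_reference(gene, idx)
        assert p is not None and (p.ref_start, p.ref_end) == (3000, 3600)

    def test_absent_cds_unplaced(self):
        rng = np.random.default_rng(5)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        cds = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        gene = GeneModel("g1", "A", "c_A", "+", [(0, 600)], cds)
        idx = alleletab.build_reference_index({"chr1": ref})
        assert alleletab.place_on_reference(gene, idx) is None


class TestOverlapRule:
    def test_boundary_strict(self):
        # overlap 50 of min length 100: 50 > 50 is false -> not paired
        a = {"gA": _pl("gA", "c", 100, 200)}
        b = {"gB": _pl("gB", "c", 150, 250)}
        assert alleletab.coordinate_overlap_pairs(a, b) == []

    def test_majority_overlap_paired(self):
        a = {"gA": _pl("gA", "c", 100, 200)}
        b = {"gB": _pl("gB", "c", 140, 240)}
        assert alleletab.coordinate_overlap_pairs(a, b) == [("gA", "gB")]

    def test_chromosome_mismatch(self):
        a = {"gA": _pl("gA", "chr1", 100, 200)}
        b = {"gB": _pl("gB", "chr2", 100, 200)}
        assert alleletab.coordinate_overlap_pairs(a, b) == []

    def test_invalid_min_frac(self):
        with pytest.raises(ValueError):
            alleletab.coordinate_overlap_pairs({}, {}, min_frac=0.0)


class TestSimilarityFilter:
    def test_statuses(self):
        pairs = [AllelePair("a", "b", 1.0, "synteny"),
                 AllelePair("c", "d", 0.875, "synteny"),
                 AllelePair("e", "f", 0.7, "synteny"),
                 AllelePair("g", "h", 0.3, "placement")]
        kept, rejected = alleletab.filter_by_similarity(pairs, 0.7)
        assert [p.status for p in kept] == ["same_allele", "allele"]
        assert [p.status for p in rejected] == ["rejected", "rejected"]

    def test_derived_seven_eighths(self):
        # independent NW-derived value: ACGTACGT vs ACGAACGT -> 7/8
        sim = alleletab.pair_similarity("ACGTACGT", "ACGAACGT")
        assert sim == 0.875
        kept, _ = alleletab.filter_by_similarity(
            [AllelePair("a", "b", sim, "synteny")])
        assert kept[0].status == "allele"


class TestResolveMultiHits:
    def test_ordering_forced(self):
        cands = [AllelePair("A1", "B1", 0.95, "placement"),
                 AllelePair("A1", "B2", 0.88, "placement")]
        primary, paralogs, rejected = alleletab.resolve_multi_hits(cands)
        assert (primary.geneA, primary.geneB) == ("A1", "B1")
        assert [p.geneB for p in paralogs] == ["B2"]
        assert rejected == []

    def test_low_similarity_rejected(self):
        cands = [AllelePair("A1", "B1", 0.95, "placement"),
                 AllelePair("A1", "B2", 0.65, "placement")]
        primary, paralogs, rejected = alleletab.resolve_multi_hits(cands)
        assert primary.geneB == "B1" and paralogs == []
        assert [p.geneB for p in rejected] == ["B2"]

    def test_tie_lexicographic(self):
        cands = [AllelePair("A1", "B2", 0.9, "placement"),
                 AllelePair("A1", "B1", 0.9, "placement")]
        primary, _, _ = alleletab.resolve_multi_hits(cands)
        assert primary.geneB == "B1"


class TestSelection:
    def _table_with(self, ka, ks, kaks):
        from haplotab.alleletab import AlleleTable, LocusRow

        p = AllelePair("a", "b", 0.9, "synteny", "allele", ka, ks, kaks)
        return AlleleTable(rows=[LocusRow("L0", ["a"], ["b"], "two_allele", p)])

    def test_positive(self):
        t = self._table_with(0.02, 0.01, 2.0)
        alleletab.classify_selection(t)
        assert t.rows[0].selection == "positive_selection"

    def test_zero_ka(self):
        t = self._table_with(0.0, 0.03, 0.0)
        alleletab.classify_selection(t)
        assert t.rows[0].selection == "none"

    def test_zero_ks_undefined(self):
        t = self._table_with(0.02, 0.0, None)
        alleletab.classify_selection(t)
        assert t.rows[0].selection == "ratio_undefined"


@pytest.fixture(scope="module")
def table(small_bundle):
    b = small_bundle
    hits = homology.cscore_filter(homology.score_gene_pairs(b.genesA, b.genesB))
    blocks = homology.chain_blocks(hits, b.genesA, b.genesB)
    pairs, _ = homology.synteny_allele_candidates(blocks, b.genesA, b.genesB)
    idx = alleletab.build_reference_index(b.monoploid)
    placements = alleletab.place_genes(b.genesA + b.genesB, idx)
    t = alleletab.build_allele_table(b.genesA, b.genesB, pairs, placements)
    alleletab.add_kaks(t, b.genesA + b.genesB)
    alleletab.classify_selection(t)
    return t


class TestTableOnSimulation:
    def test_no_gene_in_two_loci(self, table):
        seen = [g for r in table.rows for g in r.genesA + r.genesB]
        assert len(seen) == len(set(seen))

    def test_accepted_pairs_respect_strict_threshold(self, table):
        for r in table.rows:
            if r.primary_pair and r.primary_pair.status == "allele":
                assert r.primary_pair.similarity > 0.7
            for p in r.paralogs:
                assert p.similarity > 0.7
        for p in table.audit:
            assert p.status == "rejected"

    def test_classes_match_truth(self, table, small_bundle):
        from collections import Counter

        truth_counts = Counter(t.klass for t in small_bundle.truth.allele_truth)
        got = Counter(r.klass for r in table.rows)
        assert got["multi_allele"] == truth_counts["multi_allele"]
        assert got["one_allele"] == truth_counts["unpaired"]
        assert got["two_allele"] == truth_counts["two_allele"] + truth_counts["identical"]

    def test_identical_pairs_same_allele(self, table, small_bundle):
        idents = {t.geneA_ids[0] for t in small_bundle.truth.allele_truth
                  if t.klass == "identical"}
        for r in table.rows:
            if r.genesA and r.genesA[0] in idents:
                assert r.primary_pair.status == "same_allele"
                assert r.primary_pair.similarity == 1.0

    def test_deterministic_rebuild(self, table, small_bundle):
        b = small_bundle
        hits = homology.cscore_filter(homology.score_gene_pairs(b.genesA, b.genesB))
        blocks = homology.chain_blocks(hits, b.genesA, b.genesB)
        pairs, _ = homology.synteny_allele_candidates(blocks, b.genesA, b.genesB)
        idx = alleletab.build_reference_index(b.monoploid)
        placements = alleletab.place_genes(b.genesA + b.genesB, idx)
        t2 = alleletab.build_allele_table(b.genesA, b.genesB, pairs, placements)
        assert [(r.locus_id, r.genesA, r.genesB, r.klass) for r in table.rows] == \
            [(r.locus_id, r.genesA, r.genesB, r.klass) for r in t2.rows]
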