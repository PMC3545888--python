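"""Alignment, homolog mapping, parity analysis and signature scans."""

import pytest
from oracles import nw_score_oracle, rc, spearman_oracle, transposon_oracle

from baculokit.comparative import (HomologPair, align_global_identity,
                                   collinearity_stats, detect_segmental_indels,
                                   gene_parity, map_homologs,
                                   parity_from_annotation,
                                   scan_transposon_signature,
                                   summary_identities)
from baculokit.errors import BaculokitError, IntegrityError, ParameterError
from baculokit.genome_io import CircularGenome

AA = list("ACDEFGHIKLMNPQRSTVWY")


class TestAlignment:
    def test_identical_sequences(self, rng):
        p = "".join(rng.choice(AA, size=30))
        res = align_global_identity(p, p)
        assert res.pct_identity == 100.0 and res.score == 30

    def test_hand_checkable_mismatch(self):
        res = align_global_identity("MKV", "MQV")
        assert res.aligned_length == 3 and res.identities == 2
        assert round(res.pct_identity, 1) == 66.7

    def test_symmetry(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(AA, size=int(rng.integers(3, 15))))
            b = "".join(rng.choice(AA, size=int(rng.integers(3, 15))))
            r1, r2 = align_global_identity(a, b), align_global_identity(b, a)
            assert r1.score == r2.score
            assert r1.pct_identity == r2.pct_identity

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(BaculokitError, match="empty"):
            align_global_identity("", "MK")
        with pytest.raises(BaculokitError, match="non-amino-acid"):
            align_global_identity("M1K", "MK")

    def test_score_matches_enumeration_oracle(self, rng):
        """150 tiny instances against exhaustive alignment enumeration."""
        for _ in range(150):
            a = "".join(rng.choice(AA[:6], size=int(rng.integers(1, 7))))
            b = "".join(rng.choice(AA[:6], size=int(rng.integers(1, 7))))
            assert align_global_identity(a, b).score == \
                nw_score_oracle(a, b), (a, b)

    def test_score_matches_biopython(self, rng):
        """Independent library cross-check on longer sequences."""
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        for _ in range(30):
            a = "".join(rng.choice(AA, size=int(rng.integers(10, 60))))
            b = "".join(rng.choice(AA, size=int(rng.integers(10, 60))))
            assert align_global_identity(a, b).score == aligner.score(a, b)


class TestHomologs:
    def test_self_comparison(self, rng):
        prots = ["".join(rng.choice(AA, size=40)) for _ in range(6)]
        pairs = map_homologs(prots, prots)
        assert [(p.index_a, p.index_b) for p in pairs] == \
            [(i, i) for i in range(1, 7)]
        assert all(p.pct_identity == 100.0 for p in pairs)

    def test_absent_gene_unpaired(self, rng):
        prots = ["".join(rng.choice(AA, size=40)) for _ in range(5)]
        pairs = map_homologs(prots, prots[:3] + prots[4:])
        assert {p.index_a for p in pairs} == {1, 2, 3, 5}


class TestParity:
    def test_self_comparison_identity_line(self):
        pairs = [HomologPair(i, i, 100.0) for i in range(1, 11)]
        data = gene_parity(pairs, 10, 10)
        assert all(a == b for a, b, _, _ in data.points)
        assert data.unique_a == [] and data.unique_b == []

    def test_conservation_of_orf_counts(self, rng):
        perm = rng.permutation(8) + 1
        pairs = [HomologPair(i + 1, int(perm[i]), 50.0) for i in range(6)]
        data = gene_parity(pairs, 9, 8)
        assert len(data.points) + len(data.unique_a) == 9
        assert len(data.points) + len(data.unique_b) == 8

    def test_duplicate_pairing_is_integrity_error(self):
        pairs = [HomologPair(1, 1, 90.0), HomologPair(2, 1, 80.0)]
        with pytest.raises(IntegrityError, match="twice"):
            gene_parity(pairs, 3, 3)


class TestCollinearity:
    def test_perfect_collinearity(self):
        pairs = [HomologPair(i, i, 99.0) for i in range(1, 20)]
        st = collinearity_stats(gene_parity(pairs, 19, 19))
        assert st["rank_correlation"] == pytest.approx(1.0)
        assert st["adjacency_preserved_fraction"] == 1.0

    def test_full_reversal(self):
        pairs = [HomologPair(i, 20 - i, 99.0) for i in range(1, 20)]
        st = collinearity_stats(gene_parity(pairs, 19, 19))
        assert st["rank_correlation"] == pytest.approx(-1.0)

    def test_spearman_matches_direct_formula(self, rng):
        perm = [int(x) + 1 for x in rng.permutation(100)]
        pairs = [HomologPair(i + 1, perm[i], 50.0) for i in range(100)]
        st = collinearity_stats(gene_parity(pairs, 100, 100))
        want = spearman_oracle(list(range(1, 101)), perm)
        assert st["rank_correlation"] == pytest.approx(want, abs=1e-12)

    def test_single_point_reported_absent(self):
        st = collinearity_stats(gene_parity([HomologPair(1, 1, 50.0)], 1, 1))
        assert st["rank_correlation"] is None


class TestSegmentalIndels:
    def test_identical_genomes_no_indel(self):
        pairs = [HomologPair(i, i, 99.0) for i in range(1, 8)]
        assert detect_segmental_indels(pairs, list(range(1, 8)),
                                       list(range(1, 8))) == []

    def test_interior_run_with_flanks(self):
        order_a = list(range(1, 13))
        paired_a = [i for i in order_a if i not in (5, 6, 7, 8, 9)]
        pairs = [HomologPair(i, k + 1, 95.0)
                 for k, i in enumerate(paired_a)]
        runs = detect_segmental_indels(pairs, order_a,
                                       list(range(1, len(paired_a) + 1)))
        assert runs == [{"genome": "A", "missing_orfs": [5, 6, 7, 8, 9],
                         "flank_left": 4, "flank_right": 10}]

    def test_terminal_run_marked(self):
        pairs = [HomologPair(i, i, 95.0) for i in (1, 2, 3)]
        runs = detect_segmental_indels(pairs, [1, 2, 3, 4, 5], [1, 2, 3])
        assert runs[0]["flank_right"] is None
        assert runs[0]["missing_orfs"] == [4, 5]


class TestTransposonScan:
    def test_constructed_element(self, rng):
        itr = "".join(rng.choice(list("ACGT"), size=13))
        filler = "".join(rng.choice(list("ACGT"), size=60))
        elem = "TTAA" + itr + filler + rc(itr) + "TTAA"
        seq = "CGCGCGCGGC" + elem + "GCCGGCGCGC"
        g = CircularGenome("t", seq, circular=False)
        sigs = scan_transposon_signature(g, 1, len(seq))
        assert len(sigs) == 1
        s = sigs[0]
        assert s.element_start == 15 and s.element_end == 14 + 86
        assert s.itr_seq == itr
        assert s.left_tsd_pos == 11 and s.right_tsd_pos == 101

    def test_imperfect_itr_rejected(self, rng):
        itr = "ACGTACGTACGTA"
        filler = "G" * 40
        bad = list(rc(itr))
        bad[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[5]]
        elem = "TTAA" + itr + filler + "".join(bad) + "TTAA"
        g = CircularGenome("t", "C" * 10 + elem + "C" * 10, circular=False)
        assert scan_transposon_signature(g, 1, g.length) == []

    def test_itr_len_parameter_error(self):
        g = CircularGenome("t", "ACGT" * 100)
        with pytest.raises(ParameterError):
            scan_transposon_signature(g, 1, 100, itr_len=3)

    def test_matches_pair_enumeration_oracle(self, rng):
        """100 random sequences (some with planted elements) vs the oracle."""
        for k in range(100):
            n = int(rng.integers(200, 600))
            seq = list("".join(rng.choice(list("ACGT"), size=n,
                                          p=[0.3, 0.2, 0.2, 0.3])))
            if k % 2:  # plant an element half the time
                itr = "".join(rng.choice(list("ACGT"), size=13))
                elem = "TTAA" + itr + "G" * 30 + rc(itr) + "TTAA"
                pos = int(rng.integers(0, n - len(elem)))
                seq[pos:pos + len(elem)] = elem
            seq = "".join(seq)
            g = CircularGenome(f"o{k}", seq, circular=False)
            got = {(s.element_start, s.element_end)
                   for s in scan_transposon_signature(g, 1, n)}
            assert got == transposon_oracle(seq, 1, n, 13, "TTAA", n), k


class TestSummaryIdentities:
    def test_reference_shared_and_mean(self, reference_ann):
        out = summary_identities(reference_ann, "MacoNPV-B")
        assert out["n_shared"] == 161
        assert out["mean_pct_identity"] == 98.5

    def test_single_row_mean(self, reference_ann):
        from baculokit.genome_io import AnnotationSet, OrfRecord
        ann = AnnotationSet("x", 1000, [OrfRecord(
            1, "", 1, 303, ">", 100, homologs={"V": ("7", 50.0)})], [])
        assert summary_identities(ann, "V") == \
            {"virus": "V", "n_shared": 1, "mean_pct_identity": 50.0}

    def test_unknown_virus_lists_available(self, reference_ann):
        with pytest.raises(BaculokitError, match="MacoNPV-B"):
            summary_identities(reference_ann, "NoSuchVirus")


def test_parity_from_reference_annotation(reference_ann):
    data = parity_from_annotation(reference_ann, "MacoNPV-B")
    assert len(data.points) == 161
    assert data.unique_a == [139]
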