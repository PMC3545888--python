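"""ORF calling on circular genomes: boundaries, wrap handling, oracles."""

import pytest
from oracles import orf_oracle, rc

from baculokit.errors import IntegrityError
from baculokit.genome_io import CircularGenome, OrfRecord
from baculokit.orf_annotation import (OrfCandidate, annotate,
                                      find_candidate_orfs,
                                      resolve_minimal_overlap, translate_orf)
from baculokit.synthetic_data import NONSTOP_CODONS


def _pad(rng, n):
    """Stop-dense padding so no ORF can extend through it."""
    return "".join(rng.choice(["TAA", "TAG", "TGA", "CTA", "TCA", "TTA"])
                   for _ in range(n // 3 + 1))[:n]


def test_poly_a_genome_has_no_candidates():
    g = CircularGenome("a", "A" * 300)
    assert find_candidate_orfs(g) == []


def test_50_aa_boundary(rng):
    body = "ATG" + "".join(rng.choice(NONSTOP_CODONS, size=49)) + "TAA"
    assert len(body) == 153
    seq = _pad(rng, 90) + body + _pad(rng, 90)
    g = CircularGenome("b", seq, circular=False)
    fwd = [c for c in find_candidate_orfs(g, min_aa=50) if c.strand == ">"]
    assert len(fwd) == 1
    c = fwd[0]
    assert c.length_aa == 50 and c.span_nt() == 153
    assert c.start == 91 and c.end == 243
    assert [c for c in find_candidate_orfs(g, min_aa=51)
            if c.strand == ">"] == []


def test_candidates_match_oracle_on_random_sequences(rng):
    """120 random genomes, linear and circular, against the brute oracle."""
    for k in range(120):
        n = int(rng.integers(60, 320))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        circular = bool(k % 2)
        g = CircularGenome(f"r{k}", seq, circular=circular)
        got = {(c.start, c.end, c.strand)
               for c in find_candidate_orfs(g, min_aa=15)}
        assert got == orf_oracle(seq, circular, 15), (k, seq)


def test_origin_wrapping_orf_found_by_rotation(rng, synthetic_genome):
    """Rotating a genome so an ORF spans the origin must keep every call."""
    g, truth = synthetic_genome
    L = g.length
    target = truth.orfs[0]
    shift = target.start + (3 * target.length_aa) // 2  # origin mid-ORF
    rotated = CircularGenome("rot", g.sequence[shift:] + g.sequence[:shift])
    got = {((c.start + shift - 1) % L + 1, (c.end + shift - 1) % L + 1,
            c.strand) for c in find_candidate_orfs(rotated)}
    orig = {(c.start, c.end, c.strand) for c in find_candidate_orfs(g)}
    assert got == orig
    wrapped = [c for c in find_candidate_orfs(rotated) if c.wraps]
    assert len(wrapped) >= 1


def test_candidate_set_with_n_codon_rejected(rng):
    body = "ATG" + "".join(rng.choice(NONSTOP_CODONS, size=20)) + "TAA"
    seq = _pad(rng, 30) + body + _pad(rng, 30)
    g = CircularGenome("n", seq, circular=False)
    assert len(find_candidate_orfs(g, min_aa=15)) == 1
    seq_n = seq[:45] + "N" + seq[46:]  # N inside the ORF
    gn = CircularGenome("n2", seq_n, circular=False)
    assert find_candidate_orfs(gn, min_aa=15) == []


class TestResolveMinimalOverlap:
    def mk(self, start, aa, strand=">"):
        return OrfCandidate(start=start, end=start + 3 * aa + 2,
                            strand=strand, frame=start % 3, length_aa=aa)

    def test_disjoint_candidates_both_kept(self):
        out = resolve_minimal_overlap([self.mk(1, 60), self.mk(400, 70)],
                                      genome_length=1000)
        assert len(out) == 2
        assert [o.index for o in out] == [1, 2]

    def test_nested_candidate_dropped(self):
        long = self.mk(1, 300)
        nested = self.mk(100, 60, "<")
        out = resolve_minimal_overlap([nested, long], genome_length=2000)
        assert len(out) == 1 and out[0].length_aa == 300

    def test_small_overlap_retained(self):
        # 47-nt inclusive overlap, like adjacent gene pairs in real tables
        a = self.mk(1, 100)        # span 1..303
        b = self.mk(257, 100)      # span 257..559 -> overlap 47
        out = resolve_minimal_overlap([a, b], genome_length=1000)
        assert len(out) == 2

    def test_overlap_cap(self):
        a = self.mk(1, 200)        # 1..603
        b = self.mk(300, 200)      # 300..903 -> overlap 304 > 250
        out = resolve_minimal_overlap([a, b], genome_length=2000)
        assert len(out) == 1

    def test_order_invariance(self, rng):
        cands = [self.mk(int(s), int(a))
                 for s, a in zip(rng.integers(1, 3000, 30),
                                 rng.integers(50, 200, 30))]
        base = resolve_minimal_overlap(cands, genome_length=4000)
        for _ in range(5):
            perm = [cands[i] for i in rng.permutation(len(cands))]
            again = resolve_minimal_overlap(perm, genome_length=4000)
            assert [(o.start, o.end) for o in again] == \
                   [(o.start, o.end) for o in base]


class TestTranslate:
    def test_minimal_forward(self):
        g = CircularGenome("t", "ATGAAATAA", circular=False)
        orf = OrfRecord(1, "", 1, 9, ">", 2)
        assert translate_orf(g, orf) == "MK"

    def test_reverse_strand_same_protein(self):
        g = CircularGenome("t", rc("ATGAAATAA"), circular=False)
        orf = OrfRecord(1, "", 1, 9, "<", 2)
        assert translate_orf(g, orf) == "MK"

    def test_wrapping_orf_translates(self):
        # coding "ATGAAATAA" laid over the origin: 8..12 then 1..4
        seq = "ATAA" + "CCC" + "ATGAA"
        g = CircularGenome("t", seq)
        orf = OrfRecord(1, "", 8, 4, ">", 2, wraps=True)
        assert translate_orf(g, orf) == "MK"

    def test_bad_span_raises(self):
        g = CircularGenome("t", "ATGAAATAAC", circular=False)
        with pytest.raises(IntegrityError, match="divisible"):
            translate_orf(g, OrfRecord(1, "", 1, 10, ">", 2))

    def test_planted_proteins_recovered(self, synthetic_genome):
        g, truth = synthetic_genome
        ann = annotate(g)
        by_pos = {(o.start, o.end, o.strand): o for o in ann.orfs}
        for p in truth.orfs:
            orf = by_pos[(p.start, p.end, p.strand)]
            assert translate_orf(g, orf) == p.protein


def test_planted_recovery_is_exact(synthetic_genome):
    """Default synthetic conditions: precision = recall = 1."""
    g, truth = synthetic_genome
    ann = annotate(g)
    got = {(o.start, o.end, o.strand) for o in ann.orfs}
    want = {(o.start, o.end, o.strand) for o in truth.orfs}
    assert got == want


def test_returned_orfs_satisfy_invariants(rng):
    for k in range(10):
        n = int(rng.integers(500, 1500))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        g = CircularGenome(f"i{k}", seq)
        for o in annotate(g, min_aa=20).orfs:
            span = o.span_nt(n)
            assert span == 3 * o.length_aa + 3
            nt = g.fetch(o.start, o.end, wraps=o.wraps)
            if o.strand == "<":
                nt = rc(nt)
            assert nt.startswith("ATG")
            assert nt[-3:] in ("TAA", "TAG", "TGA")
            inner = [nt[i:i + 3] for i in range(3, len(nt) - 3, 3)]
            assert not set(inner) & {"TAA", "TAG", "TGA"}
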