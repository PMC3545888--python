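"""Six-frame ORF prediction on circular genomes.

The calling rule is the classical baculovirus-annotation criterion: an ORF is
a methionine-initiated frame of at least ``min_aa`` amino acids (initiator Met
counted, stop excluded) ending at a stop codon, with at most one ORF per
stop-to-stop interval, anchored at the interval's *first* ATG.  A subsequent
resolution step keeps a minimally-overlapping subset: candidates are admitted
greedily in decreasing length order, rejecting any candidate nested inside an
already-kept ORF or overlapping one by more than ``max_overlap_nt``.

Circular genomes are scanned by walking each stop-to-stop interval around the
circle, which is exact for any genome length (reading-frame chains do not
repeat with period L when L is not a multiple of 3, so a doubled-sequence
scan would not be).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import IntegrityError
from .genome_io import (FORWARD, REVERSE, AnnotationSet, CircularGenome,
                        OrfRecord, reindex, revcomp)

STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfCandidate:
    """A raw ORF call: ATG..stop on one strand, stop codon included in span."""

    start: int          # leftmost genome coordinate, 1-based
    end: int            # rightmost genome coordinate (start > end when wraps)
    strand: str
    frame: int          # 0-2, phase of the first ATG on the scanned strand
    length_aa: int
    wraps: bool = False

    def span_nt(self, genome_length: int | None = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise IntegrityError("wrapping candidate needs genome length")
            return self.end - self.start + 1 + genome_length
        return self.end - self.start + 1


def _codon(s: str, p: int, L: int, circular: bool) -> str | None:
    if circular:
        return s[p % L] + s[(p + 1) % L] + s[(p + 2) % L]
    if p + 3 > L:
        return None
    return s[p:p + 3]


def _emit(a_raw: int, span: int, min_aa: int, s: str, L: int, circular: bool):
    """Validate one first-ATG interval ORF; return (a_raw, span) or None."""
    length_aa = (span - 3) // 3
    if length_aa < min_aa:
        return None
    if circular and span > L:
        return None
    nt = "".join(s[(a_raw + k) % L] for k in range(span)) if circular \
        else s[a_raw:a_raw + span]
    if "N" in nt:
        return None  # ambiguity inside a codon: conservative rejection
    return (a_raw, span)


def _scan_strand(s: str, circular: bool, min_aa: int):
    """Yield (atg_start_raw, span_nt) on one strand, 0-based local coords.

    For circular sequences the walk continues past the origin; the raw start
    stays in [0, L) and the raw end may exceed L, signalling a wrap.
    """
    L = len(s)
    if circular:
        stop_starts = [p for p in range(L)
                       if _codon(s, p, L, True) in STOPS]
        for p in stop_starts:
            q, atg, walked = p + 3, None, 0
            # a reading-frame chain returns to its starting stop within 3L nt
            while walked <= 3 * L:
                codon = _codon(s, q, L, True)
                if codon in STOPS:
                    if atg is not None:
                        hit = _emit(atg, q + 3 - atg, min_aa, s, L, True)
                        if hit is not None:
                            yield (hit[0] % L, hit[1])
                    break
                if atg is None and codon == "ATG":
                    atg = q
                if atg is not None and q + 3 - atg > L:
                    break  # span would exceed the genome: no valid ORF here
                q += 3
                walked += 3
    else:
        for f in range(3):
            interval_start, atg = f, None
            p = f
            while p + 3 <= L:
                codon = s[p:p + 3]
                if codon in STOPS:
                    if atg is not None:
                        hit = _emit(atg, p + 3 - atg, min_aa, s, L, False)
                        if hit is not None:
                            yield hit
                    interval_start, atg = p + 3, None
                elif atg is None and codon == "ATG":
                    atg = p
                p += 3


def find_candidate_orfs(genome: CircularGenome, min_aa: int = 50
                        ) -> list[OrfCandidate]:
    """All first-ATG, >=min_aa ORFs on both strands, sorted by start."""
    L = genome.length
    if L < 3:
        return []
    out: list[OrfCandidate] = []
    seen: set[tuple] = set()
    for strand in (FORWARD, REVERSE):
        s = genome.sequence if strand == FORWARD else revcomp(genome.sequence)
        for a_raw, span in _scan_strand(s, genome.circular, min_aa):
            e_raw = a_raw + span - 1
            wraps = e_raw >= L
            if strand == FORWARD:
                start0 = a_raw
                end0 = e_raw - L if wraps else e_raw
            else:
                start0 = 2 * L - 1 - e_raw if wraps else L - 1 - e_raw
                end0 = L - 1 - a_raw
            key = (start0, end0, strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(OrfCandidate(
                start=start0 + 1, end=end0 + 1, strand=strand,
                frame=a_raw % 3, length_aa=(span - 3) // 3, wraps=wraps))
    out.sort(key=lambda c: (c.start, c.end, c.strand))
    return out


def _intervals(start: int, end: int, wraps: bool, L: int):
    """1-based inclusive linear pieces of a possibly wrapping span."""
    if wraps:
        return [(start, L), (1, end)]
    return [(start, end)]


def overlap_nt(a, b, L: int) -> int:
    """Inclusive-span intersection in nucleotides between two features."""
    total = 0
    for s1, e1 in _intervals(a.start, a.end, a.wraps, L):
        for s2, e2 in _intervals(b.start, b.end, b.wraps, L):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def resolve_minimal_overlap(candidates: list[OrfCandidate],
                            max_overlap_nt: int = 250,
                            genome_length: int | None = None
                            ) -> list[OrfRecord]:
    """Greedy longest-first selection of a minimally-overlapping ORF set.

    A candidate is kept iff its inclusive-span intersection with every
    already-kept ORF is at most ``max_overlap_nt`` and it is not fully nested
    inside a kept ORF.  The result is re-sorted by start and re-indexed.
    """
    if genome_length is None:
        genome_length = max((c.end for c in candidates), default=0)
    order = sorted(candidates,
                   key=lambda c: (-c.length_aa, c.start, c.end, c.strand))
    kept: list[OrfCandidate] = []
    for cand in order:
        ok = True
        for k in kept:
            ov = overlap_nt(cand, k, genome_length)
            if ov > max_overlap_nt or ov == cand.span_nt(genome_length):
                ok = False
                break
        if ok:
            kept.append(cand)
    records = [OrfRecord(index=0, name="", start=c.start, end=c.end,
                         strand=c.strand, length_aa=c.length_aa,
                         wraps=c.wraps) for c in kept]
    return reindex(records)


def translate_orf(genome: CircularGenome, orf) -> str:
    """Protein encoded by an ORF (standard genetic code, stop removed)."""
    L = genome.length
    span = orf.span_nt(L)
    if span < 6:
        raise IntegrityError(f"ORF span {span} nt is shorter than 6")
    if span % 3:
        raise IntegrityError(f"ORF span {span} nt not divisible by 3")
    nt = genome.fetch(orf.start, orf.end, wraps=orf.wraps)
    if orf.strand == REVERSE:
        nt = revcomp(nt)
    prot = str(Seq(nt).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def annotate(genome: CircularGenome, min_aa: int = 50,
             max_overlap_nt: int = 250) -> AnnotationSet:
    """Convenience: candidate scan + overlap resolution -> AnnotationSet."""
    cands = find_candidate_orfs(genome, min_aa=min_aa)
    orfs = resolve_minimal_overlap(cands, max_overlap_nt=max_overlap_nt,
                                   genome_length=genome.length)
    return AnnotationSet(genome.id, genome.length, orfs, [])
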