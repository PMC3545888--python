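"""Whole-genome summary statistics for an annotated baculovirus genome.

Two coding totals are reported deliberately: the plain sum of inclusive ORF
spans, and the overlap-collapsed union.  Published genome reports rarely say
which convention they use, and the two can differ by >1 kb on genomes with
many overlapping gene pairs, so both are exposed.  ORF "bp lengths" follow
the field's nominal convention of 3 x amino-acid count (stop codon excluded);
mean length is reported on both the nominal and the span scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import FORWARD, AnnotationSet, CircularGenome
from .orf_annotation import _intervals, overlap_nt
from .promoter_scan import tally_classes


@dataclass
class GenomeSummary:
    genome_length: int
    gc_percent: float | None
    n_orfs: int
    total_aa: int
    total_coding_nt: int          # sum of inclusive spans
    union_coding_nt: int          # overlap-collapsed
    intergenic_nt: int
    n_forward: int
    n_reverse: int
    largest_orf: tuple[int, int] | None     # (index, nominal bp)
    smallest_orf: tuple[int, int] | None
    n_overlapping_orfs: int
    n_overlapping_pairs: int
    total_overlap_nt: int
    min_overlap_nt: int | None
    max_overlap_nt: int | None
    promoter_tally: dict = field(default_factory=dict)
    hr_sizes: dict = field(default_factory=dict)
    hr_total_nt: int = 0
    hr_fraction_percent: float = 0.0
    mean_nominal_bp: float = 0.0
    mean_span_bp: float = 0.0

    def as_rows(self) -> list[tuple[str, object]]:
        rows = []
        for key, val in vars(self).items():
            rows.append((key, val))
        return rows


def _union_length(pieces: list[tuple[int, int]]) -> int:
    if not pieces:
        return 0
    pieces = sorted(pieces)
    total = 0
    cur_s, cur_e = pieces[0]
    for s, e in pieces[1:]:
        if s > cur_e + 1:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + cur_e - cur_s + 1


def summarize(genome: CircularGenome | None, ann: AnnotationSet
              ) -> GenomeSummary:
    """All summary fields; sequence-dependent ones are None without a genome.

    Overlap statistics run over every ORF pair with intersecting inclusive
    spans.  Promoter tallies come from the annotation's promoter classes and
    always sum to the ORF count.
    """
    L = ann.genome_length
    orfs = ann.orfs
    gc = None
    if genome is not None:
        seq = genome.sequence
        acgt = sum(seq.count(c) for c in "ACGT")  # N excluded
        gc = 100.0 * (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0

    spans = [o.span_nt(L) for o in orfs]
    pieces = [piece for o in orfs
              for piece in _intervals(o.start, o.end, o.wraps, L)]
    union_nt = _union_length(pieces)
    hr_sizes = {name: e - s + 1 for name, s, e in ann.hrs}
    hr_total = sum(hr_sizes.values())

    overlaps = []
    members: set[int] = set()
    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            ov = overlap_nt(orfs[i], orfs[j], L)
            if ov > 0:
                overlaps.append(ov)
                members.add(orfs[i].index)
                members.add(orfs[j].index)

    by_aa = sorted(orfs, key=lambda o: (o.length_aa, o.index))
    n = len(orfs)
    return GenomeSummary(
        genome_length=L,
        gc_percent=gc,
        n_orfs=n,
        total_aa=sum(o.length_aa for o in orfs),
        total_coding_nt=sum(spans),
        union_coding_nt=union_nt,
        intergenic_nt=L - union_nt - hr_total,
        n_forward=sum(o.strand == FORWARD for o in orfs),
        n_reverse=sum(o.strand != FORWARD for o in orfs),
        largest_orf=(by_aa[-1].index, by_aa[-1].nominal_bp()) if orfs else None,
        smallest_orf=(by_aa[0].index, by_aa[0].nominal_bp()) if orfs else None,
        n_overlapping_orfs=len(members),
        n_overlapping_pairs=len(overlaps),
        total_overlap_nt=sum(overlaps),
        min_overlap_nt=min(overlaps) if overlaps else None,
        max_overlap_nt=max(overlaps) if overlaps else None,
        promoter_tally=tally_classes(ann),
        hr_sizes=hr_sizes,
        hr_total_nt=hr_total,
        hr_fraction_percent=100.0 * hr_total / L if L else 0.0,
        mean_nominal_bp=sum(o.nominal_bp() for o in orfs) / n if n else 0.0,
        mean_span_bp=sum(spans) / n if n else 0.0,
    )
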