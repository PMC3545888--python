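"""Baculovirus early/late promoter motif classification.

Each ORF's upstream window (default 180 nt, strictly upstream of and not
including the A of the ATG, on the ORF's coding strand, wrapping the origin on
circular genomes) is scanned for

* an early promoter signature: a TATA box with a CAGT or CATT initiator motif
  beginning 20-40 nt downstream of the TATA box's first base, and
* a late promoter signature: (A/T/G)TAAG.

Motif offsets count nucleotides upstream of the A of the ATG: offset 1 is the
base immediately adjacent.  Motifs must lie entirely inside the window.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

from .genome_io import (FORWARD, AnnotationSet, CircularGenome, revcomp)

LATE_MOTIFS = ("ATAAG", "TTAAG", "GTAAG")
EARLY_INITIATORS = ("CAGT", "CATT")

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
          "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
          "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]"}


@dataclass(frozen=True)
class MotifHit:
    kind: str               # tata | early_initiator | late_initiator
    offset: int             # nt upstream of the A of ATG (1 = adjacent)
    matched_sequence: str   # coding-strand orientation
    strand: str             # coding strand of the ORF


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(_IUPAC[c] for c in pattern.upper()))


def upstream_window(genome: CircularGenome, orf, window: int = 180) -> str:
    """Window sequence 5'->3' on the coding strand; last base abuts the ATG."""
    L = genome.length
    if window > L:
        warnings.warn(f"window {window} exceeds genome length {L}; truncated",
                      stacklevel=2)
        window = L
    if orf.strand == FORWARD:
        atg = orf.start  # 1-based position of the A
        if genome.circular:
            idx = [(atg - 1 - k) % L for k in range(1, window + 1)]
            return "".join(genome.sequence[i] for i in reversed(idx))
        lo = max(1, atg - window)
        return genome.sequence[lo - 1:atg - 1]
    atg = orf.end
    if genome.circular:
        idx = [(atg - 1 + k) % L for k in range(1, window + 1)]
        return revcomp("".join(genome.sequence[i] for i in idx))
    hi = min(L, atg + window)
    return revcomp(genome.sequence[atg:hi])


def _scan(window_seq: str, pattern: re.Pattern):
    """Yield (offset_of_first_base, match_text) for every overlapping hit."""
    W = len(window_seq)
    for i in range(W):
        m = pattern.match(window_seq, i)
        if m and m.end() <= W:
            yield (W - i, m.group())


def find_late_motifs(genome: CircularGenome, orf, window: int = 180
                     ) -> list[MotifHit]:
    """Every (A/T/G)TAAG whose first base lies within the upstream window."""
    wseq = upstream_window(genome, orf, window)
    pat = re.compile("[ATG]TAAG")
    return [MotifHit("late_initiator", off, txt, orf.strand)
            for off, txt in _scan(wseq, pat)]


def find_early_motifs(genome: CircularGenome, orf, window: int = 180,
                      spacer_min: int = 20, spacer_max: int = 40,
                      tata_pattern: str = "TATA"
                      ) -> list[tuple[MotifHit, MotifHit]]:
    """All (TATA box, CAGT/CATT initiator) pairs with an in-range spacer.

    The spacer is measured from the first base of the TATA box to the first
    base of the initiator motif.
    """
    wseq = upstream_window(genome, orf, window)
    tatas = list(_scan(wseq, _iupac_regex(tata_pattern)))
    inits = list(_scan(wseq, re.compile("CA[GT]T")))
    pairs = []
    for t_off, t_txt in tatas:
        for i_off, i_txt in inits:
            spacer = t_off - i_off
            if spacer_min <= spacer <= spacer_max:
                pairs.append((MotifHit("tata", t_off, t_txt, orf.strand),
                              MotifHit("early_initiator", i_off, i_txt,
                                       orf.strand)))
    return pairs


def classify_orf(genome: CircularGenome, orf, window: int = 180,
                 spacer_min: int = 20, spacer_max: int = 40,
                 tata_pattern: str = "TATA") -> str:
    early = bool(find_early_motifs(genome, orf, window, spacer_min,
                                   spacer_max, tata_pattern))
    late = bool(find_late_motifs(genome, orf, window))
    if early and late:
        return "both"
    if early:
        return "early"
    if late:
        return "late"
    return "none"


def classify_promoters(genome: CircularGenome, ann: AnnotationSet,
                       window: int = 180, spacer_min: int = 20,
                       spacer_max: int = 40, tata_pattern: str = "TATA"
                       ) -> tuple[AnnotationSet, dict[str, int]]:
    """Fill promoter_class for every ORF and tally the four classes.

    The tally counts exclusive classes (early_only/late_only/both/none) and
    always sums to the number of ORFs.
    """
    new_orfs = []
    tally = {"early_only": 0, "late_only": 0, "both": 0, "none": 0}
    for orf in ann.orfs:
        cls = classify_orf(genome, orf, window, spacer_min, spacer_max,
                           tata_pattern)
        key = {"early": "early_only", "late": "late_only"}.get(cls, cls)
        tally[key] += 1
        new_orfs.append(replace(orf, promoter_class=cls))
    return (AnnotationSet(ann.genome_id, ann.genome_length, new_orfs,
                          list(ann.hrs)), tally)


def tally_classes(ann: AnnotationSet) -> dict[str, int]:
    """Exclusive promoter-class tally of an already-classified annotation."""
    tally = {"early_only": 0, "late_only": 0, "both": 0, "none": 0,
             "unassigned": 0}
    for orf in ann.orfs:
        key = {"early": "early_only", "late": "late_only"}.get(
            orf.promoter_class, orf.promoter_class)
        tally[key] += 1
    return tally
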