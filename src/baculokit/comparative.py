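"""Pairwise proteome comparison and genome-architecture analysis.

Homology between two annotated genomes is established with deterministic
global (Needleman-Wunsch) protein alignment under unit scoring (match +1,
mismatch 0, gap -1) and reciprocal-best-hit pairing on percent identity.
Shared genes feed an identity-gene-parity analysis - the scatter of ordinal
gene positions in the two genomes, with unique genes pushed onto the axes -
plus collinearity statistics, segmental-indel detection, and a scanner for
transposable-element signatures (perfect inverted terminal repeats flanked by
a duplicated TTAA target site).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import BaculokitError, IntegrityError, ParameterError
from .genome_io import AnnotationSet, CircularGenome, revcomp

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_IDENTITY_BINS = (30.0, 50.0, 70.0)

_EPS = 1e-9


@dataclass(frozen=True)
class AlignmentResult:
    aligned_length: int
    identities: int
    score: float

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.identities / self.aligned_length


@dataclass(frozen=True)
class HomologPair:
    index_a: int
    index_b: int
    pct_identity: float
    score: float = 0.0


@dataclass
class ParityPlotData:
    points: list[tuple[int, int, float, str]]   # (rank_a, rank_b, pct, bin)
    unique_a: list[int]
    unique_b: list[int]
    n_a: int
    n_b: int


@dataclass(frozen=True)
class TransposonSignature:
    element_start: int
    element_end: int
    itr_seq: str
    itr_len: int
    tsd: str
    left_tsd_pos: int
    right_tsd_pos: int


def _dp_matrix(a: str, b: str, match: float, mismatch: float, gap: float
               ) -> np.ndarray:
    """Full Needleman-Wunsch score matrix with a linear gap penalty.

    Left moves within a row are folded in with a running maximum, which is
    exact for linear gap penalties and keeps the inner loop vectorised.
    """
    n, m = len(a), len(b)
    bv = np.frombuffer(b.encode(), dtype="S1")
    g = -gap
    js = np.arange(m + 1, dtype=np.float64)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0] = gap * js
    t = np.empty(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        prev = H[i - 1]
        sub = np.where(bv == a[i - 1].encode(), match, mismatch)
        best = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        t[0] = prev[0] + gap
        t[1:] = best + g * js[1:]
        H[i] = np.maximum.accumulate(t) - g * js
    return H


def align_global_identity(prot_a: str, prot_b: str, match: float = 1.0,
                          mismatch: float = 0.0, gap: float = -1.0
                          ) -> AlignmentResult:
    """Optimal global alignment with deterministic diagonal>up>left traceback.

    Percent identity uses the full alignment length (gap columns included)
    as denominator.
    """
    for p in (prot_a, prot_b):
        if not p:
            raise BaculokitError("empty protein sequence")
        bad = set(p.upper()) - AA_ALPHABET
        if bad:
            raise BaculokitError(f"non-amino-acid characters {sorted(bad)}")
    a, b = prot_a.upper(), prot_b.upper()
    n, m = len(a), len(b)
    H = _dp_matrix(a, b, match, mismatch, gap)
    i, j = n, m
    aligned = identities = 0
    while i > 0 or j > 0:
        aligned += 1
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if abs(H[i, j] - (H[i - 1, j - 1] + sub)) < _EPS:
                identities += a[i - 1] == b[j - 1]
                i -= 1
                j -= 1
                continue
        if i > 0 and abs(H[i, j] - (H[i - 1, j] + gap)) < _EPS:
            i -= 1
            continue
        j -= 1
    return AlignmentResult(aligned_length=aligned, identities=identities,
                           score=float(H[n, m]))


def map_homologs(proteome_a: list[str], proteome_b: list[str],
                 min_pct: float = 15.0) -> list[HomologPair]:
    """Reciprocal-best-hit ortholog pairs on global percent identity.

    Proteomes are indexed by ORF order (1-based).  Best hits are ranked by
    percent identity, then alignment score, then lower partner index; pairs
    under ``min_pct`` are dropped.
    """
    if not proteome_a or not proteome_b:
        return []
    na, nb = len(proteome_a), len(proteome_b)
    pct = np.zeros((na, nb))
    score = np.zeros((na, nb))
    for i, pa in enumerate(proteome_a):
        for j, pb in enumerate(proteome_b):
            res = align_global_identity(pa, pb)
            pct[i, j] = res.pct_identity
            score[i, j] = res.score
    def best(row_pct, row_score):
        order = sorted(range(len(row_pct)),
                       key=lambda k: (-row_pct[k], -row_score[k], k))
        return order[0]
    best_a = [best(pct[i], score[i]) for i in range(na)]
    best_b = [best(pct[:, j], score[:, j]) for j in range(nb)]
    pairs = []
    for i, j in enumerate(best_a):
        if best_b[j] == i and pct[i, j] >= min_pct:
            pairs.append(HomologPair(i + 1, j + 1, float(pct[i, j]),
                                     float(score[i, j])))
    return pairs


def _bin_label(pct: float, bins) -> str:
    edges = sorted(bins)
    if pct < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if pct < hi:
            return f"{lo:g}-{hi:g}"
    return f">={edges[-1]:g}"


def gene_parity(pairs: list[HomologPair], n_a: int, n_b: int,
                bins=DEFAULT_IDENTITY_BINS) -> ParityPlotData:
    """Identity-gene-parity data: rank points for pairs, axis lists for
    unique genes; every ORF of each genome appears exactly once."""
    seen_a, seen_b = set(), set()
    points = []
    for p in pairs:
        if not (1 <= p.index_a <= n_a and 1 <= p.index_b <= n_b):
            raise IntegrityError(f"pair {p} outside genome ranges")
        if p.index_a in seen_a or p.index_b in seen_b:
            raise IntegrityError(f"ORF paired twice: {p}")
        seen_a.add(p.index_a)
        seen_b.add(p.index_b)
        points.append((p.index_a, p.index_b, p.pct_identity,
                       _bin_label(p.pct_identity, bins)))
    points.sort()
    unique_a = [i for i in range(1, n_a + 1) if i not in seen_a]
    unique_b = [j for j in range(1, n_b + 1) if j not in seen_b]
    return ParityPlotData(points, unique_a, unique_b, n_a, n_b)


def collinearity_stats(parity: ParityPlotData) -> dict:
    """Spearman rank correlation plus adjacency preservation of shared genes.

    ``adjacency_preserved_fraction`` is the fraction of consecutive-in-A
    shared-gene pairs whose partners are also consecutive in B (in either
    direction, so a whole-genome inversion still scores 1.0).
    """
    pts = sorted(parity.points)
    out = {"n_shared": len(pts),
           "n_unique_a": len(parity.unique_a),
           "n_unique_b": len(parity.unique_b),
           "rank_correlation": None,
           "adjacency_preserved_fraction": None}
    if len(pts) < 2:
        return out
    ra = [p[0] for p in pts]
    rb = [p[1] for p in pts]
    rho = stats.spearmanr(ra, rb).statistic
    out["rank_correlation"] = float(rho)
    pos_b = {r: k for k, r in enumerate(sorted(rb))}
    preserved = sum(
        abs(pos_b[q] - pos_b[p]) == 1
        for p, q in zip(rb, rb[1:]))
    out["adjacency_preserved_fraction"] = preserved / (len(pts) - 1)
    return out


def detect_segmental_indels(pairs: list[HomologPair],
                            order_a: list[int], order_b: list[int],
                            min_run: int = 2,
                            spans_a: dict | None = None,
                            spans_b: dict | None = None) -> list[dict]:
    """Maximal runs of >=min_run consecutive genes private to one genome.

    ``order_a``/``order_b`` list ORF indices in genome order.  A run present
    in genome A but absent from B is evidence of a segmental deletion in B
    (or insertion in A); flanking paired ORFs are reported, with ``None``
    marking a genome end.  When span maps are given the run's nucleotide
    extent is included.
    """
    paired_a = {p.index_a for p in pairs}
    paired_b = {p.index_b for p in pairs}
    out = []
    for genome, order, paired, spans in (
            ("A", order_a, paired_a, spans_a),
            ("B", order_b, paired_b, spans_b)):
        run: list[int] = []
        flank_left = None
        for idx in list(order) + [None]:
            if idx is not None and idx not in paired:
                run.append(idx)
                continue
            if len(run) >= min_run:
                entry = {"genome": genome, "missing_orfs": list(run),
                         "flank_left": flank_left, "flank_right": idx}
                if spans:
                    entry["nt_extent"] = (spans[run[0]][0], spans[run[-1]][1])
                out.append(entry)
            run = []
            flank_left = idx
    return out


def scan_transposon_signature(genome: CircularGenome, region_start: int,
                              region_end: int, itr_len: int = 13,
                              tsd: str = "TTAA",
                              max_span: int | None = None
                              ) -> list[TransposonSignature]:
    """Perfect-ITR + duplicated-target-site signatures within a region.

    Reports every (element_start, element_end) pair inside the region, at
    most ``max_span`` nucleotides long, where the element begins with a
    ``itr_len``-mer whose reverse complement ends the element, and ``tsd``
    lies immediately 5' of the element and immediately 3' of it.
    """
    if itr_len < 4:
        raise ParameterError("itr_len must be at least 4")
    if not (1 <= region_start <= region_end <= genome.length):
        raise ParameterError("region outside genome")
    seq = genome.sequence
    if max_span is None:
        max_span = region_end - region_start + 1
    k = len(tsd)
    # candidate element starts: position right after a TSD occurrence
    lefts = [i for i in range(region_start, region_end + 1)
             if i - k >= 1 and seq[i - 1 - k:i - 1] == tsd]
    rights = [j for j in range(region_start, region_end + 1)
              if j + k <= len(seq) and seq[j:j + k] == tsd]
    out = []
    for i in lefts:
        itr = seq[i - 1:i - 1 + itr_len]
        if len(itr) < itr_len:
            continue
        rc = revcomp(itr)
        for j in rights:
            span = j - i + 1
            if span < 2 * itr_len or span > max_span:
                continue
            if seq[j - itr_len:j] == rc:
                out.append(TransposonSignature(
                    element_start=i, element_end=j, itr_seq=itr,
                    itr_len=itr_len, tsd=tsd,
                    left_tsd_pos=i - k, right_tsd_pos=j + 1))
    out.sort(key=lambda s: (s.element_start, s.element_end))
    return out


def summary_identities(ann: AnnotationSet, virus: str) -> dict:
    """Shared-gene count and mean percent identity for one homolog column."""
    available = ann.homolog_viruses()
    if virus not in available:
        raise BaculokitError(
            f"unknown virus {virus!r}; available: {available}")
    vals = [o.homologs[virus][1] for o in ann.orfs if virus in o.homologs]
    return {"virus": virus, "n_shared": len(vals),
            "mean_pct_identity": round(float(np.mean(vals)), 1)}


def parity_from_annotation(ann: AnnotationSet, virus: str,
                           n_b: int | None = None,
                           bins=DEFAULT_IDENTITY_BINS) -> ParityPlotData:
    """Parity data built from an annotation table's homolog columns.

    The partner genome's ordinal ranks are taken from the homolog ORF ids
    (digits of ids such as "117a").  Unlike the strict reciprocal-best-hit
    path, published homolog columns may name the same partner ORF twice
    (e.g. a relocated gene and its collinear paralog), so duplicate partner
    ranks are tolerated here.
    """
    points = []
    seen_b: set[int] = set()
    max_b = 0
    unique_a = []
    for o in ann.orfs:
        if virus not in o.homologs:
            unique_a.append(o.index)
            continue
        oid, pct = o.homologs[virus]
        digits = "".join(ch for ch in oid if ch.isdigit())
        if not digits:
            unique_a.append(o.index)
            continue
        rank_b = int(digits)
        max_b = max(max_b, rank_b)
        seen_b.add(rank_b)
        points.append((o.index, rank_b, pct, _bin_label(pct, bins)))
    if n_b is None:
        n_b = max_b
    unique_b = [j for j in range(1, n_b + 1) if j not in seen_b]
    return ParityPlotData(sorted(points), unique_a, unique_b,
                          len(ann.orfs), n_b)
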