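"""Homologous-region (hr) detection from first principles.

Baculovirus hrs are clusters of direct repeats built around a "core"
imperfect palindrome, sitting in AT-rich intergenic sequence.  This module
models them explicitly as two unit classes: ~40-bp near-palindromes (type A)
and 31-bp direct flanking repeats (type B) at the head/end of one or both
sides of each palindrome.  Detection proceeds in three stages:

1. :func:`find_palindromes` - every window whose left arm matches the reverse
   complement of its right arm with at most ``max_arm_mismatch`` mismatches,
   with near-duplicate windows suppressed in favour of the best-scoring one;
2. :func:`find_flank_repeats` - a genome-wide type-B consensus is built by
   column-majority vote over the largest cluster of immediate type-A flank
   segments, then matched within a search radius of each palindrome side;
3. :func:`call_hrs` - single-linkage clustering of units into regions.

AT-richness is reported per region, not used as a gate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .genome_io import AnnotationSet, CircularGenome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class RepeatUnit:
    unit_type: str        # "A" (palindrome) or "B" (flanking direct repeat)
    start: int            # 1-based inclusive
    end: int
    orientation: str = "forward"
    mismatches: int = 0   # vs self-revcomp (A) or vs the B consensus (B)


@dataclass
class HrRegion:
    name: str
    start: int
    end: int
    units: list[RepeatUnit] = field(default_factory=list)
    at_percent: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def n_units(self, unit_type: str | None = None) -> int:
        if unit_type is None:
            return len(self.units)
        return sum(1 for u in self.units if u.unit_type == unit_type)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


def _comp_array(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    for a, b in ((b"A", b"T"), (b"T", b"A"), (b"C", b"G"), (b"G", b"C")):
        out[arr == a] = b
    return out


def find_palindromes(genome: CircularGenome, unit_len: int = 40,
                     max_arm_mismatch: int = 3) -> list[RepeatUnit]:
    """Type-A units: near-palindromic windows of ``unit_len`` nucleotides.

    A window is palindromic when its left arm equals the reverse complement
    of its right arm up to ``max_arm_mismatch`` mismatches.  Overlapping hits
    whose starts lie within ``unit_len // 2`` of a better-scoring hit are
    suppressed (ties resolved toward the leftmost window).
    """
    if unit_len % 2 or unit_len < 8:
        raise ParameterError("unit_len must be even and >= 8")
    L = genome.length
    if unit_len > L:
        return []
    arm = unit_len // 2
    seq = _seq_array(genome.sequence)
    comp = _comp_array(seq)
    n_win = L - unit_len + 1
    mm = np.zeros(n_win, dtype=np.int32)
    for k in range(arm):
        # left-arm base k against the complement of right-arm base (U-1-k)
        j = unit_len - 1 - k
        mm += (seq[k:k + n_win] != comp[j:j + n_win])
    hits = np.flatnonzero(mm <= max_arm_mismatch)
    # non-maximum suppression within unit_len/2
    order = sorted(hits, key=lambda i: (mm[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) > arm for j in kept):
            kept.append(i)
    kept.sort()
    return [RepeatUnit("A", int(i) + 1, int(i) + unit_len,
                       mismatches=2 * int(mm[i])) for i in kept]


def _nearest_match(seq: str, consensus: str, lo: int, hi: int,
                   max_mismatch: int, from_high: bool
                   ) -> tuple[int, int] | None:
    """Nearest qualifying placement of ``consensus`` with start in [lo, hi].

    Scanning starts at the end abutting the palindrome (``hi`` for a left
    flank, ``lo`` for a right flank) so a repeat at the head/end of the
    palindrome wins over an equally good copy further away.
    """
    lo = max(lo, 0)
    hi = min(hi, len(seq) - len(consensus))
    positions = range(hi, lo - 1, -1) if from_high else range(lo, hi + 1)
    for s in positions:
        d = sum(a != b for a, b in zip(seq[s:s + len(consensus)], consensus))
        if d <= max_mismatch:
            return (s, d)
    return None


def build_flank_consensus(genome: CircularGenome, palindromes,
                          unit_len: int = 31, max_mismatch: int = 4
                          ) -> str | None:
    """Column-majority consensus of the immediate type-A flank segments.

    The immediate left and right ``unit_len``-mers of every palindrome
    (de-duplicated by genomic position - a segment between two palindromes
    flanks both) are single-linkage clustered at ``max_mismatch``; the
    largest cluster seeds the consensus.  A flanking *repeat* needs at least
    two supporting copies, so a singleton cluster yields no consensus.
    """
    seq = genome.sequence
    flanks: dict[int, str] = {}
    for a in palindromes:
        left_start = a.start - 1 - unit_len
        if left_start >= 0:
            flanks[left_start] = seq[left_start:a.start - 1]
        if a.end + unit_len <= len(seq):
            flanks[a.end] = seq[a.end:a.end + unit_len]
    segments = [f for f in flanks.values() if len(f) == unit_len]
    if len(segments) < 2:
        return None
    # single-linkage clustering at the mismatch threshold
    clusters: list[list[str]] = []
    assigned = [-1] * len(segments)
    for i, f in enumerate(segments):
        if assigned[i] >= 0:
            continue
        stack, members = [i], []
        assigned[i] = len(clusters)
        while stack:
            j = stack.pop()
            members.append(segments[j])
            for k in range(len(segments)):
                if assigned[k] < 0 and sum(
                        a != b for a, b in
                        zip(segments[j], segments[k])) <= max_mismatch:
                    assigned[k] = len(clusters)
                    stack.append(k)
        clusters.append(members)
    best = max(clusters, key=lambda c: (len(c), min(c)))
    if len(best) < 2:
        return None
    cols = zip(*best)
    return "".join(Counter(col).most_common(1)[0][0] for col in cols)


def find_flank_repeats(genome: CircularGenome, palindromes,
                       unit_len: int = 31, max_mismatch: int = 4,
                       search_radius: int = 100) -> list[RepeatUnit]:
    """Type-B units: consensus-matching 31-mers beside each palindrome.

    At most one B unit is reported per side per type-A unit; a side is used
    only when its best placement within ``search_radius`` has at most
    ``max_mismatch`` mismatches against the refined consensus.
    """
    if not palindromes:
        return []
    consensus = build_flank_consensus(genome, palindromes, unit_len,
                                      max_mismatch)
    if consensus is None:
        return []
    seq = genome.sequence
    taken = {(a.start, a.end) for a in palindromes}
    out = []
    seen_pos = set()
    for a in palindromes:
        sides = (
            (a.start - 1 - search_radius - unit_len + 1,
             a.start - 1 - unit_len, True),
            (a.end, a.end + search_radius - 1, False),
        )
        for lo0, hi0, from_high in sides:
            best = _nearest_match(seq, consensus, lo0, hi0, max_mismatch,
                                  from_high)
            if best is None:
                continue
            s0, d = best
            start, end = s0 + 1, s0 + unit_len
            if (start, end) in taken or start in seen_pos:
                continue
            # never report a B unit sitting inside a type-A unit
            if any(start <= p.end and end >= p.start for p in palindromes):
                continue
            seen_pos.add(start)
            out.append(RepeatUnit("B", start, end, mismatches=d))
    out.sort(key=lambda u: u.start)
    return out


def call_hrs(genome: CircularGenome, units, min_units: int = 2,
             max_gap: int = 500, ann: AnnotationSet | None = None
             ) -> list[HrRegion]:
    """Single-linkage clustering of repeat units into hr regions.

    Clusters with fewer than ``min_units`` type-A units are discarded, as are
    regions whose span overlaps an annotated ORF by more than half of the
    region length (hrs live in intergenic sequence).
    """
    units = sorted(units, key=lambda u: (u.start, u.end))
    clusters: list[list[RepeatUnit]] = []
    for u in units:
        if clusters and u.start - clusters[-1][-1].end - 1 <= max_gap:
            clusters[-1].append(u)
        else:
            clusters.append([u])
    regions = []
    for cluster in clusters:
        n_a = sum(1 for u in cluster if u.unit_type == "A")
        if n_a < min_units:
            continue
        start = min(u.start for u in cluster)
        end = max(u.end for u in cluster)
        if ann is not None:
            length = end - start + 1
            ov = sum(max(0, min(end, o.end) - max(start, o.start) + 1)
                     for o in ann.orfs)
            if ov > 0.5 * length:
                continue
        sub = genome.sequence[start - 1:end]
        acgt = sum(sub.count(c) for c in "ACGT")
        at = sub.count("A") + sub.count("T")
        regions.append(HrRegion(
            name="", start=start, end=end, units=cluster,
            at_percent=100.0 * at / acgt if acgt else 0.0))
    for i, r in enumerate(regions, start=1):
        r.name = f"hr{i}"
    return regions


def _tokens(region: HrRegion) -> list[tuple[str, str]]:
    return [(u.unit_type, u.orientation) for u in region.units]


def _edit_script(tok_a, tok_b, units_a, units_b) -> list[dict]:
    """Minimal insert/delete script between two unit-token sequences."""
    n, m = len(tok_a), len(tok_b)
    # LCS dynamic programme (edits are pure insertions/deletions)
    lcs = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if tok_a[i] == tok_b[j]:
                lcs[i][j] = lcs[i + 1][j + 1] + 1
            else:
                lcs[i][j] = max(lcs[i + 1][j], lcs[i][j + 1])
    # walk the LCS table emitting one op per token, then merge runs
    raw: list[tuple[str, int]] = []  # (op, index into the donor unit list)
    i = j = 0
    while i < n or j < m:
        if i < n and j < m and tok_a[i] == tok_b[j]:
            i += 1
            j += 1
        elif j < m and (i == n or lcs[i][j + 1] >= lcs[i + 1][j]):
            raw.append(("insert", j))
            j += 1
        else:
            raw.append(("delete", i))
            i += 1
    ops: list[dict] = []
    for op, k in raw:
        units = units_b if op == "insert" else units_a
        u = units[k]
        if ops and ops[-1]["op"] == op and ops[-1]["_last"] == k - 1:
            ops[-1]["tokens"].append((u.unit_type, u.orientation))
            ops[-1]["n_units"] += 1
            ops[-1]["end"] = u.end
            ops[-1]["_last"] = k
        else:
            ops.append({"op": op,
                        "tokens": [(u.unit_type, u.orientation)],
                        "n_units": 1, "start": u.start, "end": u.end,
                        "_last": k})
    for entry in ops:
        entry["extent_nt"] = entry["end"] - entry["start"] + 1
        del entry["_last"]
    return ops


def diff_hr_architecture(hrs_a: list[HrRegion], hrs_b: list[HrRegion]
                         ) -> dict:
    """Unit-level edit scripts between rank-paired hr regions.

    Regions are paired by rank (hr1<->hr1, ...); each unit is treated as a
    token of (type, orientation) and a minimal insertion/deletion script is
    reported per pair, with nucleotide extents taken from the unit
    coordinates of the genome carrying the run.  Unpaired trailing regions
    are listed separately.
    """
    n = min(len(hrs_a), len(hrs_b))
    pairs = []
    for ra, rb in zip(hrs_a[:n], hrs_b[:n]):
        script = _edit_script(_tokens(ra), _tokens(rb), ra.units, rb.units)
        pairs.append({"region_a": ra.name, "region_b": rb.name,
                      "edits": script})
    return {"pairs": pairs,
            "unpaired_a": [r.name for r in hrs_a[n:]],
            "unpaired_b": [r.name for r in hrs_b[n:]]}


def hr_lengths(ann: AnnotationSet) -> dict:
    """Inclusive hr interval lengths, their total, and genome fraction."""
    lengths = {name: e - s + 1 for name, s, e in ann.hrs}
    total = sum(lengths.values())
    return {"lengths": lengths, "total_nt": total,
            "fraction_percent": 100.0 * total / ann.genome_length}
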