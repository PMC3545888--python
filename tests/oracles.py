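"""Independent brute-force oracles used to check the scanning algorithms.

Everything here is deliberately naive - position-by-position enumeration with
no shared code or data structures with the package implementations - so that
agreement between the two routes is meaningful evidence of correctness.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _codon_at(s: str, p: int, circular: bool) -> str | None:
    L = len(s)
    if circular:
        return s[p % L] + s[(p + 1) % L] + s[(p + 2) % L]
    if p + 3 > L:
        return None
    return s[p:p + 3]


def orf_oracle(seq: str, circular: bool, min_aa: int) -> set:
    """Every first-ATG ORF >= min_aa as (start, end, strand) 1-based tuples.

    For each ATG the walk extends forward to the terminating stop and
    backward to the bounding stop; the ORF qualifies only if no earlier ATG
    shares its stop-to-stop interval.
    """
    L = len(seq)
    out = set()
    for strand in (">", "<"):
        s = seq if strand == ">" else rc(seq)
        for p in range(L if circular else L - 2):
            if _codon_at(s, p, circular) != "ATG":
                continue
            # forward walk to the stop
            q = p + 3
            stop = None
            while q - p <= L:
                codon = _codon_at(s, q, circular)
                if codon is None:
                    break
                if codon in _STOPS:
                    stop = q
                    break
                q += 3
            if stop is None:
                continue
            aa = (stop - p) // 3
            span = stop + 3 - p
            if aa < min_aa or (circular and span > L):
                continue
            # backward walk: no ATG between the bounding stop and p
            first = True
            b = p - 3
            steps = 0
            while steps <= 3 * L:
                codon = _codon_at(s, b, circular) if (circular or b >= 0) \
                    else None
                if codon is None or codon in _STOPS:
                    break
                if codon == "ATG":
                    first = False
                    break
                b -= 3
                steps += 3
            if not first:
                continue
            nt = "".join(s[(p + k) % L] if circular else s[p + k]
                         for k in range(span))
            if "N" in nt:
                continue
            # map to genome coordinates
            e_raw = p + span - 1
            if strand == ">":
                start0 = p
                end0 = e_raw % L if circular else e_raw
            else:
                start0 = (L - 1 - e_raw) % L
                end0 = L - 1 - p
            out.add((start0 + 1, end0 + 1, strand))
    return out


def palindrome_oracle(seq: str, unit_len: int, max_arm_mismatch: int
                      ) -> list:
    """All near-palindromic windows after best-first suppression, as
    (start, end, mismatches) 1-based tuples (same reporting convention as
    the scanner, arrived at by direct enumeration)."""
    arm = unit_len // 2
    cands = []
    for i in range(len(seq) - unit_len + 1):
        win = seq[i:i + unit_len]
        mm = sum(a != b for a, b in zip(win[:arm], rc(win)[:arm]))
        if mm <= max_arm_mismatch:
            cands.append((mm, i))
    kept = []
    for mm, i in sorted(cands):
        if all(abs(i - j) > arm for _, j in kept):
            kept.append((mm, i))
    return sorted((i + 1, i + unit_len, 2 * mm) for mm, i in kept)


def transposon_oracle(seq: str, region_start: int, region_end: int,
                      itr_len: int, tsd: str, max_span: int) -> set:
    """All (element_start, element_end) pairs by full pair enumeration."""
    k = len(tsd)
    out = set()
    for i in range(region_start, region_end + 1):
        if i - k < 1 or seq[i - 1 - k:i - 1] != tsd:
            continue
        for j in range(region_start, region_end + 1):
            span = j - i + 1
            if span < 2 * itr_len or span > max_span:
                continue
            if j + k > len(seq) or seq[j:j + k] != tsd:
                continue
            itr = seq[i - 1:i - 1 + itr_len]
            if seq[j - itr_len:j] == rc(itr):
                out.add((i, j))
    return out


def nw_score_oracle(a: str, b: str, match=1.0, mismatch=0.0, gap=-1.0
                    ) -> float:
    """Optimal global alignment score by exhaustive recursion (tiny inputs)."""
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def spearman_oracle(xs, ys) -> float:
    """Spearman rho by the direct no-ties formula 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = len(xs)
    rank_x = {v: r for r, v in enumerate(sorted(xs), start=1)}
    rank_y = {v: r for r, v in enumerate(sorted(ys), start=1)}
    d2 = sum((rank_x[x] - rank_y[y]) ** 2 for x, y in zip(xs, ys))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def promoter_window_oracle(window: str):
    """(early_pairs, late_hits) by plain substring enumeration."""
    late = []
    for i in range(len(window) - 4):
        if window[i] in "ATG" and window[i + 1:i + 5] == "TAAG":
            late.append(len(window) - i)
    pairs = []
    tatas = [i for i in range(len(window) - 3)
             if window[i:i + 4] == "TATA"]
    inits = [i for i in range(len(window) - 3)
             if window[i:i + 4] in ("CAGT", "CATT")]
    for t in tatas:
        for c in inits:
            if 20 <= c - t <= 40:
                pairs.append((len(window) - t, len(window) - c))
    return pairs, late
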