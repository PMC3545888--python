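"""Seeded synthetic genomes, genome pairs and qPCR experiments with truth.

The generator emulates the structures the analysis pipeline is built for:

* circular genomes of methionine-initiated ORFs under a random codon model,
  separated by stop-rich AT-biased spacers so that no spurious ORF of the
  calling threshold can arise;
* planted early (TATA + CAGT/CATT at a 20-40 nt spacing) and late
  ((A/T/G)TAAG) promoter motifs in the 180-nt upstream windows, with
  competing motifs scrubbed from every window so each ORF's class is exact;
* homologous-region cassettes of ~40-bp near-palindromic type-A units with
  31-bp type-B direct repeats on one or both sides, AT-rich, sharing one
  genome-wide B consensus;
* a diverged partner genome (synonymous-biased substitutions inside ORFs,
  one contiguous multi-gene deletion, optionally one relocated gene); and
* noisy piecewise-exponential qPCR trajectories (decrease, latent,
  exponential, stationary) read out through a standard curve as triplicate
  Ct values.

Every output is deterministic given the configuration and seed, and every
truth coordinate matches the emitted sequence by construction: after
assembly the generator re-scans its own product with an independent
brute-force scanner and edits any residual off-target reading frame until
the planted annotation is the complete truth.

Type-A palindrome units are drawn "perfect or near-perfect" by design: unit
noise is resampled until an A unit keeps at most 3 mismatches per arm, since
an arbitrarily degraded palindrome would no longer be the structure being
planted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import GenerationError
from .genome_io import FORWARD, REVERSE, CircularGenome, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
#: forward-strand trinucleotides that read as a stop on the reverse strand
RC_STOP_CODONS = ("TTA", "CTA", "TCA")
_BASES = "ACGT"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
NONSTOP_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]
_SYNONYMS: dict[str, list[str]] = {}
for c in NONSTOP_CODONS:
    _SYNONYMS.setdefault(str(Seq(c).translate()), []).append(c)

WINDOW_NT = 180
_PAD_NT = WINDOW_NT + 10          # spacer room reserved per upstream window
_SOUP_UNITS = ("TAA", "TTA", "TAG", "CTA", "TGA", "TCA",
               "T", "A", "AT", "TA")
LATE_PATTERNS = ("ATAAG", "TTAAG", "GTAAG")
EARLY_INITIATORS = ("CAGT", "CATT")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class QpcrConfig:
    """Piecewise replication model + measurement model for one experiment.

    The default trajectory reproduces the canonical in-vivo picture: a drop
    over 0-4 h while input occlusion-derived virus is cleared, a flat latent
    phase to 12 h anchored at 452 viral copies per 1e5 actin copies, an
    exponential phase to 48 h at 0.798 log2/h (a doubling every ~1.25 h,
    reaching 2.02e11 per 1e5 actin), and a slow stationary rise to 96 h.
    """

    times: tuple = (0.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0)
    init_copies: float = 1356.0          # per 1e5 actin at t = 0
    drop_factor: float = 3.0             # fold decrease over 0-4 h
    decrease_end_h: float = 4.0
    latent_end_h: float = 12.0
    expo_rate_log2_per_h: float = 0.7982117
    expo_end_h: float = 48.0
    stationary_rate_log2_per_h: float = 0.047268
    ct_noise_sd: float = 0.3
    n_replicates: int = 3
    actin_copies: float = 1e5
    curve_slope: float = -3.3219         # Ct per log10(copies)
    curve_intercept: float = 40.0
    standards_log10: tuple = (3, 4, 5, 6, 7, 8, 9, 10, 11)


@dataclass
class GeneratorConfig:
    seed: int = 0
    genome_length: int | None = None     # None: as small as the plan needs
    n_orfs: int = 20
    orf_length_range: tuple[int, int] = (60, 300)      # amino acids
    promoter_mix: tuple = (0.25, 0.25, 0.25, 0.25)     # early/late/both/none
    n_hr_cassettes: int = 4
    units_per_hr_range: tuple[int, int] = (3, 7)       # type-A units
    palindrome_len: int = 40
    flank_len: int = 31
    at_bias_in_hr: float = 0.7
    hr_unit_noise: float = 0.02          # per-base substitution inside units
    divergence: float = 0.05             # partner-genome substitution rate
    deletion_block: tuple[int, int] | None = (10, 5)   # (first ORF, n genes)
    relocated_gene: int | None = None
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    def __post_init__(self) -> None:
        if abs(sum(self.promoter_mix) - 1.0) > 1e-9:
            raise GenerationError("promoter_mix must sum to 1")
        for r in (self.hr_unit_noise, self.divergence, self.at_bias_in_hr):
            if not 0.0 <= r <= 1.0:
                raise GenerationError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# plan elements

@dataclass
class OrfPlan:
    key: int                     # stable id across parent/partner genomes
    aa: int
    strand: str
    promoter_class: str
    codons: list[str]            # length aa, codons[0] == 'ATG'
    stop: str
    #: offsets of planted promoter motifs within the realized upstream
    #: window; None until the window has been planted (the window sequence
    #: itself lives in the adjacent spacer element)
    window_protected: set | None = None

    @property
    def seq(self) -> str:
        return "".join(self.codons) + self.stop


@dataclass
class HrPlan:
    parts: list[tuple[str, str]]   # (kind: 'A' | 'B' | 'linker', sequence)

    @property
    def seq(self) -> str:
        return "".join(s for _, s in self.parts)


@dataclass
class SpacerPlan:
    seq: str


@dataclass
class PlantedOrf:
    index: int
    start: int
    end: int
    strand: str
    length_aa: int
    promoter_class: str
    protein: str
    key: int = 0


@dataclass
class PlantedHr:
    name: str
    start: int
    end: int
    units: list[tuple[str, int, int]]    # (type, start, end) 1-based


@dataclass
class TruthRecord:
    orfs: list[PlantedOrf]
    hrs: list[PlantedHr]
    promoter_tally: dict
    plan: list = field(default_factory=list)


@dataclass
class HomologyTruth:
    pairs: list[tuple[int, int, float]]  # (idx in parent, idx in partner, %id)
    deleted_parent_indices: list[int]
    relocated_parent_index: int | None


@dataclass
class QpcrTruth:
    times: np.ndarray
    viral_copies: np.ndarray
    actin_copies: np.ndarray
    per_actin: np.ndarray
    curve_slope: float
    curve_intercept: float


# ---------------------------------------------------------------------------
# sequence soup and window construction

def _soup(rng: np.random.Generator, length: int) -> str:
    """Stop-rich filler: a stop trinucleotide (forward- or reverse-strand
    reading) every few bases, with 1-2 nt shims so the stops keep drifting
    through all six frames.  Shims carry C/G so the filler stays far from
    self-complementarity (random near-palindromes would otherwise mimic
    hr type-A units)."""
    stops = STOP_CODONS + RC_STOP_CODONS
    shims = ("C", "G", "CG", "GC", "CT", "GA", "C", "G")
    out = []
    total = 0
    while total < length:
        u = stops[rng.integers(len(stops))]
        out.append(u)
        total += 3
        if rng.random() < 0.5:
            sh = shims[rng.integers(4)]
            out.append(sh)
            total += len(sh)
    return "".join(out)[:length]


def _find_all(hay: str, needles) -> list[tuple[int, str]]:
    hits = []
    for i in range(len(hay)):
        for nd in needles:
            if hay.startswith(nd, i):
                hits.append((i, nd))
    return hits


def _early_pairs_in(window: str) -> list[tuple[int, int]]:
    """(tata_pos, init_pos) pairs with a 20-40 nt first-base spacing."""
    tatas = [i for i, _ in _find_all(window, ("TATA",))]
    inits = [i for i, _ in _find_all(window, EARLY_INITIATORS)]
    return [(t, c) for t in tatas for c in inits if 20 <= c - t <= 40]


def _late_hits_in(window: str) -> list[int]:
    return [i for i, _ in _find_all(window, LATE_PATTERNS)]


def _make_window(rng: np.random.Generator, promoter_class: str,
                 window: int = WINDOW_NT) -> tuple[str, set]:
    """A coding-strand upstream window realising exactly one promoter class.

    Returns the window string and the set of protected offsets (the planted
    motifs plus the final in-frame TAA, which guarantees that the adjacent
    ORF is the first ATG of its stop-to-stop interval).
    """
    want_early = promoter_class in ("early", "both")
    want_late = promoter_class in ("late", "both")
    for _ in range(50):
        w = list(_soup(rng, window))
        w[-3:] = "TAA"
        protected = set(range(window - 3, window))
        if want_early:
            c = int(rng.integers(24, 61))          # initiator offset
            t = c + int(rng.integers(20, 41))      # TATA offset
            for off, motif in ((t, "TATA"),
                               (c, EARLY_INITIATORS[rng.integers(2)])):
                p = window - off
                w[p:p + len(motif)] = motif
                protected.update(range(p, p + len(motif)))
        if want_late:
            for _try in range(50):
                off = int(rng.integers(8, window - 4))
                p = window - off
                span = set(range(p, p + 5))
                if not span & protected:
                    motif = LATE_PATTERNS[rng.integers(3)]
                    w[p:p + 5] = motif
                    protected.update(span)
                    break
        ok = _fix_window(w, protected, want_early, want_late, rng)
        if ok and _break_window_runs(w, protected, rng):
            # run-breaking may introduce motifs; re-verify, else redraw
            if _fix_window(w, protected, want_early, want_late, rng) \
                    and _longest_stop_free(("".join(w))) < _MAX_RUN_CODONS:
                return "".join(w), protected
    raise GenerationError(
        f"could not realise a {promoter_class!r} promoter window")


_MAX_RUN_CODONS = 30    # cap on stop-free codons per frame inside a window


def _stop_free_runs(s: str):
    """(strand, [trinuc starts]) of the longest stop-free run per frame."""
    runs = []
    for strand, text, bad in ((FORWARD, s, STOP_CODONS),
                              (REVERSE, s, RC_STOP_CODONS)):
        # reverse-strand stops read on the forward text as TTA/CTA/TCA
        for f in range(3):
            run: list[int] = []
            best: list[int] = []
            for p in range(f, len(text) - 2, 3):
                if text[p:p + 3] in bad:
                    run = []
                else:
                    run.append(p)
                    if len(run) > len(best):
                        best = list(run)
            if best:
                runs.append((strand, best))
    return runs


def _longest_stop_free(s: str) -> int:
    return max((len(r) for _, r in _stop_free_runs(s)), default=0)


def _break_window_runs(w: list, protected: set, rng: np.random.Generator,
                       max_iter: int = 60) -> bool:
    """Plant stops until no frame has >= _MAX_RUN_CODONS stop-free codons."""
    for _ in range(max_iter):
        long_runs = [(strand, r) for strand, r in _stop_free_runs("".join(w))
                     if len(r) >= _MAX_RUN_CODONS]
        if not long_runs:
            return True
        strand, run = long_runs[0]
        stops = STOP_CODONS if strand == FORWARD else RC_STOP_CODONS
        mid = len(run) // 2
        order = sorted(range(len(run)), key=lambda k: abs(k - mid))
        for k in order:
            q = run[k]
            if not {q, q + 1, q + 2} & protected:
                w[q:q + 3] = stops[rng.integers(len(stops))]
                break
        else:
            return False
    return False


def _fix_window(w: list, protected: set, want_early: bool, want_late: bool,
                rng: np.random.Generator, max_iter: int = 400) -> bool:
    """Mutate unprotected bases until the window carries exactly its class.

    Unwanted motif kinds are scrubbed entirely; additional copies of a
    *wanted* kind are harmless (they cannot change the class), so only the
    planted, protected motifs are guaranteed and preserved.
    """
    for _ in range(max_iter):
        s = "".join(w)
        offending: list[int] = []
        if not want_early:
            for t, c in _early_pairs_in(s):
                cand = [p for p in (*range(t, t + 4), *range(c, c + 4))
                        if p not in protected]
                if cand:
                    offending = cand
                    break
        if not offending and not want_late:
            for i in _late_hits_in(s):
                cand = [p for p in range(i, i + 5) if p not in protected]
                if cand:
                    offending = cand
                    break
        if not offending:
            if want_early and not _early_pairs_in(s):
                return False    # a fix destroyed the plant; caller redraws
            if want_late and not _late_hits_in(s):
                return False
            return True
        p = offending[rng.integers(len(offending))]
        w[p] = "CG"[rng.integers(2)]
    return False


# ---------------------------------------------------------------------------
# hr cassettes

def _at_biased(rng: np.random.Generator, length: int, at: float) -> str:
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=probs))


def _noisy_unit(rng: np.random.Generator, consensus: str, rate: float,
                check) -> str:
    """Substitute at `rate` per base, resampling until `check` passes."""
    for _ in range(100):
        u = list(consensus)
        n_sub = rng.binomial(len(u), rate)
        for p in rng.choice(len(u), size=n_sub, replace=False):
            u[p] = _BASES[rng.integers(4)]
        cand = "".join(u)
        if check(cand):
            return cand
    return consensus


def _arm_mismatches(unit: str) -> int:
    arm = len(unit) // 2
    rc = revcomp(unit)
    return sum(a != b for a, b in zip(unit[:arm], rc[:arm]))


def _make_hr_plan(rng: np.random.Generator, cfg: GeneratorConfig,
                  a_consensus: str, b_consensus: str) -> HrPlan:
    lo, hi = cfg.units_per_hr_range
    n_a = int(rng.integers(lo, hi + 1))
    parts: list[tuple[str, str]] = []
    for k in range(n_a):
        # type-B repeats sit at the head/end of the palindrome, directly
        # abutting it on one or both sides
        if rng.random() < 0.8:
            parts.append(("B", _noisy_unit(
                rng, b_consensus, cfg.hr_unit_noise,
                lambda u: sum(a != b for a, b in zip(u, b_consensus)) <= 4)))
        parts.append(("A", _noisy_unit(
            rng, a_consensus, cfg.hr_unit_noise,
            lambda u: _arm_mismatches(u) <= 3)))
        if rng.random() < 0.5:
            parts.append(("B", _noisy_unit(
                rng, b_consensus, cfg.hr_unit_noise,
                lambda u: sum(a != b for a, b in zip(u, b_consensus)) <= 4)))
        if k != n_a - 1:
            parts.append(("linker", _soup(rng, int(rng.integers(12, 31)))))
    return HrPlan(parts=parts)


def _hr_consensi(rng: np.random.Generator, cfg: GeneratorConfig
                 ) -> tuple[str, str]:
    """Genome-wide A (palindromic) and B (direct-repeat) unit consensi.

    Stop codons are embedded so cassettes cannot host long reading frames,
    and promoter-like motifs are scrubbed from both units.
    """
    arm = cfg.palindrome_len // 2
    for _ in range(200):
        s = list(_at_biased(rng, arm, cfg.at_bias_in_hr))
        s[3:6] = "TAA"
        s[12:15] = "TGA"
        a_unit = "".join(s) + revcomp("".join(s))
        b = list(_at_biased(rng, cfg.flank_len, cfg.at_bias_in_hr))
        b[5:8] = "TAG"
        b[20:23] = "TAA"
        b_unit = "".join(b)
        bad = False
        for u in (a_unit, b_unit):
            if _late_hits_in(u) or _early_pairs_in(u) or "ATG" in u:
                bad = True
        if not bad:
            return a_unit, b_unit
    raise GenerationError("could not draw clean hr unit consensi")


# ---------------------------------------------------------------------------
# plan construction

def _class_assignment(rng: np.random.Generator, n: int, mix) -> list[str]:
    """Exact class counts matching the mix (largest-remainder), shuffled."""
    names = ("early", "late", "both", "none")
    raw = [m * n for m in mix]
    counts = [int(x) for x in raw]
    rema = sorted(range(4), key=lambda k: raw[k] - counts[k], reverse=True)
    for k in rema[: n - sum(counts)]:
        counts[k] += 1
    classes = [name for name, c in zip(names, counts) for _ in range(c)]
    return list(rng.permutation(classes))


def _build_plan(cfg: GeneratorConfig, rng: np.random.Generator) -> list:
    lo, hi = cfg.orf_length_range
    classes = _class_assignment(rng, cfg.n_orfs, cfg.promoter_mix)
    orfs = []
    for i in range(cfg.n_orfs):
        aa = int(rng.integers(lo, hi + 1))
        codons = ["ATG"] + [NONSTOP_CODONS[rng.integers(len(NONSTOP_CODONS))]
                            for _ in range(aa - 1)]
        orfs.append(OrfPlan(
            key=i + 1, aa=aa,
            strand=FORWARD if rng.random() < 0.5 else REVERSE,
            promoter_class=classes[i], codons=codons,
            stop=STOP_CODONS[rng.integers(3)]))
    n_slots = cfg.n_orfs + 1
    if cfg.n_hr_cassettes > n_slots:
        raise GenerationError("more hr cassettes than spacer slots")
    hr_slots = set(rng.choice(n_slots, size=cfg.n_hr_cassettes,
                              replace=False).tolist())
    a_cons, b_cons = (_hr_consensi(rng, cfg) if cfg.n_hr_cassettes
                      else ("", ""))
    plan: list = []
    for slot in range(n_slots):
        if slot in hr_slots:
            plan.append(SpacerPlan(_soup(rng, _PAD_NT + int(rng.integers(10, 40)))))
            plan.append(_make_hr_plan(rng, cfg, a_cons, b_cons))
            plan.append(SpacerPlan(_soup(rng, _PAD_NT + int(rng.integers(10, 40)))))
        else:
            plan.append(SpacerPlan(
                _soup(rng, 2 * _PAD_NT + int(rng.integers(20, 100)))))
        if slot < cfg.n_orfs:
            plan.append(orfs[slot])
    natural = sum(len(_genome_seq(el)) for el in plan)
    if cfg.genome_length is not None:
        if cfg.genome_length < natural:
            raise GenerationError(
                f"infeasible packing: plan requires {natural} nt but "
                f"genome_length is {cfg.genome_length}")
        extra = cfg.genome_length - natural
        spacers = [el for el in plan if isinstance(el, SpacerPlan)]
        per = extra // len(spacers)
        for k, sp in enumerate(spacers):
            add = per + (extra % len(spacers) if k == len(spacers) - 1 else 0)
            if add:
                sp.seq = sp.seq + _soup(rng, add)
    return plan


def _genome_seq(el) -> str:
    if isinstance(el, OrfPlan):
        return el.seq if el.strand == FORWARD else revcomp(el.seq)
    return el.seq


# ---------------------------------------------------------------------------
# realization: assembly, window planting, sanitation

def _assemble(plan: list) -> tuple[list, list]:
    """Concatenate plan elements; return (seq chars, [(el, start0, end0)])."""
    chars: list[str] = []
    coords = []
    pos = 0
    for el in plan:
        s = _genome_seq(el)
        chars.extend(s)
        coords.append((el, pos, pos + len(s) - 1))
        pos += len(s)
    return chars, coords


def _window_interval(el: OrfPlan, s0: int, e0: int) -> tuple[int, int]:
    """0-based genome interval holding the ORF's upstream window."""
    if el.strand == FORWARD:
        return (s0 - WINDOW_NT, s0 - 1)
    return (e0 + 1, e0 + WINDOW_NT)


@dataclass
class _WindowMeta:
    lo: int                 # genome 0-based interval of the window
    hi: int
    strand: str             # coding strand of the owning ORF
    protected_off: set      # window-string offsets that must not change
    want_early: bool
    want_late: bool

    def extract(self, chars: list) -> list:
        s = "".join(chars[self.lo:self.hi + 1])
        return list(s if self.strand == FORWARD else revcomp(s))

    def insert(self, chars: list, w: list) -> None:
        s = "".join(w)
        chars[self.lo:self.hi + 1] = (s if self.strand == FORWARD
                                      else revcomp(s))

    def protected_abs(self) -> set:
        if self.strand == FORWARD:
            return {self.lo + o for o in self.protected_off}
        return {self.hi - o for o in self.protected_off}


def _plant_windows(chars: list, coords: list, rng: np.random.Generator
                   ) -> list[_WindowMeta]:
    metas = []
    for el, s0, e0 in coords:
        if not isinstance(el, OrfPlan):
            continue
        lo, hi = _window_interval(el, s0, e0)
        if lo < 0 or hi >= len(chars):
            raise GenerationError("window outside genome; pad spacers")
        if el.window_protected is None:
            w, protected = _make_window(rng, el.promoter_class)
            el.window_protected = protected
            fresh = list(w)
        else:
            # the window was realized in a previous assembly and travels
            # with the spacer sequence; reuse it untouched
            protected, fresh = el.window_protected, None
        meta = _WindowMeta(
            lo=lo, hi=hi, strand=el.strand, protected_off=protected,
            want_early=el.promoter_class in ("early", "both"),
            want_late=el.promoter_class in ("late", "both"))
        if fresh is not None:
            meta.insert(chars, fresh)
        metas.append(meta)
    return metas


def _protected_mask(length: int, windows: list[_WindowMeta],
                    coords) -> np.ndarray:
    """Only planted promoter motifs and hr units are inviolable; the rest of
    each window may be edited, with the class re-verified afterwards."""
    mask = np.zeros(length, dtype=bool)
    for meta in windows:
        for p in meta.protected_abs():
            mask[p] = True
    for el, s0, _e0 in coords:
        if isinstance(el, HrPlan):
            off = s0
            for kind, seq in el.parts:
                if kind in ("A", "B"):
                    mask[off:off + len(seq)] = True
                off += len(seq)
    return mask


def _window_class_ok(meta: _WindowMeta, chars: list) -> bool:
    s = "".join(meta.extract(chars))
    has_early = bool(_early_pairs_in(s))
    has_late = bool(_late_hits_in(s))
    return has_early == meta.want_early and has_late == meta.want_late


def _refix_windows(chars: list, windows: list[_WindowMeta],
                   rng: np.random.Generator) -> None:
    """Restore each window's promoter class after out-of-band edits."""
    for meta in windows:
        if _window_class_ok(meta, chars):
            continue
        w = meta.extract(chars)
        if not _fix_window(w, meta.protected_off, meta.want_early,
                           meta.want_late, rng):
            raise GenerationError("window class could not be restored")
        meta.insert(chars, w)


def _iter_orf_hits(s: str, L: int, min_aa: int):
    """Brute ATG-walk scanner: (atg_local, stop_local, aa) on one strand."""
    atg_positions = [p for p in range(L)
                     if s[p] == "A" and s[(p + 1) % L] == "T"
                     and s[(p + 2) % L] == "G"]
    for a0 in atg_positions:
        q = a0 + 3
        while q - a0 <= L:
            codon = s[q % L] + s[(q + 1) % L] + s[(q + 2) % L]
            if codon in STOP_CODONS:
                aa = (q - a0) // 3
                if aa >= min_aa:
                    yield (a0, q % L, aa)
                break
            q += 3


def _find_spurious(seq: str, orf_coords: list, min_aa: int) -> list[dict]:
    """Reading frames >= min_aa aa that are not the planted annotation.

    Planted ORFs are keyed by (strand, local stop position); an in-frame
    internal ATG sharing a planted stop is harmless because the caller
    anchors at the interval's first ATG, which is the planted one (a stop
    codon is planted immediately upstream of every ORF).
    """
    L = len(seq)
    planted: dict[str, dict[int, int]] = {FORWARD: {}, REVERSE: {}}
    for s0, e0, strand, aa in orf_coords:
        if strand == FORWARD:
            planted[FORWARD][(s0 + 3 * aa) % L] = s0
        else:
            planted[REVERSE][(L - 1 - e0 + 3 * aa) % L] = L - 1 - e0
    out = []
    for strand in (FORWARD, REVERSE):
        s = seq if strand == FORWARD else revcomp(seq)
        for a0, stop0, aa in _iter_orf_hits(s, L, min_aa):
            known = planted[strand].get(stop0)
            if known is not None:
                # the planted ORF itself, or an internal in-frame ATG that
                # shares its stop (harmless: the planted ATG is the
                # interval's first, thanks to the upstream TAA pad)
                if a0 == known or (a0 - known) % L < (stop0 - known) % L:
                    continue
            out.append({"strand": strand, "atg_local": a0,
                        "stop_local": stop0, "aa": aa})
    return out


def _host_of(q: int, orf_coords: list):
    for s0, e0, strand, aa in orf_coords:
        if s0 <= q and q + 2 <= e0:
            return (s0, e0, strand)
        if s0 <= q <= e0 or s0 <= q + 2 <= e0:
            return "boundary"
    return None


def _stomp(chars: list, spur: dict, orf_coords: list, mask: np.ndarray,
           rng: np.random.Generator) -> bool:
    """Break one spurious reading frame by planting an in-frame stop."""
    L = len(chars)
    strand, a0, aa = spur["strand"], spur["atg_local"], spur["aa"]
    required = STOP_CODONS if strand == FORWARD else RC_STOP_CODONS
    # mid-run first, with jitter so repeated stomps of interlocking frames
    # do not cycle through the same two positions forever
    jitter = rng.uniform(0, aa / 3, size=aa)
    ks = sorted(range(1, aa), key=lambda k: abs(k - aa / 2) + jitter[k])
    for k in ks:
        l0 = a0 + 3 * k
        q = (l0 % L) if strand == FORWARD else (L - 3 - (l0 % L)) % L
        if q + 2 >= L:
            continue
        if mask[q:q + 3].any():
            continue
        host = _host_of(q, orf_coords)
        if host == "boundary":
            continue
        if host is None:
            trinuc = required[rng.integers(len(required))]
            chars[q:q + 3] = trinuc
            return True
        s0, e0, hstrand = host
        anchor = s0 if hstrand == FORWARD else (e0 - 2)
        c0 = q - ((q - anchor) % 3)
        c_end = c0 + 2 if c0 == q else c0 + 5
        if c0 < s0 + 3 or c_end > e0 - 3:
            continue
        width = c_end - c0 + 1
        offset = q - c0
        host_bad = STOP_CODONS if hstrand == FORWARD else RC_STOP_CODONS
        free = [p for p in range(width) if not offset <= p < offset + 3]
        choices = list(required)
        rng.shuffle(choices)
        for trinuc in choices:
            found = _search_replacement(width, offset, trinuc, free,
                                        host_bad, rng)
            if found is not None:
                chars[c0:c_end + 1] = found
                return True
    return False


def _search_replacement(width, offset, trinuc, free, host_bad, rng):
    """A width-long string with `trinuc` at `offset` whose host codons are
    all non-stop on the host strand."""
    base = [""] * width
    base[offset:offset + 3] = trinuc
    order = [_BASES[i] for i in rng.permutation(4)]

    def rec(idx):
        if idx == len(free):
            cand = "".join(base)
            for c in range(0, width, 3):
                if cand[c:c + 3] in host_bad:
                    return None
            return cand
        for b in order:
            base[free[idx]] = b
            got = rec(idx + 1)
            if got is not None:
                return got
        return None

    return rec(0)


def _sanitize(chars: list, coords: list, mask: np.ndarray,
              rng: np.random.Generator, min_aa: int = 50) -> None:
    orf_coords = [(s0, e0, el.strand, el.aa) for el, s0, e0 in coords
                  if isinstance(el, OrfPlan)]
    for _ in range(60):
        spurious = _find_spurious("".join(chars), orf_coords, min_aa)
        if not spurious:
            return
        for spur in spurious:
            if not _stomp(chars, spur, orf_coords, mask, rng):
                # may already be broken by an earlier stomp this pass
                still = any(s["strand"] == spur["strand"]
                            and s["atg_local"] == spur["atg_local"]
                            for s in _find_spurious("".join(chars),
                                                    orf_coords, min_aa))
                if still:
                    raise GenerationError(
                        f"could not break spurious reading frame {spur}")
    raise GenerationError("sanitation did not converge")


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _part_offsets(el: HrPlan, s0: int):
    """[(absolute 0-based start, (kind, seq))] for a cassette's parts."""
    out = []
    off = s0
    for kind, part in el.parts:
        out.append((off, (kind, part)))
        off += len(part)
    return out


def _arm_mm_at(seq: str, i: int, unit_len: int) -> int:
    arm = unit_len // 2
    return sum(seq[i + k] != _COMP[seq[i + unit_len - 1 - k]]
               for k in range(arm))


def _spurious_palindrome_windows(seq: str, planted_a: list,
                                 unit_len: int = 40, thresh: int = 3
                                 ) -> list[int]:
    """Starts of near-palindromic windows not explained by a planted A unit."""
    arm = unit_len // 2
    sv = np.frombuffer(seq.encode(), dtype="S1")
    comp = sv.copy()
    for x, y in ((b"A", b"T"), (b"T", b"A"), (b"C", b"G"), (b"G", b"C")):
        comp[sv == x] = y
    n_win = len(seq) - unit_len + 1
    if n_win <= 0:
        return []
    mm = np.zeros(n_win, dtype=np.int32)
    for k in range(arm):
        j = unit_len - 1 - k
        mm += (sv[k:k + n_win] != comp[j:j + n_win])
    out = []
    for i in np.flatnonzero(mm <= thresh):
        i = int(i)
        if any(min(i + unit_len - 1, e0) - max(i, s0) + 1 >= arm
               for s0, e0 in planted_a):
            continue
        out.append(i)
    return out


def _break_spurious_palindromes(chars: list, coords: list, mask: np.ndarray,
                                rng: np.random.Generator,
                                unit_len: int = 40) -> bool:
    """Mutate unprotected bases until no off-target near-palindrome remains.

    Positions inside planted ORFs are edited at whole-codon granularity so
    the reading frame stays stop-free; the recorded protein is derived after
    all edits, so codon identity is free to change.
    """
    planted_a = []
    orf_coords = []
    for el, s0, _e0 in coords:
        if isinstance(el, HrPlan):
            off = s0
            for kind, part in el.parts:
                if kind == "A":
                    planted_a.append((off, off + len(part) - 1))
                off += len(part)
        elif isinstance(el, OrfPlan):
            orf_coords.append((s0, _e0, el.strand))
    for _ in range(60):
        seq = "".join(chars)
        spurious = _spurious_palindrome_windows(seq, planted_a, unit_len)
        if not spurious:
            return True
        i = spurious[0]
        if not _degrade_palindrome(chars, i, unit_len, mask, orf_coords, rng):
            raise GenerationError(
                f"could not break spurious palindrome at {i + 1}")
    return False


def _degrade_palindrome(chars: list, i: int, unit_len: int,
                        mask: np.ndarray, orf_coords: list,
                        rng: np.random.Generator) -> bool:
    arm = unit_len // 2
    target_mm = 6
    ks = list(rng.permutation(arm))
    for k in ks:
        if _arm_mm_at("".join(chars), i, unit_len) >= target_mm:
            return True
        lp, rp = i + k, i + unit_len - 1 - k
        if chars[lp] != _COMP[chars[rp]]:
            continue    # already a mismatch pair
        for pos, partner in ((lp, rp), (rp, lp)):
            if mask[pos]:
                continue
            avoid = {chars[pos], _COMP[chars[partner]]}
            host = next(((s0, e0, st) for s0, e0, st in orf_coords
                         if s0 <= pos <= e0), None)
            if host is None:
                options = [b for b in _BASES if b not in avoid]
                chars[pos] = options[rng.integers(len(options))]
                break
            s0, e0, strand = host
            anchor = s0 if strand == FORWARD else (e0 - 2)
            c0 = pos - ((pos - anchor) % 3)
            if c0 < s0 + 3 or c0 + 2 > e0 - 3:
                continue
            off = pos - c0
            bad = STOP_CODONS if strand == FORWARD else RC_STOP_CODONS
            cur = "".join(chars[c0:c0 + 3])
            cands = [cur[:off] + b + cur[off + 1:]
                     for b in _BASES if b not in avoid]
            cands = [c for c in cands if c not in bad]
            if cands:
                chars[c0:c0 + 3] = cands[rng.integers(len(cands))]
                break
    return _arm_mm_at("".join(chars), i, unit_len) >= 4


def _writeback(chars: list, coords: list) -> None:
    """Push post-sanitation sequence back into the plan elements."""
    seq = "".join(chars)
    for el, s0, e0 in coords:
        sub = seq[s0:e0 + 1]
        if isinstance(el, OrfPlan):
            coding = sub if el.strand == FORWARD else revcomp(sub)
            el.codons = [coding[3 * k:3 * k + 3] for k in range(el.aa)]
            el.stop = coding[-3:]
        elif isinstance(el, SpacerPlan):
            el.seq = sub
        else:
            off = 0
            new_parts = []
            for kind, part in el.parts:
                new_parts.append((kind, sub[off:off + len(part)]))
                off += len(part)
            el.parts = new_parts


def _truth_from(plan: list, coords: list) -> TruthRecord:
    orfs = []
    hrs = []
    n_hr = 0
    tally = {"early": 0, "late": 0, "both": 0, "none": 0}
    for el, s0, e0 in coords:
        if isinstance(el, OrfPlan):
            coding = "".join(el.codons)
            orfs.append(PlantedOrf(
                index=0, start=s0 + 1, end=e0 + 1, strand=el.strand,
                length_aa=el.aa, promoter_class=el.promoter_class,
                protein=str(Seq(coding).translate()), key=el.key))
            tally[el.promoter_class] += 1
        elif isinstance(el, HrPlan):
            n_hr += 1
            units = []
            off = s0
            for kind, part in el.parts:
                if kind in ("A", "B"):
                    units.append((kind, off + 1, off + len(part)))
                off += len(part)
            hrs.append(PlantedHr(name=f"hr{n_hr}",
                                 start=units[0][1], end=units[-1][2],
                                 units=units))
    orfs.sort(key=lambda o: o.start)
    for i, o in enumerate(orfs, start=1):
        o.index = i
    return TruthRecord(orfs=orfs, hrs=hrs, promoter_tally=tally, plan=plan)


def _realize(plan: list, rng: np.random.Generator, genome_id: str
             ) -> tuple[CircularGenome, TruthRecord]:
    chars, coords = _assemble(plan)
    windows = _plant_windows(chars, coords, rng)
    mask = _protected_mask(len(chars), windows, coords)
    # palindrome-breaking and frame sanitation can interact (both edit the
    # sequence), so alternate until a sanitation pass leaves no palindrome
    planted_a = [(off, off + len(part) - 1)
                 for el, s0, _e0 in coords if isinstance(el, HrPlan)
                 for off, (kind, part) in _part_offsets(el, s0)
                 if kind == "A"]
    orf_coords = [(s0, e0, el.strand, el.aa) for el, s0, e0 in coords
                  if isinstance(el, OrfPlan)]
    for _ in range(15):
        _break_spurious_palindromes(chars, coords, mask, rng)
        _sanitize(chars, coords, mask, rng)
        _refix_windows(chars, windows, rng)
        seq = "".join(chars)
        if (not _spurious_palindrome_windows(seq, planted_a)
                and not _find_spurious(seq, orf_coords, 50)
                and all(_window_class_ok(m, chars) for m in windows)):
            break
    else:
        raise GenerationError("sequence sanitation did not stabilise")
    _writeback(chars, coords)
    genome = CircularGenome(genome_id, "".join(chars), circular=True)
    return genome, _truth_from(plan, coords)


# ---------------------------------------------------------------------------
# public operations

def generate_annotated_genome(cfg: GeneratorConfig
                              ) -> tuple[CircularGenome, TruthRecord]:
    """A circular genome with planted ORFs, promoter classes and hrs."""
    rng = np.random.default_rng(cfg.seed)
    plan = _build_plan(cfg, rng)
    return _realize(plan, rng, genome_id=f"synthetic-{cfg.seed}")


def _mutate_orf(el: OrfPlan, rate: float, rng: np.random.Generator) -> None:
    n_sub = rng.binomial(3 * el.aa, rate)
    for _ in range(n_sub):
        if el.aa < 2:
            break
        idx = int(rng.integers(1, el.aa))
        cur = el.codons[idx]
        aa = str(Seq(cur).translate())
        if rng.random() < 0.75:
            options = [c for c in _SYNONYMS[aa] if c != cur]
        else:
            options = [c for c in NONSTOP_CODONS
                       if str(Seq(c).translate()) != aa]
        if options:
            el.codons[idx] = options[rng.integers(len(options))]


def _mutate_neutral(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_sub = rng.binomial(len(out), rate)
    for p in rng.choice(len(out), size=min(n_sub, len(out)), replace=False):
        out[p] = _BASES[rng.integers(4)]
    return "".join(out)


def diverge_genome(genome: CircularGenome, truth: TruthRecord,
                   cfg: GeneratorConfig
                   ) -> tuple[CircularGenome, TruthRecord, HomologyTruth]:
    """A diverged partner genome with one segmental deletion and, optionally,
    one relocated gene; substitutions are synonymous-biased inside ORFs and
    suppressed inside planted hr units and promoter windows."""
    rng = np.random.default_rng([cfg.seed, 104729])
    plan = copy.deepcopy(truth.plan)
    keys = [el.key for el in plan if isinstance(el, OrfPlan)]
    deleted: list[int] = []
    if cfg.deletion_block is not None:
        first, n_del = cfg.deletion_block
        deleted = [k for k in keys if first <= k < first + n_del]
        if not deleted or (first + n_del - 1) not in keys:
            raise GenerationError("deletion_block outside gene range")
    for el in plan:
        if isinstance(el, OrfPlan):
            _mutate_orf(el, cfg.divergence, rng)
        elif isinstance(el, SpacerPlan):
            # the first/last window-length stretches of a spacer may carry a
            # neighbouring ORF's realized promoter window: suppressed
            mid = _mutate_neutral(el.seq[WINDOW_NT:-WINDOW_NT],
                                  cfg.divergence, rng)
            el.seq = el.seq[:WINDOW_NT] + mid + el.seq[-WINDOW_NT:] \
                if len(el.seq) > 2 * WINDOW_NT else el.seq
        else:
            el.parts = [(kind, _mutate_neutral(part, cfg.divergence, rng)
                         if kind == "linker" else part)
                        for kind, part in el.parts]
    # contiguous deletion: drop the block's ORFs and the spacers between them
    if deleted:
        out: list = []
        i = 0
        while i < len(plan):
            el = plan[i]
            if isinstance(el, OrfPlan) and el.key in deleted:
                # also drop the following spacer unless this is the last
                # deleted gene (keep one flanking spacer)
                if el.key != deleted[-1] and i + 1 < len(plan) \
                        and isinstance(plan[i + 1], SpacerPlan):
                    i += 2
                else:
                    i += 1
                continue
            out.append(el)
            i += 1
        plan = out
    relocated = cfg.relocated_gene
    if relocated is not None and relocated not in deleted:
        idx = next(i for i, el in enumerate(plan)
                   if isinstance(el, OrfPlan) and el.key == relocated)
        el = plan.pop(idx)
        el.window_protected = None   # fresh pads need a fresh window
        # splice into the middle of a distant spacer: both spacer ends keep
        # their original content, so neighbouring ORFs' realized windows
        # (which sit at spacer edges) survive the insertion
        spacer_positions = [i for i, e in enumerate(plan)
                            if isinstance(e, SpacerPlan)
                            and len(e.seq) >= 2 * WINDOW_NT]
        target = spacer_positions[(spacer_positions.index(
            min(spacer_positions, key=lambda i: abs(i - idx)))
            + len(spacer_positions) // 2) % len(spacer_positions)]
        spacer = plan[target]
        cut = len(spacer.seq) // 2
        left = SpacerPlan(spacer.seq[:cut] + _soup(rng, _PAD_NT + 20))
        right = SpacerPlan(_soup(rng, _PAD_NT + 20) + spacer.seq[cut:])
        plan[target:target + 1] = [left, el, right]
    partner, partner_truth = _realize(
        plan, rng, genome_id=f"{genome.id}-partner")
    parent_by_key = {o.key: o for o in truth.orfs}
    pairs = []
    for o in partner_truth.orfs:
        p = parent_by_key[o.key]
        matches = sum(a == b for a, b in zip(p.protein, o.protein))
        pairs.append((p.index, o.index, 100.0 * matches / p.length_aa))
    return partner, partner_truth, HomologyTruth(
        pairs=pairs,
        deleted_parent_indices=sorted(parent_by_key[k].index
                                      for k in deleted),
        relocated_parent_index=(parent_by_key[relocated].index
                                if relocated is not None else None))


# ---------------------------------------------------------------------------
# qPCR simulation

def _true_per_actin(t: float, q: QpcrConfig) -> float:
    v4 = q.init_copies / q.drop_factor
    if t <= q.decrease_end_h:
        if q.decrease_end_h == 0:
            return q.init_copies
        return q.init_copies * (1.0 / q.drop_factor) ** (t / q.decrease_end_h)
    if t <= q.latent_end_h:
        return v4
    if t <= q.expo_end_h:
        return v4 * 2.0 ** (q.expo_rate_log2_per_h * (t - q.latent_end_h))
    v48 = v4 * 2.0 ** (q.expo_rate_log2_per_h
                       * (q.expo_end_h - q.latent_end_h))
    return v48 * 2.0 ** (q.stationary_rate_log2_per_h * (t - q.expo_end_h))


def simulate_qpcr_experiment(cfg: GeneratorConfig
                             ) -> tuple[pd.DataFrame, pd.DataFrame, QpcrTruth]:
    """Standards and samples tables plus the underlying truth.

    Ct values come from inverting the configured standard curve on the true
    copy numbers, plus Gaussian noise of sd ``ct_noise_sd`` per replicate.
    """
    q = cfg.qpcr
    if q.init_copies <= 0:
        raise GenerationError("init_copies must be positive")
    rng = np.random.default_rng([cfg.seed, 15485863])
    times = np.asarray(q.times, dtype=float)
    per_actin = np.array([_true_per_actin(t, q) for t in times])
    actin = np.full_like(per_actin, q.actin_copies)
    viral = per_actin * q.actin_copies / 1e5
    reps = [f"ct_{i + 1}" for i in range(q.n_replicates)]

    def ct_of(copies: float) -> float:
        return q.curve_slope * np.log10(copies) + q.curve_intercept

    std_rows = []
    for target in ("rr2b", "actin"):
        for lg in q.standards_log10:
            noise = rng.normal(0.0, q.ct_noise_sd, size=q.n_replicates)
            std_rows.append({"target": target, "log10_copies": float(lg),
                             **{r: q.curve_slope * lg + q.curve_intercept + e
                                for r, e in zip(reps, noise)}})
    samp_rows = []
    for t, v, a in zip(times, viral, actin):
        for target, copies in (("rr2b", v), ("actin", a)):
            noise = rng.normal(0.0, q.ct_noise_sd, size=q.n_replicates)
            samp_rows.append({"time_h": float(t), "target": target,
                              **{r: ct_of(copies) + e
                                 for r, e in zip(reps, noise)}})
    truth = QpcrTruth(times=times, viral_copies=viral, actin_copies=actin,
                      per_actin=per_actin, curve_slope=q.curve_slope,
                      curve_intercept=q.curve_intercept)
    return pd.DataFrame(std_rows), pd.DataFrame(samp_rows), truth
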