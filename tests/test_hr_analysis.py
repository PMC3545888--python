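"""Homologous-region detection: palindromes, flank repeats, clustering."""

import pytest
from oracles import palindrome_oracle, rc

from baculokit.errors import ParameterError
from baculokit.genome_io import CircularGenome
from baculokit.hr_analysis import (HrRegion, RepeatUnit, call_hrs,
                                   diff_hr_architecture, find_flank_repeats,
                                   find_palindromes, hr_lengths)


def _neutral(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n,
                              p=[0.2, 0.3, 0.3, 0.2]))


class TestPalindromes:
    def test_constructed_perfect_palindrome(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=20))
        pal = s + rc(s)
        seq = _neutral(rng, 200) + pal + _neutral(rng, 200)
        units = find_palindromes(CircularGenome("p", seq, circular=False))
        assert any(u.start == 201 and u.end == 240 and u.mismatches == 0
                   for u in units)

    def test_mismatch_threshold(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=20))
        pal = list(s + rc(s))
        for pos in (3, 11):  # two substitutions in the left arm
            pal[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[pal[pos]]
        seq = _neutral(rng, 150) + "".join(pal) + _neutral(rng, 150)
        g = CircularGenome("m", seq, circular=False)
        at2 = find_palindromes(g, max_arm_mismatch=2)
        assert any(u.start == 151 for u in at2)
        at1 = find_palindromes(g, max_arm_mismatch=1)
        assert not any(u.start == 151 for u in at1)

    def test_odd_unit_len_rejected(self):
        with pytest.raises(ParameterError):
            find_palindromes(CircularGenome("x", "ACGT" * 30), unit_len=39)

    def test_matches_exhaustive_oracle(self, rng):
        """200 seeded random sequences against the all-windows oracle."""
        for k in range(200):
            n = int(rng.integers(80, 400))
            at = rng.uniform(0.5, 0.8)
            seq = "".join(rng.choice(
                list("ACGT"), size=n,
                p=[at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]))
            got = [(u.start, u.end, u.mismatches)
                   for u in find_palindromes(
                       CircularGenome(f"o{k}", seq, circular=False))]
            assert sorted(got) == palindrome_oracle(seq, 40, 3), k

    def test_revcomp_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1500,
                                 p=[0.3, 0.2, 0.2, 0.3]))
        L = len(seq)
        fwd = find_palindromes(CircularGenome("f", seq, circular=False))
        bwd = find_palindromes(CircularGenome("b", rc(seq), circular=False))
        mapped = sorted((L + 1 - u.end, L + 1 - u.start) for u in bwd)
        assert mapped == sorted((u.start, u.end) for u in fwd)


class TestFlankRepeats:
    def _cassette(self, rng, layout):
        """Build a genome from a B-A-B style layout of planted units."""
        s = "".join(rng.choice(list("ACGT"), size=20, p=[.35, .15, .15, .35]))
        a_unit = s + rc(s)
        b_unit = "".join(rng.choice(list("ACGT"), size=31,
                                    p=[.35, .15, .15, .35]))
        parts, coords, pos = [], {}, 150
        for kind in layout:
            unit = a_unit if kind == "A" else b_unit
            parts.append(unit)
            coords.setdefault(kind, []).append((pos + 1, pos + len(unit)))
            pos += len(unit)
        seq = _neutral(rng, 150) + "".join(parts) + _neutral(rng, 150)
        return CircularGenome("c", seq, circular=False), coords, b_unit

    def test_planted_bab_found_with_correct_sides(self, rng):
        g, coords, _ = self._cassette(rng, "BABBA")
        pals = find_palindromes(g)
        bs = find_flank_repeats(g, pals)
        assert {(u.start, u.end) for u in bs} == set(coords["B"])

    def test_lone_palindrome_yields_no_flanks(self, rng):
        g, coords, _ = self._cassette(rng, "A")
        pals = find_palindromes(g)
        assert find_flank_repeats(g, pals) == []

    def test_mismatch_cap(self, rng):
        g, coords, b_unit = self._cassette(rng, "BABA")
        # corrupt the second B beyond the cap
        s, e = coords["B"][1]
        seq = list(g.sequence)
        for off in (2, 8, 14, 20, 26):
            seq[s - 1 + off] = {"A": "C", "C": "A",
                                "G": "T", "T": "G"}[seq[s - 1 + off]]
        g2 = CircularGenome("c2", "".join(seq), circular=False)
        bs = find_flank_repeats(g2, find_palindromes(g2), max_mismatch=4)
        assert (s, e) not in {(u.start, u.end) for u in bs}


class TestCallHrs:
    def test_planted_cassettes_recovered(self, synthetic_genome):
        g, truth = synthetic_genome
        pals = find_palindromes(g)
        flanks = find_flank_repeats(g, pals)
        regions = call_hrs(g, pals + flanks)
        assert len(regions) == len(truth.hrs)
        for r, p in zip(regions, truth.hrs):
            assert abs(r.start - p.start) <= 40 and abs(r.end - p.end) <= 40

    def test_scattered_singletons_make_no_region(self):
        units = [RepeatUnit("A", 100, 139), RepeatUnit("A", 2000, 2039)]
        g = CircularGenome("s", "ACGT" * 1000)
        assert call_hrs(g, units, min_units=2, max_gap=500) == []

    def test_span_equals_unit_extent_and_at_percent(self, synthetic_genome):
        g, _ = synthetic_genome
        pals = find_palindromes(g)
        flanks = find_flank_repeats(g, pals)
        for r in call_hrs(g, pals + flanks):
            assert r.start == min(u.start for u in r.units)
            assert r.end == max(u.end for u in r.units)
            assert 0 <= r.at_percent <= 100

    def test_reference_hr_lengths(self, reference_ann):
        info = hr_lengths(reference_ann)
        assert info["lengths"] == {"hr1": 1185, "hr2": 1766,
                                   "hr3": 1074, "hr4": 724}
        assert info["total_nt"] == 4749
        assert round(info["fraction_percent"], 2) == 3.08


class TestDiffArchitecture:
    def _region(self, tokens, start=1):
        units, pos = [], start
        for t in tokens:
            ln = 40 if t == "A" else 31
            units.append(RepeatUnit(t, pos, pos + ln - 1))
            pos += ln + 5
        return HrRegion("hr", units[0].start, units[-1].end, units)

    def test_identical_regions_empty_script(self):
        a = self._region("BABBA")
        b = self._region("BABBA", start=500)
        out = diff_hr_architecture([a], [b])
        assert out["pairs"][0]["edits"] == []

    def test_single_token_insertion(self):
        a = self._region("BAB")
        b = self._region("BAAB")
        out = diff_hr_architecture([a], [b])
        edits = out["pairs"][0]["edits"]
        assert len(edits) == 1
        assert edits[0]["op"] == "insert" and edits[0]["n_units"] == 1
        assert edits[0]["tokens"] == [("A", "forward")]

    def test_planted_two_token_deletion(self):
        a = self._region("BABABA")
        b = self._region("BABA")  # the trailing B,A run removed
        out = diff_hr_architecture([a], [b])
        edits = out["pairs"][0]["edits"]
        assert len(edits) == 1
        assert edits[0]["op"] == "delete" and edits[0]["n_units"] == 2

    def test_unpaired_regions_reported(self):
        a = [self._region("BA"), self._region("AB", start=900)]
        b = [self._region("BA")]
        out = diff_hr_architecture(a, b)
        assert out["unpaired_a"] == [a[1].name]
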