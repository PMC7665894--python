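"""CRISPR array parsing and cas2-flank trim/filter rules."""

import numpy as np
import pytest

from crisprterm.arrays import (CoordinateError, FlankRecord, ParseError,
                               extract_cas2_flank, extract_opposite_flank,
                               find_first_repeat15, parse_array, trim_and_filter)
from crisprterm.io import revcomp

from conftest import random_seq


def brute_force_first_repeat15(seq, k=15):
    """O(L^2) all-pairs oracle for the first recurring 15-mer."""
    seq = seq.upper()
    best = None
    for p in range(len(seq) - k + 1):
        kp = seq[p:p + k]
        if "N" in kp:
            continue
        for q in range(p + 1, len(seq) - k + 1):
            if seq[q:q + k] == kp:
                best = p if best is None else min(best, p)
                break
    return best


class TestExtractCas2Flank:
    def test_plus_strand_is_downstream_slice(self, rng):
        genome = random_seq(rng, 1000)
        f = extract_cas2_flank(genome, 100, 400, "+", length=300)
        assert f.raw == genome[400:700]
        assert not f.truncated

    def test_minus_strand_is_revcomp_of_upstream(self, rng):
        genome = random_seq(rng, 1000)
        f = extract_cas2_flank(genome, 500, 800, "-", length=300)
        assert f.raw == revcomp(genome[200:500])

    def test_truncated_at_contig_end(self, rng):
        genome = random_seq(rng, 500)
        f = extract_cas2_flank(genome, 100, 400, "+", length=300)
        assert len(f.raw) == 100
        assert f.truncated

    def test_interval_outside_contig(self, rng):
        with pytest.raises(CoordinateError):
            extract_cas2_flank(random_seq(rng, 100), 50, 150, "+")


class TestFindFirstRepeat15:
    def test_constructed_pair_at_100_and_130(self, rng):
        while True:
            r = random_seq(rng, 15)
            seq = (random_seq(rng, 100) + r + random_seq(rng, 15) + r
                   + random_seq(rng, 50))
            if brute_force_first_repeat15(seq) == 100:  # no chance earlier repeat
                break
        assert find_first_repeat15(seq) == 100

    def test_tandem_repeat_at_zero(self, rng):
        r = random_seq(rng, 15)
        assert find_first_repeat15(r + r) == 0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(30, 500))
            seq = random_seq(rng, n)
            if rng.random() < 0.5:  # force repeats into half the cases
                r = random_seq(rng, 15)
                p, q = sorted(rng.integers(0, max(n - 15, 1), size=2))
                seq = seq[:p] + r + seq[p + 15:q] + r + seq[q + 15:]
            assert find_first_repeat15(seq) == brute_force_first_repeat15(seq)

    def test_none_for_all_distinct_kmers(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 60)
            if brute_force_first_repeat15(seq) is None:
                assert find_first_repeat15(seq) is None
                return
        pytest.fail("could not draw a repeat-free 60-mer")

    def test_n_containing_kmers_never_match(self):
        seq = "A" * 14 + "N" + "A" * 14 + "N"  # every 15-mer contains the N
        assert find_first_repeat15(seq) is None


class TestTrimAndFilter:
    def make(self, raw):
        return FlankRecord(genus="g", source_id="x", raw=raw)

    def test_repeat_at_120_kept(self, rng):
        while True:
            r = random_seq(rng, 15)
            raw = random_seq(rng, 120) + r + random_seq(rng, 30) + r
            if brute_force_first_repeat15(raw) == 120:
                break
        f = trim_and_filter(self.make(raw))
        assert f.status == "kept"
        assert len(f.trimmed) == 120
        assert raw.startswith(f.trimmed)

    def test_repeat_at_10_too_short(self, rng):
        r = random_seq(rng, 15)
        f = trim_and_filter(self.make(random_seq(rng, 10) + r + r))
        assert f.status == "too_short"

    def test_no_repeat_discarded(self, rng):
        for _ in range(20):
            raw = random_seq(rng, 120)
            if brute_force_first_repeat15(raw) is None:
                f = trim_and_filter(self.make(raw))
                assert f.status == "no_repeat"
                return
        pytest.fail("could not draw a repeat-free flank")

    def test_trimming_kept_flank_is_idempotent(self, rng):
        while True:
            r = random_seq(rng, 15)
            raw = random_seq(rng, 60) + r + random_seq(rng, 20) + r
            f = trim_and_filter(self.make(raw))
            if f.status == "kept" and len(f.trimmed) == 60:
                break
        again = trim_and_filter(FlankRecord("g", "x", raw=f.trimmed))
        assert again.status == "no_repeat"  # second copy was trimmed away


class TestParseArray:
    def test_direct_construction(self, rng):
        r = random_seq(rng, 29)
        s1, s2 = random_seq(rng, 32), random_seq(rng, 32)
        arr = parse_array(r + s1 + r + s2 + r, r)
        assert [sp.seq for sp in arr.spacers] == [s1, s2]
        assert [sp.index for sp in arr.spacers] == [1, 2]

    def test_single_occurrence_is_error(self, rng):
        r = random_seq(rng, 29)
        with pytest.raises(ParseError):
            parse_array(r + random_seq(rng, 50), r)

    def test_roundtrip_with_simulator(self, small_genome, small_config):
        genome, truth = small_genome
        for arr in truth.arrays:
            start = arr.leader[0]
            end = arr.spacers[-1].end + len(arr.repeat_seq)
            parsed = parse_array(genome[start:end], arr.repeat_seq,
                                 offset=start)
            assert [s.seq for s in parsed.spacers] == [s.seq for s in arr.spacers]
            assert [(s.start, s.end) for s in parsed.spacers] == \
                   [(s.start, s.end) for s in arr.spacers]


class TestExtractOppositeFlank:
    def test_coordinate_identity(self, rng):
        genome = random_seq(rng, 2000)
        seq, trunc = extract_opposite_flank(genome, 1000, 1500, "+")
        assert seq == revcomp(genome[1500:1800])
        assert not trunc

    def test_involution(self, rng):
        genome = random_seq(rng, 2000)
        seq, _ = extract_opposite_flank(genome, 1000, 1500, "+")
        assert revcomp(seq) == genome[1500:1800]

    def test_truncated_at_contig_end(self, rng):
        genome = random_seq(rng, 1600)
        seq, trunc = extract_opposite_flank(genome, 1000, 1500, "+")
        assert len(seq) == 100
        assert trunc
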