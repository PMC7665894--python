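"""Seed+PAM matching and unique assignment of peaks to spacers."""

import numpy as np
import pytest

from crisprterm.assignment import (PAM_SEED5, SEED5_78, assign,
                                   assignment_summary, build_regions,
                                   collapse_duplicate_spacers, find_matches)
from crisprterm.io import revcomp
from crisprterm.workflows import brute_force_matches, matcher_oracle_check

from conftest import random_seq


class TestBuildRegions:
    def test_single_peak(self):
        (pk,) = build_regions([500])
        assert pk.region == (450, 551)
        assert pk.center == 500

    def test_merge_overlapping(self):
        (pk,) = build_regions([100, 150])
        assert pk.region == (50, 201)
        assert pk.center == 125
        assert pk.positions == [100, 150]

    def test_disjoint_peaks_stay_separate(self):
        peaks = build_regions([100, 300])
        assert len(peaks) == 2
        assert [p.center for p in peaks] == [100, 300]

    def test_clipping_at_contig_bounds(self):
        (pk,) = build_regions([10], contig_length=400)
        assert pk.region == (0, 61)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            build_regions([100], width=100)


class TestFindMatches:
    SPACER = "GCTAACGTTA"

    def test_pam_seed_hit(self):
        region = "TTTTT" + "AAG" + "GCTAA" + "TTTTTTT"
        hits = find_matches(region, {"sp": self.SPACER})
        assert any(h.mode == PAM_SEED5 and h.pam == "AAG" and h.strand == "+"
                   for h in hits)

    def test_seed78_hit_without_pam(self):
        # seed GCTAA + any position 6 + positions 7-8 = GT
        region = "TT" + "GCTAA" + "A" + "GT" + "CCCCC"
        hits = find_matches(region, {"sp": self.SPACER})
        assert any(h.mode == SEED5_78 and h.pam == "" for h in hits)

    def test_minus_strand_hit(self):
        region = "CCCC" + revcomp("AAGGCTAA") + "CCCC"
        hits = find_matches(region, {"sp": self.SPACER})
        assert any(h.strand == "-" and h.mode == PAM_SEED5 for h in hits)

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError):
            find_matches("ACGTACGTACGT", {"sp": "ACGTACG"})

    def test_n_in_region_never_matches(self):
        region = "TT" + "AAG" + "GCTAN" + "TTTT"
        assert find_matches(region, {"sp": self.SPACER}) == []

    def test_equals_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            region = random_seq(rng, 150)
            spacers = {f"s{j}": random_seq(rng, 32) for j in range(3)}
            assert set(find_matches(region, spacers)) == \
                brute_force_matches(region, spacers)

    def test_oracle_workflow_full_agreement(self):
        res = matcher_oracle_check(n_instances=150, seed=5)
        assert res["agreement_fraction"] == 1.0
        assert res["mean_hits_per_instance"] > 0.5  # instances are not vacuous

    def test_strand_symmetry(self, rng):
        for _ in range(20):
            region = random_seq(rng, 120)
            spacers = {f"s{j}": random_seq(rng, 32) for j in range(3)}
            fwd = find_matches(region, spacers)
            rev = find_matches(revcomp(region), spacers)
            flip = {"+": "-", "-": "+"}
            assert {(h.spacer_id, flip[h.strand], h.offset, h.mode) for h in fwd} \
                == {(h.spacer_id, h.strand, h.offset, h.mode) for h in rev}


class TestAssign:
    def _peak(self, seq):
        peaks = build_regions([len(seq) // 2], width=101,
                              contig_length=len(seq))
        peaks[0].seq = seq
        return peaks

    def test_single_hit_is_unique(self, rng):
        sp = random_seq(rng, 32)
        seq = random_seq(rng, 40) + "AAG" + sp + random_seq(rng, 30)
        peaks = self._peak(seq)
        assign(peaks, {"a": sp})
        assert peaks[0].status == "unique"
        assert peaks[0].assigned_spacer == "a"
        assert peaks[0].provenance == "direct_unique"

    def test_two_distinct_spacers_are_ambiguous(self, rng):
        s1, s2 = random_seq(rng, 32), random_seq(rng, 32)
        seq = ("AAG" + s1[:5] + random_seq(rng, 20)
               + "ATG" + s2[:5] + random_seq(rng, 40))
        peaks = self._peak(seq)
        assign(peaks, {"a": s1, "b": s2})
        assert peaks[0].status == "ambiguous"
        assert peaks[0].candidates == {"a", "b"}

    def test_no_hit_is_unassigned(self, rng):
        peaks = self._peak("T" * 101)
        assign(peaks, {"a": random_seq(rng, 32).replace("T", "A")})
        assert peaks[0].status == "unassigned"

    def test_duplicate_spacers_collapse_to_one_identity(self, rng):
        sp = random_seq(rng, 32)
        seq = random_seq(rng, 40) + "AAG" + sp + random_seq(rng, 30)
        peaks = self._peak(seq)
        assign(peaks, {"10": sp, "26": sp})
        assert peaks[0].status == "unique"
        assert peaks[0].assigned_spacer == "10/26"

    def test_order_independence(self, rng):
        spacers = {f"s{j}": random_seq(rng, 32) for j in range(4)}
        seq = random_seq(rng, 200)
        p1 = self._peak(seq)
        assign(p1, spacers)
        p2 = self._peak(seq)
        assign(p2, dict(reversed(list(spacers.items()))))
        assert p1[0].status == p2[0].status
        assert p1[0].candidates == p2[0].candidates

    def test_collapse_helper(self):
        collapsed, alias = collapse_duplicate_spacers(
            {"x": "ACGTACGTAC", "y": "ACGTACGTAC", "z": "TTTTACGTAC"})
        assert collapsed == {"x/y": "ACGTACGTAC", "z": "TTTTACGTAC"}
        assert alias["y"] == "x/y"


class TestSyntheticRoundTrip:
    def test_all_planted_sites_unique_and_correct(self, small_genome):
        genome, truth = small_genome
        centers = ((truth.sites["start"] + truth.sites["end"]) // 2).tolist()
        peaks = build_regions(centers, contig_length=len(genome), chrom="chr")
        for pk in peaks:
            pk.seq = genome[pk.region[0]:pk.region[1]]
        assign(peaks, truth.spacers)
        truth_map = dict(zip(centers, truth.sites["spacer_id"]))
        summary = assignment_summary(peaks)
        assert summary["unique"] == summary["total_peaks"] == len(truth.sites)
        for pk in peaks:
            assert pk.assigned_spacer == truth_map[pk.positions[0]]
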