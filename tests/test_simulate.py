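"""Synthetic-data generator: determinism, construction identities, and
statistical behaviour of the termination/coverage/conjugation models."""

import numpy as np
import pandas as pd
import pytest

from crisprterm import (ArraySpec, SimulationConfig, TerminationModel,
                        make_cas2_flank_set, make_crispr_genome,
                        simulate_chip_coverage, simulate_conjugation_counts,
                        simulate_crrna_abundance, step_hazard)
from crisprterm.arrays import find_first_repeat15, trim_and_filter, FlankRecord
from crisprterm.conjugation import count_reads, select_tags
from crisprterm.io import revcomp
from crisprterm.simulate import make_reads_from_counts


class TestMakeCrisprGenome:
    def test_deterministic_under_seed(self, small_config, small_genome):
        genome2, truth2 = make_crispr_genome(small_config)
        genome1, truth1 = small_genome
        assert genome1 == genome2
        pd.testing.assert_frame_equal(truth1.sites, truth2.sites)

    def test_no_offtargets_leaves_empty_site_table(self):
        cfg = SimulationConfig(seed=3, genome_length=12_000,
                               arrays=[ArraySpec("A", 3), ArraySpec("B", 3)],
                               offtargets_per_spacer=0)
        genome, truth = make_crispr_genome(cfg)
        assert truth.sites.empty
        assert len(truth.arrays) == 2
        for arr in truth.arrays:
            assert genome.count(arr.repeat_seq) >= arr.n_spacers + 1

    def test_every_site_reconstructs_from_genome(self, small_genome):
        genome, truth = small_genome
        assert len(truth.sites) == 2 * 6 * 2
        for row in truth.sites.itertuples(index=False):
            piece = genome[row.start:row.end]
            expected = row.seq if row.strand == "+" else revcomp(row.seq)
            assert piece == expected
            # construct = PAM + protospacer with exact seed
            assert row.seq[:3] == row.pam
            assert row.seq[3:8] == truth.spacers[row.spacer_id][:5]

    def test_arrays_contain_boxa_at_planted_interval(self, small_genome):
        genome, truth = small_genome
        for arr in truth.arrays:
            s, e = arr.boxa
            assert genome[s:e] == arr.boxa_seq

    def test_capacity_error_when_genome_too_small(self):
        cfg = SimulationConfig(seed=0, genome_length=5_000)
        with pytest.raises(Exception, match="genome_length"):
            make_crispr_genome(cfg)


class TestCrrnaAbundance:
    def test_no_termination_keeps_abundance_flat(self):
        ab = simulate_crrna_abundance(6, TerminationModel(rho_per_spacer=0.0))
        assert np.allclose(ab, 1.0)

    def test_absorbing_termination_zeroes_downstream(self):
        rho = np.zeros(5)
        rho[2] = 1.0  # interval after spacer 3
        ab = simulate_crrna_abundance(
            6, TerminationModel(rho_per_spacer=rho, boxA_intact=False))
        assert np.allclose(ab[:3], 1.0)
        assert np.allclose(ab[3:], 0.0)

    def test_constant_hazard_closed_form(self):
        ab = simulate_crrna_abundance(
            8, TerminationModel(rho_per_spacer=0.1, boxA_intact=False))
        assert np.allclose(ab, 0.9 ** np.arange(8))

    def test_boxa_protection_uses_protected_hazard(self):
        m = TerminationModel(rho_per_spacer=0.3, rho_protected=0.05,
                             boxA_intact=True)
        ab = simulate_crrna_abundance(5, m)
        assert np.allclose(ab, 0.95 ** np.arange(5))

    def test_internal_promoter_adds_propagated_initiation(self):
        m = TerminationModel(rho_per_spacer=0.1, boxA_intact=False,
                             internal_promoter_at=3, promoter_strength=0.5)
        ab = simulate_crrna_abundance(5, m)
        base = 0.9 ** np.arange(5)
        extra = np.array([0, 0, 0.5, 0.5 * 0.9, 0.5 * 0.81])
        assert np.allclose(ab, base + extra)

    def test_monotone_without_internal_promoter(self, rng):
        for _ in range(20):
            rho = rng.uniform(0, 1, size=9)
            ab = simulate_crrna_abundance(
                10, TerminationModel(rho_per_spacer=rho, boxA_intact=False))
            assert np.all(np.diff(ab) <= 1e-12)

    def test_step_hazard_shape(self):
        rho = step_hazard(23, 8, 0.02, 0.15)
        assert len(rho) == 22
        assert np.allclose(rho[:7], 0.02)
        assert np.allclose(rho[7:], 0.15)


class TestChipCoverage:
    def test_noiseless_proportionality(self, small_genome):
        genome, truth = small_genome
        two = truth.sites.iloc[[0, 2]]  # sites of two different spacers
        assert two.iloc[0]["spacer_id"] != two.iloc[1]["spacer_id"]
        ab = {two.iloc[0]["spacer_id"]: 0.8, two.iloc[1]["spacer_id"]: 0.2}
        cov = simulate_chip_coverage(len(genome), two, ab, depth=100, seed=0,
                                     noise="none", background_rate=0.0)
        c0 = (two.iloc[0]["start"] + two.iloc[0]["end"]) // 2
        c1 = (two.iloc[1]["start"] + two.iloc[1]["end"]) // 2
        assert cov["+"][c0] / cov["+"][c1] == pytest.approx(4.0)
        assert np.array_equal(cov["+"], cov["-"])

    def test_poisson_site_mean_within_3_se(self, small_genome):
        genome, truth = small_genome
        ab = {sid: 1.0 for sid in truth.spacers}
        depth = 200.0
        cov = simulate_chip_coverage(len(genome), truth.sites, ab, depth=depth,
                                     seed=42, background_rate=1.0)
        centers = ((truth.sites["start"] + truth.sites["end"]) // 2).to_numpy()
        vals = cov["+"][centers]
        mu = depth + 1.0
        se = np.sqrt(mu / len(vals))
        assert abs(vals.mean() - mu) < 3 * se

    def test_deterministic_under_seed(self, small_genome):
        genome, truth = small_genome
        ab = {sid: 1.0 for sid in truth.spacers}
        a = simulate_chip_coverage(len(genome), truth.sites, ab, 50, seed=7)
        b = simulate_chip_coverage(len(genome), truth.sites, ab, 50, seed=7)
        assert np.array_equal(a["+"], b["+"]) and np.array_equal(a["-"], b["-"])


class TestConjugationCounts:
    def _setup(self, effs):
        pool = {k: 1.0 for k in effs} | {"control": 1.0}
        samples = {"dcascade": {k: 1.0 for k in pool},
                   "wt": {**effs, "control": 1.0}}
        return pool, samples

    def test_counts_sum_to_depth(self):
        pool, samples = self._setup({"a": 0.5, "b": 0.1})
        counts = simulate_conjugation_counts(pool, samples, depth=1000, seed=1)
        sums = counts.groupby(["sample", "replicate"])["count"].sum()
        assert (sums == 1000).all()

    def test_full_interference_suppresses_counts(self):
        pool, samples = self._setup({"a": 0.0, "b": 1.0})
        counts = simulate_conjugation_counts(pool, samples, depth=30_000, seed=2)
        a_wt = counts.query("plasmid=='a' and sample=='wt'")["count"]
        assert (a_wt == 0).all()

    def test_efficiency_recovery_20pct(self):
        """Planted efficiency 0.2 recovered within 2% over 20 seeds."""
        from crisprterm.conjugation import filter_low, normalize_efficiency
        rec = []
        for seed in range(20):
            pool, samples = self._setup({"a": 0.2, "b": 1.0})
            counts = simulate_conjugation_counts(pool, samples,
                                                 depth=100_000, seed=seed)
            kept, _ = filter_low(counts)
            eff = normalize_efficiency(kept)
            rec.append(eff.query("plasmid=='a'")["efficiency_pct"].mean())
        assert abs(np.mean(rec) - 20.0) < 2.0

    def test_reads_roundtrip_reproduces_counts_exactly(self, rng):
        from conftest import random_seq
        protos = {f"p{i}": random_seq(rng, 32) for i in range(4)}
        pool = {k: 1.0 for k in protos} | {"control": 1.0}
        samples = {"dcascade": {k: 1.0 for k in pool}}
        counts = simulate_conjugation_counts(pool, samples, depth=2000, seed=9,
                                             n_replicates=1)
        refs = select_tags(protos)
        reads = make_reads_from_counts(
            counts[counts["plasmid"] != "control"], protos, seed=10)
        got, stats = count_reads(reads[("dcascade", 1)], refs)
        want = dict(counts[counts["plasmid"] != "control"]
                    .set_index("plasmid")["count"])
        assert got == want
        assert stats == {"no_tag": 0, "multi_tag": 0}


class TestCas2FlankSet:
    def test_exact_planting_count(self):
        _, truth = make_cas2_flank_set(187, "TGCTCTTTAACA", 52 / 187, seed=0)
        assert (truth["motif_offset"] >= 0).sum() == 52

    def test_zero_planting_fraction(self):
        records, truth = make_cas2_flank_set(30, "TGCTCTTTAACA", 0.0, seed=1)
        assert (truth["motif_offset"] >= 0).sum() == 0
        n_with = sum("TGCTCTTTAACA" in s for _, _, s in records)
        assert n_with <= 1  # at most chance occurrence

    def test_trim_recovers_planted_repeat_offset(self):
        records, truth = make_cas2_flank_set(20, "TGCTCTTTAACA", 0.5, seed=2)
        offsets = dict(zip(truth["source_id"], truth["repeat_offset"]))
        for sid, genus, seq in records:
            f = trim_and_filter(FlankRecord(genus, sid, raw=seq))
            assert f.status == "kept"
            assert len(f.trimmed) == offsets[sid]

    def test_motif_planted_upstream_of_repeat(self):
        records, truth = make_cas2_flank_set(50, "TGCTCTTTAACA", 0.4, seed=3)
        seqs = {sid: s for sid, _, s in records}
        for row in truth.itertuples(index=False):
            if row.motif_offset >= 0:
                assert seqs[row.source_id][row.motif_offset:
                                           row.motif_offset + 12] == "TGCTCTTTAACA"
                assert row.motif_offset + 12 <= row.repeat_offset
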