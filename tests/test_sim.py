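"""Simulator unit and property tests: genome layout, bias field, planted
truths, read placement statistics and allele-count expectations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

import gametecnv as g
from gametecnv.sim import ROLE_BASELINES


class TestMakeGenome:
    def test_centromere_width_and_position(self):
        layout = g.make_genome([("chr1", 100_000_000)],
                               centromere_fraction=0.02, seed=3)
        cs, ce = layout.centromeres["chr1"]
        assert ce - cs == 2_000_000
        # midpoint drawn from the middle half
        assert 25_000_000 - 1_000_000 <= cs and ce <= 75_000_000 + 1_000_000

    def test_deterministic_given_seed(self):
        spec = [("chr1", 50_000_000), ("chr2", 30_000_000)]
        assert g.make_genome(spec, seed=7) == g.make_genome(spec, seed=7)

    def test_invariants_on_ten_chromosomes(self, rng):
        lengths = rng.integers(30_000_000, 60_000_000, size=10)
        spec = [(f"chr{i}", int(l)) for i, l in enumerate(lengths, 1)]
        layout = g.make_genome(spec, centromere_fraction=0.03, seed=5)
        assert len(layout.centromeres) == 10
        for name, length in layout.chromosomes:
            cs, ce = layout.centromeres[name]
            assert 0 < cs < ce < length

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            g.make_genome([("chr1", 0)])


class TestBiasField:
    def test_sigma_zero_is_uniform(self, small_genome):
        field = g.simulate_bias_field(small_genome, sigma=0.0, seed=0)
        for mult in field.multipliers.values():
            assert np.allclose(mult, 1.0)

    def test_mean_one_and_reproducible(self, small_genome):
        f1 = g.simulate_bias_field(small_genome, sigma=0.5, seed=9)
        f2 = g.simulate_bias_field(small_genome, sigma=0.5, seed=9)
        assert abs(f1.mean_multiplier() - 1.0) < 1e-9
        for c in f1.multipliers:
            assert np.array_equal(f1.multipliers[c], f2.multipliers[c])
        assert all((m > 0).all() for m in f1.multipliers.values())

    def test_different_seeds_differ(self, small_genome):
        f1 = g.simulate_bias_field(small_genome, sigma=0.5, seed=1)
        f2 = g.simulate_bias_field(small_genome, sigma=0.5, seed=2)
        assert any(not np.array_equal(f1.multipliers[c], f2.multipliers[c])
                   for c in f1.multipliers)


class TestPlantPollenTruth:
    def test_type_I_complementary_pair(self, genome):
        scenario = [[{"type": "I", "length": 20_000_000, "chrom": "chr2",
                      "sperm": 0}]]
        trophic, s1, s2 = g.plant_pollen_truth(genome, scenario, seed=0)
        assert trophic.events == []
        (e1,), (e2,) = s1.events, s2.events
        assert (e1.chrom, e1.start, e1.end) == (e2.chrom, e2.start, e2.end)
        assert e1.end - e1.start == 20_000_000
        mid = (e1.start + e1.end) // 2
        assert sum(s1.copies_at("chr2", mid)) == 0
        assert sum(s2.copies_at("chr2", mid)) == 2
        assert sum(trophic.copies_at("chr2", mid)) == 1

    def test_empty_scenario_all_euploid(self, genome):
        profiles = g.plant_pollen_truth(genome, [[]], seed=0)
        assert all(not p.events for p in profiles)

    def test_type_III_on_every_chromosome(self, genome):
        scenario = [[{"type": "III", "length": 5_000_000, "chrom": c}
                     for c in genome.names]]
        _, s1, s2 = g.plant_pollen_truth(genome, scenario, seed=0)
        for sperm in (s1, s2):
            assert {e.chrom for e in sperm.events} == set(genome.names)
            assert all(sum(sperm.copies_at(e.chrom, e.start)) == 0
                       for e in sperm.events)

    def test_event_longer_than_chromosome_rejected(self, small_genome):
        with pytest.raises(ValueError):
            g.plant_pollen_truth(
                small_genome,
                [[{"type": "II", "length": 10**9, "chrom": "chr1"}]], seed=0)


class TestPlantKernelTruth:
    def test_classI_incomplete_retains_listed_fragments(self, genome):
        retained = [("chr1", 5_000_000, 25_000_000), ("chr7", 0, 15_000_000),
                    ("chr8", 10_000_000, 28_000_000), ("chr9", 0, 20_000_000)]
        scenario = [{"embryo": {"class": "classI_incomplete",
                                "retained": retained}}]
        embryo, endosperm = g.plant_kernel_truth(genome, scenario, seed=0)
        for chrom, s, e in retained:
            assert embryo.copies_at(chrom, (s + e) // 2) == (1, 1)
        assert embryo.copies_at("chr1", 1_000_000) == (1, 0)
        assert embryo.copies_at("chr2", 1_000_000) == (1, 0)
        assert endosperm.events == []

    def test_euploid_baselines(self, genome):
        embryo, endosperm = g.plant_kernel_truth(genome, [{}], seed=0)
        assert (embryo.baseline_maternal, embryo.baseline_paternal) == (1, 1)
        assert (endosperm.baseline_maternal,
                endosperm.baseline_paternal) == (2, 1)

    def test_classII_maternal_endosperm(self, genome):
        scenario = [{"endosperm": {"class": "classII", "parent": "maternal",
                                   "chrom": "chr4", "start": 1_000_000,
                                   "end": 21_000_000}}]
        _, endosperm = g.plant_kernel_truth(genome, scenario, seed=0)
        assert endosperm.copies_at("chr4", 10_000_000) == (1, 1)
        assert endosperm.copies_at("chr4", 22_000_000) == (2, 1)

    def test_retained_fragment_outside_genome_rejected(self, small_genome):
        with pytest.raises(ValueError):
            g.plant_kernel_truth(
                small_genome,
                [{"embryo": {"class": "classI_incomplete",
                             "retained": [("chr1", 0, 10**9)]}}], seed=0)


class TestSimulateReads:
    def test_exact_read_count_and_bounds(self, small_genome):
        bias = g.simulate_bias_field(small_genome, sigma=0.2, seed=0)
        truth = g.TruthProfile("s", "sperm", 1, 0)
        reads = g.simulate_reads(truth, bias, n_reads=10, seed=0)
        assert len(reads) == 10
        for r in reads.itertuples():
            assert 0 <= r.start < r.end <= small_genome.length(r.chrom)

    def test_no_reads_in_copy_zero_interval(self, small_genome):
        bias = g.simulate_bias_field(small_genome, sigma=0.0, seed=0)
        truth = g.TruthProfile("s", "sperm", 1, 0, [
            g.sim.TruthEvent("chr1", 2_000_000, 6_000_000, -1, 0)])
        reads = g.simulate_reads(truth, bias, n_reads=50_000, seed=1)
        on = reads[(reads.chrom == "chr1") & (reads.start >= 2_000_000)
                   & (reads.start < 6_000_000)]
        assert len(on) == 0

    def test_uniform_counts_pass_goodness_of_fit(self, small_genome):
        """Euploid, no bias, no overdispersion: per-window counts are
        multinomial-uniform, so a chi-square GOF rejects at alpha=0.01 in
        at most ~1% of replicates (we allow 2 of 20)."""
        bias = g.simulate_bias_field(small_genome, sigma=0.0, seed=0)
        truth = g.TruthProfile("s", "sperm", 1, 0)
        passed = 0
        for rep in range(20):
            reads = g.simulate_reads(truth, bias, n_reads=20_000,
                                     mapq_model=(0.0, 5, 42), seed=100 + rep)
            sub = reads[reads.chrom == "chr1"]
            counts, _ = np.histogram(sub.start, bins=20,
                                     range=(0, small_genome.length("chr1")))
            _, p = chisquare(counts)
            passed += p > 0.01
        assert passed >= 18

    def test_all_zero_truth_rejected(self, small_genome):
        bias = g.simulate_bias_field(small_genome, sigma=0.0, seed=0)
        truth = g.TruthProfile("s", "sperm", 1, 0, [
            g.sim.TruthEvent(c, 0, small_genome.length(c), -1, 0)
            for c in small_genome.names])
        with pytest.raises(ValueError, match="copy 0"):
            g.simulate_reads(truth, bias, n_reads=100, seed=0)


class TestAlleleCounts:
    @pytest.mark.parametrize("role,expected", [("embryo", 0.5),
                                               ("endosperm", 2 / 3)])
    def test_euploid_allele_fraction(self, genome, role, expected):
        panel = g.make_snp_panel(genome, 50_000, seed=0)
        bm, bp = ROLE_BASELINES[role]
        truth = g.TruthProfile("k", role, bm, bp)
        counts = g.simulate_allele_counts(truth, panel, mean_depth=1.0, seed=2)
        frac = counts.maternal_count.sum() / (
            counts.maternal_count.sum() + counts.paternal_count.sum())
        assert abs(frac - expected) < 0.01

    def test_classI_complete_has_no_paternal_reads(self, genome):
        scenario = [{"embryo": {"class": "classI_complete"}}]
        embryo, _ = g.plant_kernel_truth(genome, scenario, seed=0)
        panel = g.make_snp_panel(genome, 5_000, seed=0)
        counts = g.simulate_allele_counts(embryo, panel, mean_depth=1.0, seed=3)
        assert counts.paternal_count.sum() == 0
        assert counts.maternal_count.sum() > 0

    def test_empty_panel_rejected(self, genome):
        truth = g.TruthProfile("k", "embryo", 1, 1)
        with pytest.raises(ValueError):
            g.simulate_allele_counts(truth, pd.DataFrame(
                columns=["chrom", "pos", "maternal", "paternal"]), seed=0)


class TestSimulateCohort:
    CFG = {
        "genome": {"lengths": [10_000_000, 8_000_000]},
        "reads_per_nucleus": 5_000,
        "event_length_range": [2_000_000, 4_000_000],
        "lines": [{"name": "L1", "group": "inducer", "n_pollen": 2,
                   "nuclei_per_pollen": 3, "one_aneuploid": 1,
                   "two_aneuploid": 0}],
    }

    def test_byte_identical_given_seed(self, tmp_path):
        g.simulate_cohort(self.CFG, tmp_path / "a", seed=4)
        g.simulate_cohort(self.CFG, tmp_path / "b", seed=4)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes()

    def test_zero_rate_manifest_has_no_events(self, tmp_path):
        cfg = dict(self.CFG)
        cfg["lines"] = [{"name": "L1", "group": "regular", "n_pollen": 2,
                         "nuclei_per_pollen": 2, "one_aneuploid": 0,
                         "two_aneuploid": 0}]
        g.simulate_cohort(cfg, tmp_path / "c", seed=0)
        manifest = pd.read_csv(tmp_path / "c" / "truth_manifest.tsv", sep="\t")
        assert (manifest["chrom"] == ".").all()

    def test_truth_events_round_trip_manifest(self, tmp_path):
        g.simulate_cohort(self.CFG, tmp_path / "d", seed=4)
        _, _, _, truths = g.simulate_pollen_cohort(self.CFG, seed=4)
        manifest = pd.read_csv(tmp_path / "d" / "truth_manifest.tsv", sep="\t")
        planted = {(sid, e.chrom, e.start, e.end, e.maternal_delta)
                   for sid, t in truths.items() for e in t.events}
        written = {(r.sample_id, r.chrom, r.start, r.end, r.maternal_delta)
                   for r in manifest.itertuples() if r.chrom != "."}
        assert planted == written
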