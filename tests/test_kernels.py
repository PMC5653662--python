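"""SNP binning, ratio/RGR arithmetic and kernel class recovery."""

import numpy as np
import pandas as pd
import pytest

import gametecnv as g
import gametecnv.kernels as kn


def panel_on_one_chrom(n, spacing=1000, chrom="chr1"):
    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(n) * spacing,
        "maternal": "A",
        "paternal": "C",
    })


def counts_df(panel, maternal, paternal):
    return pd.DataFrame({
        "chrom": panel["chrom"], "pos": panel["pos"],
        "maternal_count": maternal, "paternal_count": paternal,
    })


class TestBuildSnpBins:
    def test_exact_division(self):
        scheme = kn.build_snp_bins(panel_on_one_chrom(2100), k=700)
        assert len(scheme) == 3
        assert scheme.bins["n_snps"].tolist() == [700, 700, 700]

    def test_short_final_bin(self):
        scheme = kn.build_snp_bins(panel_on_one_chrom(2099), k=700)
        assert scheme.bins["n_snps"].tolist() == [700, 700, 699]

    def test_k_one_gives_one_bin_per_snp(self):
        scheme = kn.build_snp_bins(panel_on_one_chrom(5), k=1)
        assert len(scheme) == 5

    def test_span_is_half_open(self):
        scheme = kn.build_snp_bins(panel_on_one_chrom(10, spacing=100), k=5)
        assert scheme.bins.iloc[0][["start", "end"]].tolist() == [0, 401]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            kn.build_snp_bins(panel_on_one_chrom(0), k=700)


class TestSnpRatio:
    def test_balanced_bin_is_half(self):
        panel = panel_on_one_chrom(100)
        scheme = kn.build_snp_bins(panel, k=100)
        track = kn.snp_ratio(counts_df(panel, 30, 30), scheme, min_reads=10)
        assert track.ratio[0] == pytest.approx(0.5)

    def test_two_to_one_bin(self):
        panel = panel_on_one_chrom(60)
        scheme = kn.build_snp_bins(panel, k=60)
        maternal = np.zeros(60, dtype=int)
        paternal = np.zeros(60, dtype=int)
        maternal[:40] = 1
        paternal[40:60] = 1
        track = kn.snp_ratio(counts_df(panel, maternal, paternal), scheme,
                             min_reads=10)
        assert track.ratio[0] == pytest.approx(2 / 3)

    def test_low_coverage_bin_masked(self):
        panel = panel_on_one_chrom(10)
        scheme = kn.build_snp_bins(panel, k=10)
        maternal = np.zeros(10, dtype=int)
        maternal[:3] = 1
        track = kn.snp_ratio(counts_df(panel, maternal, 0), scheme,
                             min_reads=10)
        assert track.masked[0]
        assert np.isnan(track.ratio[0])


class TestRGR:
    def make_tracks(self, ratios_by_sample, informative=1000):
        panel = panel_on_one_chrom(len(next(iter(ratios_by_sample.values()))) * 10)
        scheme = kn.build_snp_bins(panel, k=10)
        tracks = {}
        for sid, ratios in ratios_by_sample.items():
            r = np.asarray(ratios, dtype=float)
            tracks[sid] = kn.SNPRatioTrack(
                sid, r, np.full(len(r), informative),
                np.zeros(len(r), dtype=bool), scheme)
        return tracks

    def test_identical_samples_give_zero(self):
        tracks = self.make_tracks({"a": [0.5] * 4, "b": [0.5] * 4,
                                   "c": [0.5] * 4})
        profiles = kn.rgr_profile(tracks)
        for prof in profiles.values():
            assert np.allclose(prof.log2_rgr, 0.0)

    def test_haploid_maternal_sample_shifts_positive(self):
        """One fully-maternal sample among euploids: its ratio is 1, the
        cross-sample mean is (0.5 (n-1) + 1)/n, so its log2(RGR) equals
        log2(n / (0.5 n + 0.5)) > 0 genome-wide."""
        n = 5
        tracks = self.make_tracks(
            {f"e{i}": [0.5] * 6 for i in range(n - 1)} | {"hap": [1.0] * 6})
        profiles = kn.rgr_profile(tracks)
        expected = np.log2(1.0 / ((0.5 * (n - 1) + 1.0) / n))
        assert np.allclose(profiles["hap"].log2_rgr, expected)
        assert (profiles["hap"].log2_rgr > 0).all()

    def test_below_mean_sample_is_negative(self):
        tracks = self.make_tracks({"a": [0.4] * 4, "b": [0.6] * 4})
        profiles = kn.rgr_profile(tracks)
        assert (profiles["a"].log2_rgr < 0).all()
        assert (profiles["b"].log2_rgr > 0).all()

    def test_scale_free_in_depth(self, genome):
        """Multiplying every sample's depths by a constant leaves
        log2(RGR) unchanged."""
        panel = g.make_snp_panel(genome, 5000, seed=0)
        scheme = kn.build_snp_bins(panel, k=100)
        rng = np.random.default_rng(3)
        base = {}
        scaled = {}
        for sid in ("a", "b", "c"):
            depth = rng.poisson(4, size=len(panel)) + 1
            m = rng.binomial(depth, 0.5)
            c1 = counts_df(panel, m, depth - m)
            c5 = counts_df(panel, 5 * m, 5 * (depth - m))
            base[sid] = kn.snp_ratio(c1, scheme, min_reads=1, sample_id=sid)
            scaled[sid] = kn.snp_ratio(c5, scheme, min_reads=1, sample_id=sid)
        p1 = kn.rgr_profile(base)
        p5 = kn.rgr_profile(scaled)
        for sid in base:
            np.testing.assert_allclose(p1[sid].log2_rgr, p5[sid].log2_rgr)

    def test_fully_masked_bin_stays_masked(self):
        tracks = self.make_tracks({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        for t in tracks.values():
            t.masked[1] = True
        profiles = kn.rgr_profile(tracks)
        assert all(p.masked[1] for p in profiles.values())

    def test_single_sample_rejected(self):
        tracks = self.make_tracks({"a": [0.5] * 4})
        with pytest.raises(ValueError):
            kn.rgr_profile(tracks)


@pytest.fixture(scope="module")
def cohort_result():
    scenario = [{} for _ in range(8)]
    scenario += [
        {"embryo": {"class": "classI_complete"}},
        {"embryo": {"class": "classI_incomplete",
                    "retained": [("chr1", 5_000_000, 25_000_000),
                                 ("chr7", 0, 15_000_000),
                                 ("chr8", 10_000_000, 28_000_000),
                                 ("chr9", 4_000_000, 20_000_000)]}},
        {"embryo": {"class": "classII", "parent": "paternal",
                    "length": 20_000_000}},
        {"endosperm": {"class": "classII", "parent": "maternal",
                       "length": 20_000_000}},
    ]
    sim = g.simulate_kernel_cohort(scenario, seed=21)
    genome, samples, placements, counts, truths, panel = sim
    res = g.run_kernel_pipeline(genome, samples, placements, counts, panel)
    return scenario, res


class TestKernelClassification:
    """End-to-end class recovery on a small simulated kernel cohort."""

    def test_planted_classes_recovered(self, cohort_result):
        scenario, res = cohort_result
        for i, kernel in enumerate(scenario):
            for tissue in ("embryo", "endosperm"):
                call = res.kernel_calls[f"kernel{i + 1:03d}_{tissue}"]
                spec = kernel.get(tissue, {"class": "euploid"})
                expected = spec.get("class", "euploid")
                if expected == "classII":
                    expected = f"classII_{spec.get('parent', 'paternal')}"
                assert call.cls == expected, (i, tissue)

    def test_classI_parent_is_paternal(self, cohort_result):
        _, res = cohort_result
        assert res.kernel_calls["kernel009_embryo"].eliminated_parent == \
            "paternal"

    def test_incomplete_elimination_recovers_four_fragments(self, cohort_result):
        scenario, res = cohort_result
        call = res.kernel_calls["kernel010_embryo"]
        assert call.cls == "classI_incomplete"
        assert len(call.retained_fragments) == 4
        planted = scenario[9]["embryo"]["retained"]
        for (pc, ps, pe) in planted:
            match = [f for f in call.retained_fragments if f[0] == pc]
            assert len(match) == 1
            _, s, e = match[0]
            inter = min(e, pe) - max(s, ps)
            union = max(e, pe) - min(s, ps)
            assert inter / union >= 0.8  # per-fragment Jaccard

    def test_report_counts_match_truth(self, cohort_result):
        _, res = cohort_result
        rep = res.report.set_index(["tissue", "class"])["count"]
        assert rep[("embryo", "classI_complete")] == 1
        assert rep[("embryo", "classI_incomplete")] == 1
        assert rep[("embryo", "classII_paternal")] == 1
        assert rep[("endosperm", "classII_maternal")] == 1
        assert rep[("embryo", "euploid")] == 9
        assert rep[("endosperm", "euploid")] == 11

    def test_maternal_loss_sign_convention(self, cohort_result):
        """A planted maternal loss drives log2(RGR) negative on the
        planted interval."""
        scenario, res = cohort_result
        prof = res.rgr["kernel012_endosperm"]
        call = res.kernel_calls["kernel012_endosperm"]
        seg = call.supporting_segments[0]
        bins = prof.scheme.bins
        on = ((bins["chrom"] == seg.chrom) & (bins["start"] < seg.end)
              & (bins["end"] > seg.start)).to_numpy() & ~prof.masked
        assert np.nanmean(prof.log2_rgr[on]) < 0


def test_tissue_baseline_mismatch_rejected(genome):
    from gametecnv.segment import NucleusCall

    cnv = NucleusCall("k", "embryo", 3, [], False, 0.0)
    panel = g.make_snp_panel(genome, 2000, seed=0)
    scheme = kn.build_snp_bins(panel, k=100)
    prof = kn.RGRProfile("k", np.full(len(scheme), 0.5),
                         np.full(len(scheme), 0.5),
                         np.zeros(len(scheme)),
                         np.full(len(scheme), 1000),
                         np.zeros(len(scheme), dtype=bool), scheme)
    with pytest.raises(ValueError, match="baseline"):
        kn.classify_kernel(cnv, prof, genome, "embryo", min_seg_bp=2_000_000)


def test_cohort_report_fraction_example():
    calls = ([kn.KernelCall(f"e{i}", "embryo", "classI_complete", "paternal")
              for i in range(8)]
             + [kn.KernelCall(f"u{i}", "embryo", "euploid")
                for i in range(73)])
    rep = kn.cohort_kernel_report(calls)
    row = rep[(rep.tissue == "embryo")
              & (rep["class"] == "classI_complete")].iloc[0]
    assert (row["count"], row.total) == (8, 81)
    assert row.fraction == pytest.approx(8 / 81)
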