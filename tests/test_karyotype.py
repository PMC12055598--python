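import numpy as np
import pytest

from leukopore.karyotype import (bin_depth, classify_aneuploidy, fit_karyotype,
                                 interpolated_median)
from leukopore.simulate import TruthModel, simulate_reads

from conftest import flat_profile, make_read, make_segment


class TestBinDepth:
    def test_read_center_assigns_bin(self, toy_g):
        read = make_read("r", [make_segment("chr1", 1_400_000, 1_600_000)])
        prof = bin_depth([read], toy_g, bin_size=1_000_000)
        assert prof.counts["chr1"][1] == 1      # center 1,500,000 -> bin 1
        assert prof.counts["chr1"].sum() == 1

    def test_three_reads_same_bin(self, toy_g):
        reads = [make_read(f"r{i}", [make_segment("chr2", 55_000 + i, 63_000 + i)])
                 for i in range(3)]
        prof = bin_depth(reads, toy_g, bin_size=10_000)
        assert prof.counts["chr2"][5] == 3

    def test_split_read_counts_once_via_longest_segment(self, toy_g):
        read = make_read("r", [
            make_segment("chr12", 100_000, 104_000, query_end=4000),
            make_segment("chr21", 200_000, 200_800, query_start=4000,
                         query_end=4800, primary=False)])
        prof = bin_depth([read], toy_g, bin_size=10_000)
        assert prof.counts["chr12"].sum() == 1
        assert prof.counts["chr21"].sum() == 0

    def test_centromere_and_truncated_bins_unusable(self, toy_g):
        prof = bin_depth([], toy_g, bin_size=10_000)
        cen = toy_g.centromere("chr1")
        assert not prof.usable["chr1"][cen[0] // 10_000]
        assert not prof.usable["chr1"][-1]      # truncated final bin

    def test_empty_input_all_zero(self, toy_g):
        prof = bin_depth([], toy_g, bin_size=10_000)
        assert prof.total_reads() == 0


class TestInterpolatedMedian:
    def test_matches_plain_median_on_untied_data(self):
        x = [1.5, 2.5, 9.25]
        assert interpolated_median(x) == pytest.approx(2.5)

    def test_continuous_on_tied_integers(self):
        # 4 values below 10, 6 at 10: grouped median sits inside [9.5, 10.5)
        x = [8, 9, 9, 9, 10, 10, 10, 10, 10, 10]
        v = interpolated_median(x)
        assert 9.5 < v < 10.5
        assert v == pytest.approx(9.5 + (5 - 4) / 6)


class TestFitKaryotype:
    def test_pure_tumor_two_three_ratio(self, toy_g, tcfg):
        vals = {c: 100 for c in toy_g.names}
        vals["chr21"] = 150
        vals["chrX"] = vals["chrY"] = 50
        call = fit_karyotype(flat_profile(toy_g, vals), toy_g, tcfg)
        assert call.copy_number["chr21"] == 3
        assert all(call.copy_number[c] == 2 for c in toy_g.autosomes
                   if c != "chr21")
        assert call.total_count == 47

    def test_pure_tumor_one_two_ratio_monosomy(self, toy_g, tcfg):
        vals = {c: 100 for c in toy_g.names}
        vals["chr7"] = 50
        vals["chrX"] = vals["chrY"] = 50
        call = fit_karyotype(flat_profile(toy_g, vals), toy_g, tcfg)
        assert call.copy_number["chr7"] == 1
        assert call.total_count == 45
        assert call.aneuploidy_class == "other_aneuploid"

    def test_euploid_male_no_aneuploidy(self, toy_g, tcfg):
        vals = {c: 100 for c in toy_g.names}
        vals["chrX"] = vals["chrY"] = 50
        call = fit_karyotype(flat_profile(toy_g, vals), toy_g, tcfg)
        assert call.total_count == 46
        assert call.sex == "XY"
        assert call.aneuploidy_class == "none"
        assert not call.arm_events

    def test_diluted_trisomy_recovers_blast_fraction(self, toy_g, tcfg):
        # f = 0.5: trisomic/diploid medians 125:100
        vals = {c: 100 for c in toy_g.names}
        vals["chr21"] = 125
        vals["chrX"] = vals["chrY"] = 50
        call = fit_karyotype(flat_profile(toy_g, vals), toy_g, tcfg)
        assert call.copy_number["chr21"] == 3
        assert abs(call.blast_fraction - 0.5) <= 0.05

    def test_scale_invariance(self, toy_g, tcfg):
        truth = TruthModel(genome=toy_g, blast_fraction=0.85,
                           copy_numbers={"chr4": 3, "chr21": 4},
                           sex="XY", read_count=60_000)
        reads, _ = simulate_reads(truth, seed=5)
        prof = bin_depth(reads, toy_g, bin_size=tcfg.bin_size)
        call = fit_karyotype(prof, toy_g, tcfg)
        scaled = flat_profile(toy_g, {}, tcfg.bin_size)
        scaled.counts = {c: v * 3 for c, v in prof.counts.items()}
        scaled.usable = prof.usable
        call3 = fit_karyotype(scaled, toy_g, tcfg)
        assert call3.copy_number == call.copy_number
        assert call3.sex == call.sex
        assert call3.aneuploidy_class == call.aneuploidy_class

    def test_masked_bins_never_contribute(self, toy_g, tcfg):
        truth = TruthModel(genome=toy_g, blast_fraction=0.85,
                           copy_numbers={"chr4": 3, "chr21": 4},
                           sex="XY", read_count=60_000)
        reads, _ = simulate_reads(truth, seed=6)
        prof = bin_depth(reads, toy_g, bin_size=tcfg.bin_size)
        call = fit_karyotype(prof, toy_g, tcfg)
        cen = toy_g.centromere("chr1")
        prof.counts["chr1"][cen[0] // tcfg.bin_size] = 10_000_000
        prof.counts["chr1"][-1] = 999_999
        call2 = fit_karyotype(prof, toy_g, tcfg)
        assert call2.copy_number == call.copy_number
        assert call2.total_count == call.total_count

    def test_degenerate_profile_raises(self, toy_g, tcfg):
        with pytest.raises(ValueError, match="no usable depth"):
            fit_karyotype(flat_profile(toy_g, {c: 0 for c in toy_g.names}),
                          toy_g, tcfg)

    def test_low_blast_fraction_flagged(self, toy_g, tcfg):
        # f = 0.2 trisomy: medians 110 vs 100
        vals = {c: 100 for c in toy_g.names}
        vals["chr21"] = 110
        vals["chrX"] = vals["chrY"] = 50
        call = fit_karyotype(flat_profile(toy_g, vals), toy_g, tcfg)
        if call.blast_fraction < tcfg.low_confidence_blast_fraction:
            assert call.low_confidence

    def test_recovery_on_random_aneuploid_truths(self, toy_g, tcfg):
        """Simulated truths with f >= 0.5 and counts in the clinical range
        are recovered in at least 95% of seeded replicates."""
        rng = np.random.default_rng(12345)
        hits = trials = 0
        for rep in range(20):
            f = float(rng.uniform(0.5, 1.0))
            kind = rep % 3
            copy_numbers = {}
            autos = list(toy_g.autosomes)
            if kind == 0:          # hyperdiploid: 5-9 gains, one tetrasomy
                gains = rng.choice(autos, size=int(rng.integers(5, 10)),
                                   replace=False)
                for c in gains:
                    copy_numbers[c] = 3
                copy_numbers[str(gains[0])] = 4
            elif kind == 1:        # hypodiploid: 4-8 monosomies
                losses = rng.choice(autos, size=int(rng.integers(4, 9)),
                                    replace=False)
                for c in losses:
                    copy_numbers[c] = 1
            else:                  # near-haploid with 2-4 disomies
                copy_numbers = {c: 1 for c in autos}
                for c in rng.choice(autos, size=int(rng.integers(2, 5)),
                                    replace=False):
                    copy_numbers[str(c)] = 2
            sex = "XY" if rng.random() < 0.5 else "XX"
            truth = TruthModel(genome=toy_g, blast_fraction=round(f, 2),
                               copy_numbers=copy_numbers, sex=sex,
                               read_count=100_000)
            want = sum(truth.blast_copies(c) for c in toy_g.names)
            reads, _ = simulate_reads(truth, seed=int(rng.integers(2**31)))
            prof = bin_depth(reads, toy_g, bin_size=tcfg.bin_size)
            call = fit_karyotype(prof, toy_g, tcfg)
            trials += 1
            hits += call.total_count == want
        assert hits >= trials - 1, f"{hits}/{trials} truths recovered"

    def test_added_evidence_never_flips_correct_call(self, toy_g, tcfg):
        truth = TruthModel(genome=toy_g, blast_fraction=0.85,
                           copy_numbers={"chr4": 3, "chr5": 3, "chr6": 3,
                                         "chr10": 3, "chr14": 3, "chr17": 3,
                                         "chr18": 3, "chr21": 4},
                           sex="XY", read_count=120_000)
        reads, _ = simulate_reads(truth, seed=9)
        small = fit_karyotype(bin_depth(reads[:30_000], toy_g,
                                        bin_size=tcfg.bin_size), toy_g, tcfg)
        full = fit_karyotype(bin_depth(reads, toy_g, bin_size=tcfg.bin_size),
                             toy_g, tcfg)
        if small.total_count == 55:
            assert full.total_count == 55


class TestClassifyAneuploidy:
    @pytest.mark.parametrize("count,expected", [
        (24, "near_haploid"), (27, "near_haploid"), (30, "near_haploid"),
        (31, "low_hypodiploid"), (38, "low_hypodiploid"), (39, "low_hypodiploid"),
        (40, "other_aneuploid"), (45, "other_aneuploid"), (46, "none"),
        (47, "other_aneuploid"), (50, "other_aneuploid"),
        (51, "high_hyperdiploid"), (55, "high_hyperdiploid"),
    ])
    def test_class_boundaries(self, count, expected):
        assert classify_aneuploidy(count) == expected

    def test_arm_event_makes_46_other_aneuploid(self):
        assert classify_aneuploidy(46, has_events=True) == "other_aneuploid"

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify_aneuploidy(5)
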