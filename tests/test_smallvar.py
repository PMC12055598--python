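import numpy as np
import pytest

from leukopore.config import DEFAULT_PRIMERS, RunConfig
from leukopore.reads import revcomp
from leukopore.simulate import random_reference, simulate_region_reads
from leukopore.smallvar import (build_consensus, detect_itd, insilico_pcr,
                                phase_variants, realign_and_call)

from conftest import make_read, make_segment

CFG = RunConfig()
REF = random_reference({"chrT": 3_000}, seed=42)
REGION = ("chrT", 0, 3_000)


def _column_reads(n_alt, n_ref, pos=1_500, alt=None):
    """Error-free full-region reads; n_alt carry a substitution at pos."""
    ref = REF["chrT"]
    alt_base = alt or ("A" if ref[pos] != "A" else "G")
    reads = []
    for i in range(n_alt):
        seq = ref[:pos] + alt_base + ref[pos + 1:]
        reads.append(make_read(f"alt{i}", [make_segment(
            "chrT", 0, 3_000, cigar="3000M")], seq=seq))
    for i in range(n_ref):
        reads.append(make_read(f"ref{i}", [make_segment(
            "chrT", 0, 3_000, cigar="3000M")], seq=ref))
    return reads, alt_base


class TestBuildConsensus:
    def test_sub_majority_variant_recorded_but_consensus_keeps_majority(self):
        reads, alt = _column_reads(8, 12)       # alt fraction 0.4
        cons = build_consensus(reads, REGION, REF, CFG)
        assert cons.sequence[1_500] == REF["chrT"][1_500]
        cands = [c for c in cons.candidates if c.ref_pos == 1_500]
        assert len(cands) == 1
        assert cands[0].alt_allele == alt
        assert cands[0].pass1_fraction == pytest.approx(0.4)
        assert not cands[0].in_consensus

    def test_fraction_below_threshold_not_recorded(self):
        reads, _ = _column_reads(29, 71)        # 0.29 < 0.30
        cons = build_consensus(reads, REGION, REF, CFG)
        assert [c for c in cons.candidates if c.ref_pos == 1_500] == []

    def test_fraction_at_threshold_recorded(self):
        reads, _ = _column_reads(30, 70)        # exactly 0.30
        cons = build_consensus(reads, REGION, REF, CFG)
        assert len([c for c in cons.candidates if c.ref_pos == 1_500]) == 1

    def test_all_reference_reads_give_reference_consensus(self):
        reads, _ = _column_reads(0, 15)
        cons = build_consensus(reads, REGION, REF, CFG)
        assert cons.sequence == REF["chrT"]
        assert cons.candidates == []

    def test_below_min_depth_raises(self):
        reads, _ = _column_reads(0, 5)
        with pytest.raises(ValueError, match="min_depth"):
            build_consensus(reads, REGION, REF, CFG)


class TestRealignAndCall:
    def test_sharp_maf_threshold_on_noise_free_reads(self):
        for n_alt, expect in ((29, 0), (30, 1)):
            reads, _ = _column_reads(n_alt, 100 - n_alt)
            cons = build_consensus(reads, REGION, REF, CFG)
            variants = realign_and_call(reads, cons, REGION, REF, CFG)
            assert len([v for v in variants if v.kind == "SNV"]) == expect

    def test_homozygous_snv_called_at_fraction_one(self):
        reads, alt = _column_reads(20, 0)
        cons = build_consensus(reads, REGION, REF, CFG)
        variants = realign_and_call(reads, cons, REGION, REF, CFG)
        assert len(variants) == 1
        v = variants[0]
        assert v.alt_allele == alt and v.allele_fraction == 1.0
        assert v.pos == 1_500

    def test_heterozygous_snv_under_error_recovered(self):
        events = {0: [], 1: [("snv", 1_500, "A" if REF["chrT"][1500] != "A" else "G")]}
        reads = simulate_region_reads(REF["chrT"], "chrT", 0, events,
                                      {0: 0.5, 1: 0.5}, n_reads=90,
                                      read_len_mean=1_200, error_sub=0.02,
                                      error_ins=0.005, error_del=0.005, seed=3)
        cons = build_consensus(reads, REGION, REF, CFG)
        variants = realign_and_call(reads, cons, REGION, REF, CFG)
        snv = [v for v in variants if v.kind == "SNV" and v.pos == 1_500]
        assert len(snv) == 1
        assert abs(snv[0].allele_fraction - 0.5) <= 0.1

    def test_realignment_never_decreases_itd_fraction(self):
        """The stated motivation for pass 2: realigning to a consensus that
        carries the indel recovers at least the pass-1 supporting fraction."""
        ref = REF["chrT"]
        dup = ref[1_000:1_060]
        events = {0: [], 1: [("ins", 1_060, dup)]}
        for seed in range(10):
            reads = simulate_region_reads(ref, "chrT", 0, events,
                                          {0: 0.5, 1: 0.5}, n_reads=80,
                                          read_len_mean=1_500,
                                          error_sub=0.03, error_ins=0.01,
                                          error_del=0.01, seed=seed)
            cons = build_consensus(reads, REGION, REF, CFG)
            cand = [c for c in cons.candidates
                    if c.kind == "insertion" and c.in_consensus]
            assert cand, "pass-1 must incorporate the duplication"
            variants = realign_and_call(reads, cons, REGION, REF, CFG)
            called = [v for v in variants if v.kind == "insertion"]
            assert called
            assert called[0].allele_fraction >= cand[0].pass1_fraction - 1e-9


class TestPhasing:
    def _phased_variants(self, cis=True):
        ref = REF["chrT"]
        a1 = "A" if ref[800] != "A" else "G"
        a2 = "C" if ref[2_000] != "C" else "T"
        if cis:
            events = {0: [], 1: [("snv", 800, a1), ("snv", 2_000, a2)]}
            fr = {0: 0.5, 1: 0.5}
        else:
            events = {0: [("snv", 800, a1)], 1: [("snv", 2_000, a2)]}
            fr = {0: 0.5, 1: 0.5}
        reads = simulate_region_reads(ref, "chrT", 0, events, fr, n_reads=80,
                                      read_len_mean=2_800, error_sub=0.01,
                                      error_ins=0.003, error_del=0.003, seed=9)
        cons = build_consensus(reads, REGION, REF, CFG)
        variants = realign_and_call(reads, cons, REGION, REF, CFG)
        return phase_variants([v for v in variants if v.kind == "SNV"], CFG)

    def test_cis_pair_shares_phase_group(self):
        phased = self._phased_variants(cis=True)
        assert len(phased) == 2
        assert phased[0].phase_group is not None
        assert phased[0].phase_group == phased[1].phase_group

    def test_trans_pair_in_different_groups(self):
        phased = self._phased_variants(cis=False)
        assert len(phased) == 2
        groups = {v.pos: v.phase_group for v in phased}
        assert groups[800] != groups[2_000] or all(
            g is None for g in groups.values())

    def test_uncovered_pair_unphased(self):
        from leukopore.smallvar import SmallVariant
        v1 = SmallVariant("chrT", 10, "A", "G", "SNV", 0.5, 20,
                          alt_read_ids=frozenset({"a", "b"}),
                          ref_read_ids=frozenset({"c", "d"}))
        v2 = SmallVariant("chrT", 100_000, "C", "T", "SNV", 0.5, 20,
                          alt_read_ids=frozenset({"x", "y"}),
                          ref_read_ids=frozenset({"z"}))
        out = phase_variants([v1, v2], CFG)
        assert all(v.phase_group is None for v in out)


class TestDetectItd:
    def test_exact_tandem_duplication_is_itd(self):
        ref = REF["chrT"]
        dup = ref[1_000:1_081]
        consensus = ref[:1_081] + dup + ref[1_081:]
        itd = detect_itd(consensus, REF, REGION, CFG)
        assert itd is not None
        assert itd.kind == "ITD"
        assert len(itd.alt_allele) - 1 == 81
        assert itd.itd_interval[1] - itd.itd_interval[0] == 81

    def test_random_insertion_is_not_itd(self):
        rng = np.random.default_rng(0)
        ins = "".join(rng.choice(list("ACGT")) for _ in range(81))
        ref = REF["chrT"]
        consensus = ref[:1_081] + ins + ref[1_081:]
        assert detect_itd(consensus, REF, REGION, CFG) is None

    def test_sixty_nt_duplication_survives_consensus_errors(self):
        ref = REF["chrT"]
        dup = ref[1_000:1_060]
        events = {0: [], 1: [("ins", 1_060, dup)]}
        hits = 0
        for seed in range(5):
            reads = simulate_region_reads(ref, "chrT", 0, events,
                                          {0: 0.5, 1: 0.5}, n_reads=90,
                                          read_len_mean=1_500,
                                          error_sub=0.03, error_ins=0.01,
                                          error_del=0.01, seed=seed)
            cons = build_consensus(reads, REGION, REF, CFG)
            itd = detect_itd(cons.sequence, REF, REGION, CFG)
            if itd is not None and len(itd.alt_allele) - 1 == 60:
                hits += 1
        assert hits >= 4


class TestInSilicoPCR:
    FWD = DEFAULT_PRIMERS["FLT3_ITD"]["fwd"]
    REV = DEFAULT_PRIMERS["FLT3_ITD"]["rev"]

    @classmethod
    def _amplicons(cls):
        rng = np.random.default_rng(5)
        mid = "".join(rng.choice(list("ACGT")) for _ in range(300))
        pad5 = "".join(rng.choice(list("ACGT")) for _ in range(150))
        pad3 = "".join(rng.choice(list("ACGT")) for _ in range(150))
        ref = pad5 + cls.FWD + mid + revcomp(cls.REV) + pad3
        wt = cls.FWD + mid + revcomp(cls.REV)
        dup = mid[100:181]
        itd = cls.FWD + mid[:181] + dup + mid[181:] + revcomp(cls.REV)
        return ref, wt, itd

    def _reads(self, n_itd=18, n_wt=28):
        ref, wt, itd = self._amplicons()
        reads = [make_read(f"wt{i}", [], seq=wt) for i in range(n_wt)]
        reads += [make_read(f"itd{i}", [],
                            seq=itd if i % 2 else revcomp(itd))
                  for i in range(n_itd)]
        return ref, reads

    def test_worked_example_allelic_ratio(self):
        """46 qualifying reads, 18 duplication-bearing and 28 wild type,
        with the FLT3 11F/12R primers give AR = 0.64."""
        ref, reads = self._reads()
        res = insilico_pcr(reads, self.FWD, self.REV, ref, config=CFG)
        assert (res.itd_count, res.wt_count) == (18, 28)
        assert round(res.allelic_ratio, 2) == 0.64

    def test_error_free_reference_read_sizes_exactly(self):
        ref, wt, _ = self._amplicons()
        res = insilico_pcr([make_read("w", [], seq=wt)], self.FWD, self.REV,
                           ref, config=CFG)
        assert res.amplicon_lengths == [res.wt_length]

    def test_read_missing_reverse_site_excluded(self):
        ref, wt, _ = self._amplicons()
        truncated = wt[:len(wt) - len(self.REV) - 5]
        res = insilico_pcr([make_read("t", [], seq=truncated)], self.FWD,
                           self.REV, ref, config=CFG)
        assert res.itd_count == 0 and res.wt_count == 0
        assert res.amplicon_lengths == []

    def test_orientation_invariance(self):
        ref, reads = self._reads()
        flipped = [make_read(r.read_id, [], seq=revcomp(r.seq)) for r in reads]
        a = insilico_pcr(reads, self.FWD, self.REV, ref, config=CFG)
        b = insilico_pcr(flipped, self.FWD, self.REV, ref, config=CFG)
        assert (a.itd_count, a.wt_count, sorted(a.amplicon_lengths)) == \
               (b.itd_count, b.wt_count, sorted(b.amplicon_lengths))

    def test_ratio_invariant_under_read_duplication(self):
        ref, reads = self._reads()
        a = insilico_pcr(reads, self.FWD, self.REV, ref, config=CFG)
        b = insilico_pcr(reads + reads, self.FWD, self.REV, ref, config=CFG)
        assert b.itd_count == 2 * a.itd_count
        assert b.allelic_ratio == pytest.approx(a.allelic_ratio)

    def test_no_wildtype_reads_flags_infinite(self):
        ref, reads = self._reads(n_itd=5, n_wt=0)
        res = insilico_pcr(reads, self.FWD, self.REV, ref, config=CFG)
        assert res.allelic_ratio is None and res.infinite

    def test_short_primer_rejected(self):
        ref, reads = self._reads(1, 1)
        with pytest.raises(ValueError, match="15 nt"):
            insilico_pcr(reads, "ACGTACGT", self.REV, ref, config=CFG)
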