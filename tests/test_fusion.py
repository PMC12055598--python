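import random

import pytest

from leukopore.fusion import (anchor_reads, call_fusions, dedup_duplex,
                              fusion_orientation)
from leukopore.genome import MaskSet, PanelGene, TargetPanel
from leukopore.simulate import FusionTruth, TruthModel, simulate_reads

from conftest import make_read, make_segment


def _two_gene_read(read_id="r", len_a=4000, len_b=1200, channel=None,
                   start_time=None, duration=None, strand_a="+", strand_b="+"):
    """Split read: segment ending at ETV6 junction, then one in RUNX1."""
    seg_a = make_segment("chr12", 119_500 - len_a, 119_500, strand_a,
                         0, len_a)
    seg_b = make_segment("chr21", 362_500, 362_500 + len_b, strand_b,
                         len_a, len_a + len_b, primary=False)
    return make_read(read_id, [seg_a, seg_b], channel=channel,
                     start_time=start_time, duration=duration)


class TestAnchoring:
    def test_two_gene_split_read_is_anchored(self, toy_panel, tcfg):
        out = anchor_reads([_two_gene_read()], toy_panel, None, tcfg)
        assert len(out) == 1
        assert out[0].genes == frozenset({"ETV6", "RUNX1"})

    @pytest.mark.parametrize("aligned,expected", [(499, 0), (500, 1)])
    def test_500nt_anchor_boundary(self, toy_panel, tcfg, aligned, expected):
        read = make_read("r", [
            make_segment("chr12", 119_000, 119_000 + aligned, query_end=aligned),
            make_segment("chr21", 362_000, 364_000, query_start=aligned,
                         query_end=aligned + 2000, primary=False)])
        out = anchor_reads([read], toy_panel, None, tcfg)
        assert len(out) == expected

    @pytest.mark.parametrize("gap,expected", [(5_001, 0), (4_999, 1)])
    def test_5kbp_margin_boundary(self, toy_panel, tcfg, gap, expected):
        # segment upstream of ETV6 (gene starts at 118,000) by `gap` bp
        far = make_segment("chr12", 118_000 - gap - 2000, 118_000 - gap,
                           query_end=2000)
        near = make_segment("chr21", 362_000, 364_000, query_start=2000,
                            query_end=4000, primary=False)
        out = anchor_reads([make_read("r", [far, near])], toy_panel, None, tcfg)
        assert len(out) == expected

    def test_mask_removes_anchor_and_call(self, toy_panel, tcfg):
        reads = [_two_gene_read(f"r{i}") for i in range(3)]
        calls = call_fusions(anchor_reads(reads, toy_panel, None, tcfg), tcfg)
        assert len(calls) == 1
        mask = MaskSet({"chr21": [(360_000, 365_000)]})
        anchored = anchor_reads(reads, toy_panel, mask, tcfg)
        assert anchored == []
        assert call_fusions(anchored, tcfg) == []


class TestDuplexDedup:
    def _pair(self, dt, ch_a=212, ch_b=212):
        return [
            _two_gene_read("a", channel=ch_a, start_time=100.0, duration=10.0),
            _two_gene_read("b", channel=ch_b, start_time=100.0 + dt, duration=10.0),
        ]

    def test_same_channel_within_window_collapses(self, toy_panel, tcfg):
        anchored = anchor_reads(self._pair(10.0), toy_panel, None, tcfg)
        assert len(dedup_duplex(anchored, tcfg)) == 1

    def test_31s_apart_not_collapsed(self, toy_panel, tcfg):
        anchored = anchor_reads(self._pair(31.0), toy_panel, None, tcfg)
        assert len(dedup_duplex(anchored, tcfg)) == 2

    def test_different_channels_not_collapsed(self, toy_panel, tcfg):
        anchored = anchor_reads(self._pair(5.0, ch_b=7), toy_panel, None, tcfg)
        assert len(dedup_duplex(anchored, tcfg)) == 2

    def test_transitive_chain_collapses_to_earliest(self, toy_panel, tcfg):
        reads = [_two_gene_read(f"r{i}", channel=3, start_time=100.0 + 20 * i,
                                duration=5.0) for i in range(3)]
        anchored = anchor_reads(reads, toy_panel, None, tcfg)
        kept = dedup_duplex(anchored, tcfg)
        assert [a.read_id for a in kept] == ["r0"]

    def test_idempotence_and_monotone_support(self, toy_panel, tcfg):
        reads = self._pair(10.0) + self._pair(40.0)[1:]
        anchored = anchor_reads(reads, toy_panel, None, tcfg)
        once = dedup_duplex(anchored, tcfg)
        twice = dedup_duplex(once, tcfg)
        assert [a.read_id for a in once] == [a.read_id for a in twice]
        assert len(once) <= len(anchored)

    def test_missing_metadata_passes_through(self, toy_panel, tcfg):
        reads = [_two_gene_read("a"), _two_gene_read("b")]
        anchored = anchor_reads(reads, toy_panel, None, tcfg)
        assert len(dedup_duplex(anchored, tcfg)) == 2


class TestCallFusions:
    def test_two_supports_one_call(self, toy_panel, tcfg):
        reads = [_two_gene_read("a"), _two_gene_read("b", len_a=3500)]
        calls = call_fusions(anchor_reads(reads, toy_panel, None, tcfg), tcfg)
        assert len(calls) == 1
        assert calls[0].name == "ETV6::RUNX1"
        assert calls[0].support_count == 2
        assert calls[0].breakpoint_a == 119_500
        assert calls[0].breakpoint_b == 362_500

    def test_single_support_no_call(self, toy_panel, tcfg):
        calls = call_fusions(anchor_reads([_two_gene_read()], toy_panel,
                                          None, tcfg), tcfg)
        assert calls == []

    def test_distant_junctions_split_into_clusters(self, toy_panel, tcfg):
        near = [_two_gene_read(f"n{i}") for i in range(2)]
        far = [make_read(f"f{i}", [
            make_segment("chr12", 114_000, 118_200, "+", 0, 4200),
            make_segment("chr21", 363_500, 364_700, "+", 4200, 5400,
                         primary=False)]) for i in range(2)]
        calls = call_fusions(anchor_reads(near + far, toy_panel, None, tcfg), tcfg)
        assert len(calls) == 2

    def test_symmetry_under_read_order(self, toy_panel, tcfg):
        reads = [_two_gene_read(f"r{i}", len_a=3000 + 100 * i) for i in range(4)]
        a = call_fusions(anchor_reads(reads, toy_panel, None, tcfg), tcfg)
        rev = list(reversed(reads))
        b = call_fusions(anchor_reads(rev, toy_panel, None, tcfg), tcfg)
        assert [(c.name, c.support_count, c.breakpoint_a, c.breakpoint_b)
                for c in a] == \
               [(c.name, c.support_count, c.breakpoint_a, c.breakpoint_b)
                for c in b]

    def test_three_gene_read_contributes_all_pairs(self, toy_panel, tcfg):
        def tri(rid):
            return make_read(rid, [
                make_segment("chr12", 118_500, 119_500, "+", 0, 1000),
                make_segment("chr21", 362_000, 363_000, "+", 1000, 2000,
                             primary=False),
                make_segment("chr11", 1_181_000, 1_182_000, "+", 2000, 3000,
                             primary=False)])
        calls = call_fusions(anchor_reads([tri("a"), tri("b")], toy_panel,
                                          None, tcfg), tcfg)
        assert {c.name for c in calls} == \
            {"ETV6::RUNX1", "ETV6::KMT2A", "KMT2A::RUNX1"}

    def test_simulated_fusion_with_duplex_twin(self, toy_g, toy_panel, tcfg):
        truth = TruthModel(genome=toy_g, read_count=2_000,
                           fusions=[FusionTruth("ETV6", "chr12", 119_500,
                                                "RUNX1", "chr21", 362_500,
                                                n_molecules=5)])
        reads, info = simulate_reads(truth, seed=4)
        twin_src = next(r for r in reads if r.read_id.startswith("fusion"))
        twin = make_read(twin_src.read_id + "_dx", [
            make_segment(s.chrom, s.ref_start, s.ref_end,
                         "-" if s.strand == "+" else "+",
                         s.query_start, s.query_end, primary=s.is_primary)
            for s in twin_src.segments],
            channel=twin_src.channel,
            start_time=twin_src.start_time + 8.0,
            duration=twin_src.duration)
        anchored = anchor_reads(reads + [twin], toy_panel, None, tcfg)
        deduped = dedup_duplex(anchored, tcfg)
        calls = call_fusions(deduped, tcfg)
        assert len(calls) == 1
        assert calls[0].support_count == 5     # twin collapsed

    def test_null_run_produces_zero_calls(self, toy_g, toy_panel, tcfg):
        for seed in range(20):
            truth = TruthModel(genome=toy_g, read_count=2_000, duplex_prob=0.02)
            reads, _ = simulate_reads(truth, seed=seed)
            anchored = dedup_duplex(anchor_reads(reads, toy_panel, None, tcfg),
                                    tcfg)
            assert call_fusions(anchored, tcfg) == []


class TestOrientation:
    def _call(self, strand_a, strand_b):
        reads = [_two_gene_read(f"r{i}", strand_a=strand_a, strand_b=strand_b)
                 for i in range(2)]
        panel = TargetPanel(entries=[
            PanelGene("ETV6", "chr12", 118_000, 120_500, "+"),
            PanelGene("RUNX1", "chr21", 361_000, 364_000, "-")],
            anchor_margin=5_000)
        calls = call_fusions(anchor_reads(reads, panel, None))
        return fusion_orientation(calls[0], panel)

    def test_head_to_head_inversion_compatible(self):
        # genes on (+,-): segments (+,-) traverse both along coding
        assert self._call("+", "-").orientation == "compatible"

    def test_both_along_coding_compatible(self):
        panel = TargetPanel(entries=[
            PanelGene("ETV6", "chr12", 118_000, 120_500, "+"),
            PanelGene("RUNX1", "chr21", 361_000, 364_000, "+")])
        reads = [_two_gene_read(f"r{i}", strand_a="+", strand_b="+")
                 for i in range(2)]
        calls = call_fusions(anchor_reads(reads, panel, None))
        assert fusion_orientation(calls[0], panel).orientation == "compatible"

    def test_coding_into_antisense_incompatible(self):
        panel = TargetPanel(entries=[
            PanelGene("ETV6", "chr12", 118_000, 120_500, "+"),
            PanelGene("RUNX1", "chr21", 361_000, 364_000, "+")])
        reads = [_two_gene_read(f"r{i}", strand_a="+", strand_b="-")
                 for i in range(2)]
        calls = call_fusions(anchor_reads(reads, panel, None))
        assert fusion_orientation(calls[0], panel).orientation == "incompatible"

    def test_missing_strand_unknown(self):
        panel = TargetPanel(entries=[
            PanelGene("ETV6", "chr12", 118_000, 120_500, "."),
            PanelGene("RUNX1", "chr21", 361_000, 364_000, "-")])
        reads = [_two_gene_read(f"r{i}") for i in range(2)]
        calls = call_fusions(anchor_reads(reads, panel, None))
        assert fusion_orientation(calls[0], panel).orientation == "unknown"
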