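import itertools

import numpy as np
import pytest

from leukopore.config import RunConfig, toy_config
from leukopore.genome import GenomeModel, PanelGene, TargetPanel, toy_genome
from leukopore.karyotype import DepthProfile
from leukopore.reads import AlignmentSegment, ReadRecord


@pytest.fixture(scope="session")
def toy_g():
    return toy_genome()


@pytest.fixture(scope="session")
def tcfg():
    return toy_config()


@pytest.fixture(scope="session")
def mini_genome():
    """One 400-kb chromosome; enough for focal-CNV and region tests."""
    return GenomeModel(chromosomes=(("chr12", 400_000),),
                       centromeres={"chr12": (10_000, 12_000)},
                       sex_chromosome_names=frozenset())


@pytest.fixture(scope="session")
def toy_panel(tcfg):
    """Four well-separated genes on the toy genome."""
    return TargetPanel(entries=[
        PanelGene("ETV6", "chr12", 118_000, 120_500, "+"),
        PanelGene("RUNX1", "chr21", 361_000, 364_000, "-"),
        PanelGene("KMT2A", "chr11", 1_180_000, 1_183_000, "+"),
        PanelGene("FLT3", "chr13", 280_000, 283_000, "-"),
    ], panel_margin=tcfg.panel_margin, anchor_margin=tcfg.anchor_margin)


def make_read(read_id="r", segments=(), channel=None, start_time=None,
              duration=None, seq=None, read_len=None):
    segs = list(segments)
    if read_len is None:
        read_len = max((s.query_end for s in segs), default=len(seq or ""))
    return ReadRecord(read_id=read_id, read_len=read_len, segments=segs,
                      channel=channel, start_time=start_time,
                      duration=duration, seq=seq)


def make_segment(chrom, ref_start, ref_end, strand="+", query_start=0,
                 query_end=None, aligned=None, cigar=None, primary=True):
    span = ref_end - ref_start
    if query_end is None:
        query_end = query_start + span
    if aligned is None:
        aligned = query_end - query_start
    return AlignmentSegment(chrom=chrom, ref_start=ref_start, ref_end=ref_end,
                            strand=strand, query_start=query_start,
                            query_end=query_end, aligned_query_len=aligned,
                            cigar=cigar, is_primary=primary)


def flat_profile(genome, per_chrom_value, bin_size=10_000):
    """Noise-free DepthProfile with a constant count per chromosome."""
    counts, usable = {}, {}
    for chrom, length in genome.chromosomes:
        nb = max(1, -(-length // bin_size))
        counts[chrom] = np.full(nb, per_chrom_value.get(chrom, 0), dtype=np.int64)
        u = np.ones(nb, dtype=bool)
        if nb * bin_size > length:
            u[-1] = False
        cen = genome.centromere(chrom)
        if cen is not None and cen[1] > cen[0]:
            u[cen[0] // bin_size:min(nb - 1, (cen[1] - 1) // bin_size) + 1] = False
        usable[chrom] = u
    return DepthProfile(bin_size=bin_size, counts=counts, usable=usable)


# ---------------------------------------------------------------------------
# independent two-sample KS oracle (brute-force enumeration)
# ---------------------------------------------------------------------------

def ks_statistic_brute(a, b):
    """max |ECDF_a - ECDF_b| evaluated at every pooled value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = 0.0
    for v in np.concatenate([a, b]):
        d = max(d, abs((a <= v).mean() - (b <= v).mean()))
    return d


def ks_exact_pvalue_enum(a, b):
    """Exact permutation p-value: fraction of all C(n+m, n) label
    assignments of the pooled sample whose D meets or exceeds the observed
    D.  Feasible for n + m <= ~16."""
    pooled = list(a) + list(b)
    n = len(a)
    d_obs = ks_statistic_brute(a, b)
    idx = range(len(pooled))
    hits = total = 0
    for comb in itertools.combinations(idx, n):
        comb_set = set(comb)
        x = [pooled[i] for i in comb]
        y = [pooled[i] for i in idx if i not in comb_set]
        if ks_statistic_brute(x, y) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return d_obs, hits / total
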