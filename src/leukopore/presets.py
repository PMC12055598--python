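"""Reference scenarios: the study conditions the package is validated on.

Each function builds the truth model (or synthetic input set) for one of
the canonical cases — the 55,XY high-hyperdiploid, the 27,XY near-haploid
and the 38,XX low-hypodiploid (+11q) digital karyotypes, the heterozygous
81-nt FLT3 internal tandem duplication, the in silico PCR allelic-ratio
worked example, and a focal RUNX1 amplification (iAMP21).  Tests, the
acceptance script and the examples all draw from here so the conditions
are stated once.
"""

from __future__ import annotations

import numpy as np

from .config import DEFAULT_PRIMERS
from .genome import GenomeModel, toy_genome
from .reads import ReadRecord, revcomp
from .simulate import TruthModel, random_reference, simulate_region_reads

#: read count used for the karyotype recovery scenarios (>= 50k with margin
#: so the arm-level KS confirmation in the hypodiploid case is well powered)
KARYOTYPE_READ_COUNT = 120_000


def hyperdiploid_55_truth(genome: GenomeModel | None = None,
                          read_count: int = KARYOTYPE_READ_COUNT) -> TruthModel:
    """55,XY,+4,+5,+6,+10,+14,+17,+18,+21,+21 at blast fraction 0.85."""
    return TruthModel(
        genome=genome or toy_genome(), blast_fraction=0.85,
        copy_numbers={"chr4": 3, "chr5": 3, "chr6": 3, "chr10": 3,
                      "chr14": 3, "chr17": 3, "chr18": 3, "chr21": 4},
        sex="XY", read_count=read_count)


def near_haploid_27_truth(genome: GenomeModel | None = None,
                          read_count: int = KARYOTYPE_READ_COUNT) -> TruthModel:
    """27,XY,+10,+18,+21: haploid blasts with three disomies, f = 0.9."""
    genome = genome or toy_genome()
    copy_numbers = {c: 1 for c in genome.autosomes}
    copy_numbers.update({"chr10": 2, "chr18": 2, "chr21": 2})
    return TruthModel(genome=genome, blast_fraction=0.9,
                      copy_numbers=copy_numbers, sex="XY",
                      read_count=read_count)


def low_hypodiploid_38_truth(genome: GenomeModel | None = None,
                             read_count: int = KARYOTYPE_READ_COUNT) -> TruthModel:
    """38,XX,-3,-4,-7,-9,+11q,-15,-16,-17,-18 at blast fraction 0.85."""
    return TruthModel(
        genome=genome or toy_genome(), blast_fraction=0.85,
        copy_numbers={c: 1 for c in ("chr3", "chr4", "chr7", "chr9",
                                     "chr15", "chr16", "chr17", "chr18")},
        arm_copy={("chr11", "q"): 3}, sex="XX", read_count=read_count)


# -- FLT3-ITD -----------------------------------------------------------

FLT3_REGION = ("chr13", 0, 10_000)
FLT3_DUP = (5_000, 5_081)        # 81-nt tandem-duplicated segment


def flt3_reference() -> dict:
    return random_reference({"chr13": FLT3_REGION[2]}, seed=7)


def flt3_itd_reads(seed: int, n_reads: int = 135,
                   carrier_fraction: float = 0.5):
    """Reads over a FLT3-like target with the 81-nt duplication on half the
    molecules, at ~5% read error and ~40x depth."""
    ref = flt3_reference()
    refseq = ref["chr13"]
    dup_seq = refseq[FLT3_DUP[0]:FLT3_DUP[1]]
    events = {0: [], 1: [("ins", FLT3_DUP[1], dup_seq)]}
    reads = simulate_region_reads(
        refseq, "chr13", 0, events,
        {0: 1.0 - carrier_fraction, 1: carrier_fraction},
        n_reads=n_reads, read_len_mean=3_000,
        error_sub=0.03, error_ins=0.01, error_del=0.01, seed=seed)
    return ref, reads


# -- in silico PCR worked example ---------------------------------------

def insilico_pcr_example(n_itd: int = 18, n_wt: int = 28):
    """46 error-free amplicon reads between the FLT3 11F/12R primer sites:
    18 carry an internal 81-nt duplication, 28 are wild type (AR = 0.64)."""
    fwd = DEFAULT_PRIMERS["FLT3_ITD"]["fwd"]
    rev = DEFAULT_PRIMERS["FLT3_ITD"]["rev"]
    rng = np.random.default_rng(5)
    draw = lambda n: "".join(rng.choice(list("ACGT")) for _ in range(n))
    mid = draw(300)
    refseq = draw(150) + fwd + mid + revcomp(rev) + draw(150)
    wt = fwd + mid + revcomp(rev)
    itd = fwd + mid[:181] + mid[100:181] + mid[181:] + revcomp(rev)
    reads = [ReadRecord(read_id=f"wt{i}", read_len=len(wt), segments=[],
                        seq=wt) for i in range(n_wt)]
    reads += [ReadRecord(read_id=f"itd{i}", read_len=len(itd), segments=[],
                         seq=itd if i % 2 else revcomp(itd))
              for i in range(n_itd)]
    return refseq, reads, fwd, rev


# -- iAMP21 -------------------------------------------------------------

def iamp21_reads():
    """Noise-free per-base depth: a RUNX1-containing interval at three
    times the diploid baseline in a pure-tumor specimen (six copies)."""
    from .reads import ReadRecord
    from .reads import AlignmentSegment

    def seg(start, end):
        return AlignmentSegment(chrom="chr21", ref_start=start, ref_end=end,
                                strand="+", query_start=0,
                                query_end=end - start,
                                aligned_query_len=end - start)

    reads = [ReadRecord(read_id=f"base{i}", read_len=30_000,
                        segments=[seg(300_000, 330_000)]) for i in range(20)]
    reads += [ReadRecord(read_id=f"amp{i}", read_len=6_000,
                         segments=[seg(360_000, 366_000)]) for i in range(60)]
    baseline_region = ("chr21", 300_000, 330_000)
    amp_region = ("chr21", 360_000, 366_000)
    runx1_region = ("chr21", 361_000, 364_000)
    return reads, baseline_region, amp_region, runx1_region
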