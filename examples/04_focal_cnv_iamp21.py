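"""Focal deletion calling and the iAMP21 flag.

Part 1: a clonal 10-kb interstitial deletion (CRLF2-P2RY8-style at toy
scale) detected from the conjunction of a depth drop and split reads.
Part 2: a RUNX1-containing interval at 3x the diploid baseline estimates
six copies and triggers the iAMP21 flag.
"""

from leukopore.cnv import (call_focal_amplification, call_focal_deletion,
                           estimate_region_copies, flag_iamp21)
from leukopore.config import toy_config
from leukopore.genome import GenomeModel, toy_genome
from leukopore.karyotype import KaryotypeCall
from leukopore.presets import iamp21_reads
from leukopore.simulate import DeletionTruth, TruthModel, simulate_reads

config = toy_config()
mini = GenomeModel(chromosomes=(("chr12", 400_000),),
                   centromeres={"chr12": (10_000, 12_000)},
                   sex_chromosome_names=frozenset())
truth = TruthModel(genome=mini, blast_fraction=0.85, read_count=28_000,
                   read_len_median=800.0, read_len_sigma=0.35,
                   deletions=[DeletionTruth("chr12", 200_000, 210_000, 1.0)])
reads, _ = simulate_reads(truth, seed=0)
kcall = KaryotypeCall(blast_fraction=0.85, per_copy_depth=1.0,
                      copy_number={"chr12": 2})
for c in call_focal_deletion(reads, ("chr12", 180_000, 230_000), kcall, config):
    print(f"deletion {c.chrom}:{c.start}-{c.end}: {c.copy_estimate} copy lost, "
          f"clonal fraction {c.clonal_fraction:.2f}, "
          f"{c.split_support} split reads, depth ratio {c.depth_ratio:.2f}")

genome = toy_genome()
amp_reads, baseline, amp_region, runx1 = iamp21_reads()
kc21 = KaryotypeCall(blast_fraction=1.0, per_copy_depth=1.0,
                     copy_number={"chr21": 2})
copies = estimate_region_copies(amp_reads, amp_region, kc21,
                                baseline_region=baseline, config=config)
amp = call_focal_amplification(amp_reads, amp_region, kc21,
                               baseline_region=baseline, config=config)
flagged, rationale = flag_iamp21(copies, [amp], None, genome,
                                 runx1_region=runx1)
print(f"RUNX1 region: {copies} copies; iAMP21 = {flagged} ({rationale})")
# A deletion requires split-read and/or depth evidence per the configured
# rules; iAMP21 requires >=4 RUNX1 copies inside a focal amplification.
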