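"""Infer a digital karyotype from a simulated high-hyperdiploid run.

Simulates ~120k timed reads from a 55,XY,+4,+5,+6,+10,+14,+17,+18,+21,+21
specimen at 85% blast fraction on the 1/100-scale toy genome, bins read
centers, and fits the copy-number mixture model.
"""

from leukopore.config import toy_config
from leukopore.genome import toy_genome
from leukopore.karyotype import bin_depth, fit_karyotype
from leukopore.presets import hyperdiploid_55_truth
from leukopore.simulate import simulate_reads

genome = toy_genome()
config = toy_config()
truth = hyperdiploid_55_truth(genome)

reads, _info = simulate_reads(truth, seed=1)
profile = bin_depth(reads, genome, bin_size=config.bin_size)
call = fit_karyotype(profile, genome, config)

print("inferred karyotype:", call.iscn(genome))
print(f"aneuploidy class:   {call.aneuploidy_class}")
print(f"blast fraction:     {call.blast_fraction:.2f} (truth 0.85)")
print(f"per-copy depth:     {call.per_copy_depth:.1f} reads/bin per haploid copy")
# The ISCN-like string lists the total chromosome count, sex, and every
# whole-chromosome gain/loss in the dominant blast clone; the class follows
# the clinical count bands (>50 chromosomes = high hyperdiploidy).
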