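"""Run configuration: every tunable constant of the pipeline, with defaults.

Defaults mirror the published analysis: 1-Mbp read-center bins, the 500-nt /
5-kbp anchoring rule, two independent supporting reads per fusion, a 30-s
same-channel duplex window, the 0.3 alternate-allele-fraction reporting
threshold, KS p < 1e-9 with >=20% median divergence, detection thresholds at
>=53 / <=39 chromosomes, a 5-min analysis latency and a 1-min timepoint grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: FLT3-ITD capillary-electrophoresis surrogate primers (11F / 12R).
DEFAULT_PRIMERS = {
    "FLT3_ITD": {
        "fwd": "GCAATTTAGGTATGAAAGCCAGC",
        "rev": "CTTTCAGCATTTTGACGGCAACC",
    }
}


@dataclass
class RunConfig:
    # karyotype
    bin_size: int = 1_000_000          # bp per read-center bin
    copy_max: int = 8                  # per-chromosome integer copy ceiling
    blast_fraction_min: float = 0.05   # grid lower bound for f
    blast_fraction_step: float = 0.01
    low_confidence_blast_fraction: float = 0.3
    min_usable_bins: int = 20          # below this a chromosome is low-confidence

    # fusion
    anchor_len: int = 500              # nt of aligned query to anchor a gene
    anchor_margin: int = 5_000         # bp around the gene still anchoring
    min_fusion_support: int = 2
    duplex_window: float = 30.0        # s, same-channel duplex collapse
    junction_tolerance: int = 50       # bp, breakpoint clustering

    # cnv
    min_deletion_size: int = 50        # bp; smaller events belong to smallvar
    max_query_gap: int = 30            # nt between split segments in the read
    min_flank_depth: float = 10.0      # below: low-confidence, require both evidences
    region_copy_max: int = 12

    # smallvar
    maf_threshold: float = 0.3         # alternate-allele fraction to report
    min_depth: int = 10
    max_primer_edits: int = 3          # edit distance for in silico PCR sites
    itd_min_gain: int = 9              # nt of amplicon gain to classify ITD
    itd_min_identity: float = 0.8      # inserted seq vs adjacent reference
    phase_min_reads: int = 5
    phase_concordance: float = 0.9

    # realtime
    ks_p_threshold: float = 1e-9
    median_divergence: float = 0.20
    ks_all_pairs: bool = False         # require divergence vs every modal chrom
    hyperdiploid_detect: int = 53      # chromosomes
    hypodiploid_detect: int = 39
    analysis_latency: float = 300.0    # s added to the second supporting read
    timepoint_step: float = 60.0       # s, cumulative-evidence grid

    # metadata / IO
    panel_margin: int = 50_000         # bp kept on-target around panel genes
    sequencing_rate: float = 400.0     # nt/s; duration fallback = read_len/rate
    channel_tag: str = "ch"
    time_tag: str = "st"
    duration_tag: str = "du"
    primers: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PRIMERS.items()})

    def __post_init__(self):
        if not 0 < self.maf_threshold <= 1:
            raise ValueError("maf_threshold must be in (0, 1]")
        if self.bin_size <= 0 or self.anchor_len <= 0:
            raise ValueError("bin_size and anchor_len must be positive")
        if self.duplex_window < 0 or self.analysis_latency < 0:
            raise ValueError("time windows must be >= 0")
        if not 0 < self.ks_p_threshold < 1:
            raise ValueError("ks_p_threshold must be in (0, 1)")
        if self.hypodiploid_detect >= self.hyperdiploid_detect:
            raise ValueError("hypodiploid_detect must be < hyperdiploid_detect")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def toy_config(**overrides) -> RunConfig:
    """Config re-scaled for the 1/100 toy genome (10-kbp bins)."""
    kw = dict(bin_size=10_000, panel_margin=500)
    kw.update(overrides)
    return RunConfig(**kw)
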