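"""Genome coordinate model: chromosomes, centromeres, arms, target panels, masks.

All coordinates are 0-based half-open throughout the package; the only
conversion to 1-based happens at the VCF boundary in :mod:`leukopore.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# GRCh38 chromosome lengths (bp) and approximate centromere midpoints (bp).
# Used both for the real coordinate frame and, scaled down, for the toy genome.
_GRCH38_LENGTHS = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895, "chrY": 57_227_415,
}
_GRCH38_CEN_MID = {
    "chr1": 123_400_000, "chr2": 93_900_000, "chr3": 90_900_000,
    "chr4": 50_000_000, "chr5": 48_800_000, "chr6": 59_800_000,
    "chr7": 60_100_000, "chr8": 45_200_000, "chr9": 43_000_000,
    "chr10": 39_800_000, "chr11": 53_400_000, "chr12": 35_500_000,
    "chr13": 17_700_000, "chr14": 17_200_000, "chr15": 19_000_000,
    "chr16": 36_800_000, "chr17": 25_100_000, "chr18": 18_500_000,
    "chr19": 26_200_000, "chr20": 28_100_000, "chr21": 12_000_000,
    "chr22": 15_000_000, "chrX": 60_500_000, "chrY": 10_400_000,
}


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths, centromere intervals and p/q arms.

    ``chromosomes`` is an ordered list of ``(name, length)``; ``centromeres``
    maps chromosome name to a 0-based half-open interval.  Arms are derived:
    p = ``[0, cen.start)``, q = ``[cen.end, length)``.
    """

    chromosomes: tuple = ()
    centromeres: dict = field(default_factory=dict)
    sex_chromosome_names: frozenset = frozenset({"chrX", "chrY"})

    def __post_init__(self):
        seen = set()
        for name, length in self.chromosomes:
            if name in seen:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seen.add(name)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            cen = self.centromeres.get(name)
            if cen is not None:
                cs, ce = cen
                if not (0 <= cs <= ce <= length):
                    raise ValueError(
                        f"centromere {cen} outside chromosome {name!r} (length {length})"
                    )

    @property
    def names(self) -> list:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def autosomes(self) -> list:
        return [n for n in self.names if n not in self.sex_chromosome_names]

    def is_sex(self, chrom: str) -> bool:
        return chrom in self.sex_chromosome_names

    def arms(self, chrom: str) -> dict:
        """p/q arm intervals for ``chrom`` (0-based half-open)."""
        length = self.length(chrom)
        cen = self.centromeres.get(chrom)
        if cen is None:
            mid = length // 2
            cen = (mid, mid)
        return {"p": (0, cen[0]), "q": (cen[1], length)}

    def centromere(self, chrom: str):
        return self.centromeres.get(chrom)


def grch38_genome() -> GenomeModel:
    """Full-scale human genome model with approximate centromere intervals."""
    half = 2_500_000
    cens = {
        c: (max(0, m - half), min(_GRCH38_LENGTHS[c], m + half))
        for c, m in _GRCH38_CEN_MID.items()
    }
    return GenomeModel(
        chromosomes=tuple(_GRCH38_LENGTHS.items()),
        centromeres=cens,
    )


def toy_genome(scale: float = 0.01) -> GenomeModel:
    """Down-scaled 24-chromosome genome (default 1/100 of GRCh38).

    Keeps the relative chromosome sizes and centromere placement of the human
    genome so that bin counts, arm sizes and class boundaries behave like the
    real thing while whole simulated runs fit in seconds.
    """
    chroms = tuple((c, max(1, round(l * scale))) for c, l in _GRCH38_LENGTHS.items())
    half = max(1, round(2_500_000 * scale))
    cens = {}
    lengths = dict(chroms)
    for c, m in _GRCH38_CEN_MID.items():
        mid = round(m * scale)
        cens[c] = (max(0, mid - half), min(lengths[c], mid + half))
    return GenomeModel(chromosomes=chroms, centromeres=cens)


@dataclass(frozen=True)
class PanelGene:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class TargetPanel:
    """Adaptive-sampling enrichment targets: genes with optional strand.

    ``panel_margin`` is the flank kept on-target by the sequencer's decision
    rule; ``anchor_margin`` is the flank within which a long alignment still
    anchors a read to the gene for fusion calling.
    """

    entries: list
    panel_margin: int = 50_000
    anchor_margin: int = 5_000

    def __post_init__(self):
        if self.panel_margin < 0 or self.anchor_margin < 0:
            raise ValueError("margins must be >= 0")
        names = [e.gene for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("gene names in a panel must be unique")
        for e in self.entries:
            if not (0 <= e.start < e.end):
                raise ValueError(f"invalid interval for gene {e.gene!r}")

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = genome.lengths
        for e in self.entries:
            if e.chrom not in lengths:
                raise ValueError(f"gene {e.gene!r}: unknown chromosome {e.chrom!r}")
            if e.end > lengths[e.chrom]:
                raise ValueError(
                    f"gene {e.gene!r} interval exceeds {e.chrom} length {lengths[e.chrom]}"
                )

    def get(self, gene: str) -> PanelGene:
        for e in self.entries:
            if e.gene == gene:
                return e
        raise KeyError(gene)

    def genes(self) -> list:
        return [e.gene for e in self.entries]

    def on_target(self, chrom: str, start: int, end: int) -> bool:
        """Does [start, end) overlap any panel gene padded by panel_margin?"""
        for e in self.entries:
            if e.chrom != chrom:
                continue
            if start < e.end + self.panel_margin and end > e.start - self.panel_margin:
                return True
        return False


class MaskSet:
    """Per-chromosome sorted, non-overlapping excluded intervals.

    Emulates masking of centromeric/satellite repeats and segmental
    duplications that would otherwise produce ambiguous alignments.
    """

    def __init__(self, intervals: dict | None = None):
        self._iv: dict = {}
        if intervals:
            for chrom, ivs in intervals.items():
                for s, e in ivs:
                    self.add(chrom, s, e)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start < 0 or end < start:
            raise ValueError(f"invalid mask interval [{start}, {end})")
        self._iv.setdefault(chrom, []).append((start, end))
        self._iv[chrom] = _merge(self._iv[chrom])

    def intervals(self, chrom: str) -> list:
        return list(self._iv.get(chrom, []))

    def chromosomes(self) -> list:
        return sorted(self._iv)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self._iv.get(chrom, []):
            if start < e and end > s:
                return True
        return False

    def __eq__(self, other):
        return isinstance(other, MaskSet) and self._iv == other._iv


def _merge(ivs: list) -> list:
    out: list = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
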