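"""Gene-fusion calling from anchored split reads.

A read is *anchored* in a panel gene when one of its alignment segments has
at least ``anchor_len`` aligned query bases and lies within ``anchor_margin``
of the gene interval (promoter-swap rearrangements place breakpoints just
outside annotated bounds).  Reads anchored in two distinct genes evidence a
rearrangement; duplex-strand artifacts (same channel within the duplex
window) are collapsed before counting independent support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from .config import RunConfig
from .genome import MaskSet, TargetPanel


@dataclass
class Anchor:
    gene: str
    segment: object


@dataclass
class AnchoredRead:
    read_id: str
    anchors: list
    channel: int | None = None
    start_time: float | None = None
    finish_time: float | None = None

    @property
    def genes(self) -> frozenset:
        return frozenset(a.gene for a in self.anchors)


def anchor_reads(reads, panel: TargetPanel, mask: MaskSet | None = None,
                 config: RunConfig | None = None) -> list:
    """Reads with >=anchor_len-nt alignments in two or more distinct genes.

    Segments overlapping the mask are discarded before anchoring, so a mask
    over one partner removes the evidence entirely.
    """
    config = config or RunConfig()
    margin = config.anchor_margin
    out = []
    for read in reads:
        anchors = []
        for seg in read.segments:
            if mask is not None and mask.overlaps(seg.chrom, seg.ref_start, seg.ref_end):
                continue
            if seg.aligned_query_len < config.anchor_len:
                continue
            for entry in panel.entries:
                if entry.chrom != seg.chrom:
                    continue
                if seg.ref_start < entry.end + margin and seg.ref_end > entry.start - margin:
                    anchors.append(Anchor(gene=entry.gene, segment=seg))
        if len({a.gene for a in anchors}) >= 2:
            out.append(AnchoredRead(
                read_id=read.read_id, anchors=anchors, channel=read.channel,
                start_time=read.start_time, finish_time=read.finish_time))
    return out


def dedup_duplex(anchored, config: RunConfig | None = None) -> list:
    """Collapse same-channel duplex twins supporting the same rearrangement.

    Within each anchored gene set, reads on the same channel whose start
    times fall within the duplex window are transitively clustered and only
    the earliest is kept.  Reads without channel/time metadata pass through
    untouched (conservatively treated as independent).
    """
    config = config or RunConfig()
    window = config.duplex_window
    keep: list = []
    groups: dict = {}
    for ar in anchored:
        if ar.channel is None or ar.start_time is None:
            keep.append(ar)
            continue
        groups.setdefault((ar.genes, ar.channel), []).append(ar)
    for members in groups.values():
        members.sort(key=lambda a: (a.start_time, a.read_id))
        cluster = [members[0]]
        for ar in members[1:]:
            if ar.start_time - cluster[-1].start_time <= window:
                cluster.append(ar)          # transitive chain
            else:
                keep.append(cluster[0])
                cluster = [ar]
        keep.append(cluster[0])
    keep.sort(key=lambda a: a.read_id)
    return keep


@dataclass
class SupportingRead:
    read_id: str
    junction_a: int
    junction_b: int
    strand_a: str
    strand_b: str
    channel: int | None = None
    start_time: float | None = None
    finish_time: float | None = None


@dataclass
class FusionCall:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    breakpoint_a: int
    breakpoint_b: int
    strand_a: str
    strand_b: str
    support_count: int
    supporting_reads: list = field(default_factory=list)
    orientation: str = "unknown"         # compatible / incompatible / unknown
    detection_time: float | None = None
    ambiguous: bool = False

    @property
    def name(self) -> str:
        return f"{self.gene_a}::{self.gene_b}"


def _junctions(seg_first, seg_second):
    """Breakpoint coordinates at the split between two query-ordered segments.

    The junction side of the earlier segment is its query end (ref_end on
    '+', ref_start on '-'); of the later segment, its query start.
    """
    ja = seg_first.ref_end if seg_first.strand == "+" else seg_first.ref_start
    jb = seg_second.ref_start if seg_second.strand == "+" else seg_second.ref_end
    return ja, jb


def call_fusions(anchored, config: RunConfig | None = None) -> list:
    """One call per gene pair and breakpoint cluster with sufficient support.

    Junction pairs are clustered with a 50-bp tolerance (imperfect
    double-strand-break repair leaves small indels at real breakpoints);
    a read anchored in three or more genes contributes to all its pairs.
    """
    config = config or RunConfig()
    tol = config.junction_tolerance
    by_pair: dict = {}
    for ar in anchored:
        best = {}
        for a in ar.anchors:             # longest anchor per gene
            if a.gene not in best or a.segment.aligned_query_len > best[a.gene].segment.aligned_query_len:
                best[a.gene] = a
        genes = sorted(best)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                ga, gb = genes[i], genes[j]
                sa, sb = best[ga].segment, best[gb].segment
                if sa.query_start <= sb.query_start:
                    ja, jb = _junctions(sa, sb)
                else:
                    jb, ja = _junctions(sb, sa)
                by_pair.setdefault((ga, gb), []).append(SupportingRead(
                    read_id=ar.read_id, junction_a=ja, junction_b=jb,
                    strand_a=sa.strand, strand_b=sb.strand,
                    channel=ar.channel, start_time=ar.start_time,
                    finish_time=ar.finish_time))

    calls = []
    for (ga, gb), supports in sorted(by_pair.items()):
        supports.sort(key=lambda s: (s.junction_a, s.junction_b, s.read_id))
        clusters: list = []
        for s in supports:
            placed = False
            for cl in clusters:
                if (abs(s.junction_a - median(x.junction_a for x in cl)) <= tol
                        and abs(s.junction_b - median(x.junction_b for x in cl)) <= tol):
                    cl.append(s)
                    placed = True
                    break
            if not placed:
                clusters.append([s])
        for cl in clusters:
            uniq = {s.read_id: s for s in cl}
            if len(uniq) < config.min_fusion_support:
                continue
            members = sorted(uniq.values(), key=lambda s: s.read_id)
            sa = max((s.strand_a for s in members),
                     key=[s.strand_a for s in members].count)
            sb = max((s.strand_b for s in members),
                     key=[s.strand_b for s in members].count)
            seg_a = next(a.segment for ar2 in anchored if ar2.read_id == members[0].read_id
                         for a in ar2.anchors if a.gene == ga)
            seg_b = next(a.segment for ar2 in anchored if ar2.read_id == members[0].read_id
                         for a in ar2.anchors if a.gene == gb)
            calls.append(FusionCall(
                gene_a=ga, gene_b=gb,
                chrom_a=seg_a.chrom, chrom_b=seg_b.chrom,
                breakpoint_a=int(median(s.junction_a for s in members)),
                breakpoint_b=int(median(s.junction_b for s in members)),
                strand_a=sa, strand_b=sb,
                support_count=len(members), supporting_reads=members))
    calls.sort(key=lambda c: (c.gene_a, c.gene_b, c.breakpoint_a))
    return calls


def fusion_orientation(call: FusionCall, panel: TargetPanel) -> FusionCall:
    """Annotate whether the junction preserves both genes' coding orientation.

    Reading along the fused molecule, gene A is traversed with its coding
    direction iff segment strand equals gene strand; likewise for B.  The
    junction is fusion-competent when both agree or both disagree (the
    latter is the same chimera read from the complementary strand).
    """
    try:
        strand_a = panel.get(call.gene_a).strand
        strand_b = panel.get(call.gene_b).strand
    except KeyError:
        call.orientation = "unknown"
        return call
    if strand_a not in "+-" or strand_b not in "+-":
        call.orientation = "unknown"
        return call
    along_a = call.strand_a == strand_a
    along_b = call.strand_b == strand_b
    call.orientation = "compatible" if along_a == along_b else "incompatible"
    return call
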