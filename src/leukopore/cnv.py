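"""Focal copy-number variation within panel genes: deletions from the
conjunction of a per-nucleotide depth drop and split-read junction
evidence, amplifications and iAMP21 from integer region-copy estimates.

Depth here is base-level coverage (unlike the karyotype's read-center
counting): within enriched regions adaptive sampling gives uniform full-
length reads, so per-base depth is informative again.  Copy estimates use
the same blast-fraction mixture as the karyotype:

    depth_region / depth_baseline = (2*(1-f) + f*n_region) / 2
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from .config import RunConfig
from .genome import GenomeModel


@dataclass
class FocalCNVCall:
    chrom: str
    start: int
    end: int
    kind: str                      # deletion / amplification
    copy_estimate: int             # region copies in the blast clone (deletion: copies lost)
    clonal_fraction: float         # fraction of blast cells carrying the event
    split_support: int
    depth_ratio: float             # region depth / flank depth
    low_confidence: bool = False
    focal: bool = True
    supporting_reads: tuple = ()


def pernuc_depth(reads, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base count of covering aligned segments over [start, end).

    Deletion gaps inside a CIGAR (D/N) do not contribute coverage; the gap
    between split segments of one read contributes nothing either.
    """
    from .smallvar import _parse_ext_cigar

    L = end - start
    delta = np.zeros(L + 1, dtype=np.int64)
    for read in reads:
        for seg in read.segments:
            if seg.chrom != chrom or seg.ref_end <= start or seg.ref_start >= end:
                continue
            if seg.cigar is None:
                s = max(seg.ref_start, start) - start
                e = min(seg.ref_end, end) - start
                delta[s] += 1
                delta[e] -= 1
                continue
            rp = seg.ref_start
            for op, ln in _parse_ext_cigar(seg.cigar):
                if op in "M=X":
                    s = max(rp, start) - start
                    e = min(rp + ln, end) - start
                    if e > s:
                        delta[s] += 1
                        delta[e] -= 1
                    rp += ln
                elif op in "DN":
                    rp += ln
    return np.cumsum(delta[:-1])


def _split_deletion_junctions(reads, chrom: str, start: int, end: int,
                              config: RunConfig):
    """Reference gaps between query-adjacent same-strand segments."""
    out = []
    for read in reads:
        segs = [s for s in read.segments if s.chrom == chrom]
        segs.sort(key=lambda s: s.query_start)
        for a, b in zip(segs[:-1], segs[1:]):
            if a.strand != b.strand:
                continue
            lo, hi = sorted([(a.ref_start, a.ref_end), (b.ref_start, b.ref_end)])
            gap_start, gap_end = lo[1], hi[0]
            if gap_end - gap_start < config.min_deletion_size:
                continue
            if b.query_start - a.query_end > config.max_query_gap:
                continue
            if gap_end <= start or gap_start >= end:
                continue
            out.append((gap_start, gap_end, read.read_id))
    return out


def _solve_clonal_fraction(ratio: float, f: float, n_c: int):
    """Best integer copy loss Delta and carrier fraction from a depth ratio.

    depth_in/depth_flank = (2(1-f) + f*(n_c - cf*Delta)) / (2(1-f) + f*n_c)
    inverted for cf; the smallest Delta with cf <= 1 is reported.
    """
    level = 2.0 * (1 - f) + f * n_c
    if f <= 0 or level <= 0 or n_c < 1:
        return 1, float("nan")
    for delta in range(1, n_c + 1):
        cf = (1.0 - ratio) * level / (f * delta)
        if cf <= 1.0 + 0.1:
            return delta, float(np.clip(cf, 0.0, 1.0))
    return n_c, float(np.clip((1.0 - ratio) * level / (f * n_c), 0.0, 1.0))


def call_focal_deletion(reads, region: tuple, karyotype_call,
                        config: RunConfig | None = None) -> list:
    """Deletions inside a panel region from depth plus split reads.

    Split junctions (same chromosome, same strand, reference gap >=
    min_deletion_size, query gap <= max_query_gap) are clustered with the
    junction tolerance; depth-only candidates are admitted when the drop
    matches a (near-)clonal integer copy loss.  Below 10x flanking depth
    both evidence types are required and the call is flagged
    low-confidence.
    """
    config = config or RunConfig()
    chrom, start, end = region
    f = karyotype_call.blast_fraction
    n_c = karyotype_call.copy_number.get(chrom, 2)
    depth = pernuc_depth(reads, chrom, start, end)

    junctions = _split_deletion_junctions(reads, chrom, start, end, config)
    junctions.sort()
    clusters: list = []
    tol = config.junction_tolerance
    for js, je, rid in junctions:
        placed = False
        for cl in clusters:
            if (abs(js - median(x[0] for x in cl)) <= tol
                    and abs(je - median(x[1] for x in cl)) <= tol):
                cl.append((js, je, rid))
                placed = True
                break
        if not placed:
            clusters.append([(js, je, rid)])

    candidates = []
    claimed = np.zeros(end - start, dtype=bool)
    for cl in clusters:
        ds = int(median(x[0] for x in cl))
        de = int(median(x[1] for x in cl))
        rids = sorted({x[2] for x in cl})
        candidates.append((ds, de, rids))
        claimed[max(0, ds - start):max(0, de - start)] = True

    # depth-only candidates: runs below the halfway level to one copy less
    level = 2.0 * (1 - f) + f * n_c
    drop_level = 2.0 * (1 - f) + f * max(n_c - 1, 0)
    overall = float(np.median(depth)) if depth.size else 0.0
    if overall > 0 and level > 0:
        thr = overall * (level + drop_level) / (2.0 * level)
        low = (depth < thr) & ~claimed
        i = 0
        L = end - start
        while i < L:
            if low[i]:
                j = i
                while j < L and low[j]:
                    j += 1
                if j - i >= config.min_deletion_size:
                    candidates.append((start + i, start + j, []))
                i = j
            else:
                i += 1

    calls = []
    for ds, de, rids in sorted(candidates):
        s_loc, e_loc = ds - start, de - start
        inside = depth[max(0, s_loc):max(0, e_loc)]
        flank_w = max(de - ds, 200)
        left = depth[max(0, s_loc - flank_w):max(0, s_loc)]
        right = depth[e_loc:e_loc + flank_w]
        flank = np.concatenate([left, right])
        if inside.size == 0 or flank.size == 0:
            continue
        d_in = float(np.mean(inside))
        d_flank = float(np.mean(flank))
        if d_flank <= 0:
            continue
        ratio = d_in / d_flank
        delta, cf = _solve_clonal_fraction(ratio, f, n_c)
        low_conf = d_flank < config.min_flank_depth
        split_support = len(rids)
        depth_consistent = np.isfinite(cf) and cf >= 0.8
        depth_drop = ratio < (level + drop_level) / (2.0 * level)
        if low_conf:
            qualifies = split_support >= 2 and depth_drop
        else:
            qualifies = split_support >= 2 or depth_consistent
        if not qualifies:
            continue
        calls.append(FocalCNVCall(
            chrom=chrom, start=ds, end=de, kind="deletion",
            copy_estimate=delta, clonal_fraction=cf,
            split_support=split_support, depth_ratio=ratio,
            low_confidence=low_conf, supporting_reads=tuple(rids)))
    return calls


def estimate_region_copies(reads, region: tuple, karyotype_call,
                           baseline_depth: float | None = None,
                           baseline_region: tuple | None = None,
                           config: RunConfig | None = None) -> int:
    """Integer copies of a region in the blast clone from relative depth.

    ``d_rel`` is region depth over the diploid-baseline depth (a supplied
    value, a supplied diploid region, or flanks within the same panel
    region as fallback); copies = round((2*d_rel - 2*(1-f)) / f), clipped
    to [0, region_copy_max].
    """
    config = config or RunConfig()
    chrom, start, end = region
    d_region = float(np.mean(pernuc_depth(reads, chrom, start, end)))
    if baseline_depth is None:
        if baseline_region is None:
            raise ValueError("no diploid baseline available: supply "
                             "baseline_depth or baseline_region")
        bc, bs, be = baseline_region
        baseline_depth = float(np.mean(pernuc_depth(reads, bc, bs, be)))
    if baseline_depth <= 0:
        raise ValueError("no diploid baseline available: baseline depth is zero")
    f = karyotype_call.blast_fraction
    d_rel = d_region / baseline_depth
    n = (2.0 * d_rel - 2.0 * (1 - f)) / f if f > 0 else 2.0 * d_rel / 2.0 * 2
    return int(np.clip(np.rint(n), 0, config.region_copy_max))


def call_focal_amplification(reads, region: tuple, karyotype_call,
                             baseline_depth: float | None = None,
                             baseline_region: tuple | None = None,
                             flank: int = 2_000,
                             config: RunConfig | None = None) -> FocalCNVCall | None:
    """Amplification call for a candidate region (copies >= 3, flanks lower)."""
    config = config or RunConfig()
    chrom, start, end = region
    copies = estimate_region_copies(reads, region, karyotype_call,
                                    baseline_depth=baseline_depth,
                                    baseline_region=baseline_region,
                                    config=config)
    if copies < 3:
        return None
    d_region = float(np.mean(pernuc_depth(reads, chrom, start, end)))
    left = pernuc_depth(reads, chrom, max(0, start - flank), start)
    right = pernuc_depth(reads, chrom, end, end + flank)
    flanks = np.concatenate([left, right])
    d_flank = float(np.mean(flanks)) if flanks.size else 0.0
    focal = d_flank < d_region
    return FocalCNVCall(
        chrom=chrom, start=start, end=end, kind="amplification",
        copy_estimate=copies, clonal_fraction=1.0, split_support=0,
        depth_ratio=d_region / d_flank if d_flank > 0 else float("inf"),
        focal=focal)


def flag_iamp21(runx1_copies: int, amplification_calls, chr21_call,
                genome: GenomeModel, runx1_region: tuple | None = None):
    """Intrachromosomal amplification of chromosome 21.

    True iff RUNX1 is present at four or more copies AND an amplification
    interval containing it is focal: shorter than the 21q arm with flanking
    depth below the amplified region.  Whole-chromosome polysomy without
    focal structure does not qualify.
    """
    if runx1_copies < 4:
        return False, f"RUNX1 at {runx1_copies} copies (<4)"
    q_start, q_end = genome.arms("chr21")["q"]
    q_len = q_end - q_start
    for call in amplification_calls:
        if call.chrom != "chr21" or call.kind != "amplification":
            continue
        if runx1_region is not None:
            _rc, rs, re_ = runx1_region
            if not (call.start <= rs and call.end >= re_):
                continue
        if (call.end - call.start) >= q_len:
            continue
        if not call.focal:
            continue
        return True, (f"RUNX1 at {runx1_copies} copies within focal "
                      f"amplification {call.chrom}:{call.start}-{call.end}")
    return False, (f"RUNX1 at {runx1_copies} copies but no focal "
                   "amplification interval contains it")
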