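"""Targeted consensus calling of SNVs, indels and FLT3-ITD.

Adaptive sampling leaves coverage too uneven for genome-wide nanopore SNV
callers, so calling is restricted to enriched regions and proceeds in two
passes: (1) a columnar pileup of the existing alignments builds a consensus
sequence — majority base per column, indels incorporated at or above the
reporting fraction; (2) every overlapping read is realigned to that
consensus (edit-distance alignment via edlib) and allele fractions are
re-measured before variants at or above the threshold are reported.  The
two-pass design exists because nanopore indels misalign against the raw
reference; realigning to a consensus that already carries the indel
recovers the true supporting fraction.

"MAF" here is the alternate-allele fraction: a homozygous variant at
fraction 1.0 is reported (a literal minor-allele reading would cap at 0.5).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import edlib
import numpy as np

from .config import RunConfig
from .reads import revcomp


@dataclass
class SmallVariant:
    chrom: str
    pos: int                       # 0-based reference coordinate (VCF-style anchor for indels)
    ref_allele: str
    alt_allele: str
    kind: str                      # SNV / insertion / deletion / ITD
    allele_fraction: float = 0.0
    depth: int = 0
    phase_group: int | None = None
    itd_interval: tuple | None = None
    alt_read_ids: frozenset = frozenset()
    ref_read_ids: frozenset = frozenset()

    def __post_init__(self):
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must be in [0, 1]")


@dataclass
class InSilicoPCRResult:
    """Virtual amplicon sizing between two primer sites, mimicking the
    capillary-electrophoresis FLT3-ITD assay."""

    amplicon_lengths: list
    wt_length: int
    itd_count: int
    wt_count: int
    allelic_ratio: float | None    # None with infinite=True when wt_count=0
    infinite: bool = False

    def to_dict(self) -> dict:
        return {
            "amplicon_lengths": list(self.amplicon_lengths),
            "wt_length": self.wt_length,
            "itd_count": self.itd_count,
            "wt_count": self.wt_count,
            "allelic_ratio": self.allelic_ratio,
            "infinite": self.infinite,
        }


def get_reference_seq(reference, chrom: str, start: int, end: int) -> str:
    """Region sequence from a dict of strings or a pysam.FastaFile."""
    if isinstance(reference, dict):
        return reference[chrom][start:end].upper()
    return reference.fetch(chrom, start, end).upper()


def _parse_ext_cigar(cig: str):
    ops = []
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def _aligned_chunk(read, seg):
    """The segment's read bases in reference orientation."""
    if read.seq is None:
        return None
    chunk = read.seq[seg.query_start:seg.query_end]
    return chunk if seg.strand == "+" else revcomp(chunk)


def consensus_of_sequences(seqs: list) -> str:
    """Majority-vote consensus of similar short sequences.

    Picks the medoid (minimum summed edit distance), aligns every sequence
    to it, and votes per medoid column including insertions.  Two polish
    rounds are enough at nanopore error rates when ~10+ copies are present.
    """
    seqs = [s for s in seqs if s]
    if not seqs:
        return ""
    if len(seqs) == 1:
        return seqs[0]
    sample = seqs[:30]
    dist_sums = []
    for s in sample:
        d = sum(edlib.align(s, t)["editDistance"] for t in sample)
        dist_sums.append(d)
    draft = sample[int(np.argmin(dist_sums))]
    for _ in range(2):
        cols = [collections.Counter() for _ in range(len(draft))]
        inserts = [collections.Counter() for _ in range(len(draft) + 1)]
        for s in seqs:
            res = edlib.align(s, draft, task="path")
            qi = ti = 0
            for op, ln in _parse_ext_cigar(res["cigar"]):
                if op in "=X":
                    for _k in range(ln):
                        cols[ti][s[qi]] += 1
                        qi += 1
                        ti += 1
                elif op == "I":
                    inserts[ti][s[qi:qi + ln]] += 1
                    qi += ln
                elif op == "D":
                    for _k in range(ln):
                        cols[ti][""] += 1
                        ti += 1
        half = len(seqs) / 2.0
        out = []
        for ti in range(len(draft)):
            ins, cnt = (inserts[ti].most_common(1) or [("", 0)])[0]
            if cnt > half:
                out.append(ins)
            best = cols[ti].most_common(1)
            if best and best[0][0]:
                out.append(best[0][0])
            elif not best:
                out.append(draft[ti])
        ins, cnt = (inserts[len(draft)].most_common(1) or [("", 0)])[0]
        if cnt > half:
            out.append(ins)
        new = "".join(out)
        if new == draft:
            break
        draft = new
    return draft


# --------------------------------------------------------------------------
# pass 1: pileup consensus
# --------------------------------------------------------------------------

@dataclass
class Candidate:
    kind: str                  # SNV / insertion / deletion
    ref_pos: int               # region-local start of the event
    ref_allele: str
    alt_allele: str
    pass1_fraction: float
    in_consensus: bool


@dataclass
class ConsensusResult:
    region: tuple              # (chrom, start, end)
    sequence: str
    cons_to_ref: np.ndarray    # consensus idx -> region-local ref pos (-1 = inserted)
    ref_to_cons: np.ndarray    # region-local ref pos -> consensus idx (-1 = deleted)
    candidates: list
    depth: np.ndarray          # per-column aligned depth
    n_reads: int


def build_consensus(reads, region: tuple, reference,
                    config: RunConfig | None = None) -> ConsensusResult:
    """Pass-1 consensus from the existing alignments.

    Substitution columns keep the majority base (a 0.4-fraction alternate
    would misalign the 0.6 majority in pass 2); insertions and deletions
    supported by at least ``maf_threshold`` of junction-spanning reads are
    incorporated, and every event at or above the threshold is recorded as
    a candidate for re-quantification.
    """
    config = config or RunConfig()
    chrom, start, end = region
    L = end - start
    ref = get_reference_seq(reference, chrom, start, end)
    if len(ref) < L:
        raise ValueError(f"reference shorter than region {region}")

    base_counts = [collections.Counter() for _ in range(L)]
    del_depth = np.zeros(L, dtype=np.int64)
    ins_events: dict = collections.defaultdict(list)
    n_reads = 0
    for read in reads:
        for seg in read.segments:
            if seg.chrom != chrom or seg.cigar is None:
                continue
            if seg.ref_end <= start or seg.ref_start >= end:
                continue
            chunk = _aligned_chunk(read, seg)
            if chunk is None:
                continue
            n_reads += 1
            rp = seg.ref_start
            qi = 0
            for op, ln in _parse_ext_cigar(seg.cigar):
                if op in "M=X":
                    for _k in range(ln):
                        if start <= rp < end:
                            base_counts[rp - start][chunk[qi]] += 1
                        rp += 1
                        qi += 1
                elif op == "I":
                    if start <= rp <= end:
                        ins_events[rp - start].append(chunk[qi:qi + ln])
                    qi += ln
                elif op in "DN":
                    for _k in range(ln):
                        if start <= rp < end:
                            del_depth[rp - start] += 1
                        rp += 1
            break   # one segment per read is enough for targeted regions

    depth = np.array([sum(c.values()) for c in base_counts]) + del_depth
    if n_reads == 0 or int(depth.max(initial=0)) < config.min_depth:
        raise ValueError(
            f"region {chrom}:{start}-{end} below min_depth "
            f"{config.min_depth} ({n_reads} overlapping reads)")

    maf = config.maf_threshold
    candidates: list = []
    cons_chars: list = []
    cons_to_ref: list = []
    ref_to_cons = np.full(L, -1, dtype=np.int64)

    # deletion runs at/above threshold
    del_frac = np.where(depth > 0, del_depth / np.maximum(depth, 1), 0.0)
    del_cols = del_frac >= maf
    deleted = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        if del_cols[i] and depth[i] >= config.min_depth:
            j = i
            while j < L and del_cols[j]:
                j += 1
            frac = float(np.mean(del_frac[i:j]))
            anchor = i - 1
            candidates.append(Candidate(
                kind="deletion", ref_pos=max(anchor, 0),
                ref_allele=ref[max(anchor, 0):j], alt_allele=ref[max(anchor, 0)],
                pass1_fraction=frac, in_consensus=True))
            deleted[i:j] = True
            i = j
        else:
            i += 1

    for p in range(L):
        # insertions before column p
        events = ins_events.get(p, [])
        jdepth = int(depth[p]) if p < L else int(depth[L - 1])
        if events and jdepth >= config.min_depth:
            frac = len(events) / jdepth
            if frac >= maf:
                ins_seq = consensus_of_sequences(events)
                if ins_seq:
                    candidates.append(Candidate(
                        kind="insertion", ref_pos=p,
                        ref_allele=ref[p - 1] if p > 0 else "",
                        alt_allele=(ref[p - 1] if p > 0 else "") + ins_seq,
                        pass1_fraction=frac, in_consensus=True))
                    for ch in ins_seq:
                        cons_chars.append(ch)
                        cons_to_ref.append(-1)
        if deleted[p]:
            continue
        counts = base_counts[p]
        col_depth = int(depth[p])
        if counts:
            best = counts.most_common(1)[0][0]
        else:
            best = ref[p]
        ref_to_cons[p] = len(cons_chars)
        cons_chars.append(best)
        cons_to_ref.append(p)
        if col_depth >= config.min_depth:
            for base, cnt in counts.items():
                if base != ref[p] and cnt / col_depth >= maf:
                    candidates.append(Candidate(
                        kind="SNV", ref_pos=p, ref_allele=ref[p],
                        alt_allele=base, pass1_fraction=cnt / col_depth,
                        in_consensus=(base == best)))

    candidates.sort(key=lambda c: (c.ref_pos, c.kind, c.alt_allele))
    return ConsensusResult(
        region=region, sequence="".join(cons_chars),
        cons_to_ref=np.array(cons_to_ref, dtype=np.int64),
        ref_to_cons=ref_to_cons, candidates=candidates,
        depth=depth, n_reads=n_reads)


# --------------------------------------------------------------------------
# pass 2: realign to consensus and re-quantify
# --------------------------------------------------------------------------

def _cons_index(cons: ConsensusResult, ref_pos: int) -> int:
    idx = cons.ref_to_cons[ref_pos] if 0 <= ref_pos < cons.ref_to_cons.size else -1
    if idx >= 0:
        return int(idx)
    later = cons.ref_to_cons[cons.ref_to_cons >= 0]
    pos_ok = np.flatnonzero((cons.cons_to_ref >= ref_pos))
    return int(pos_ok[0]) if pos_ok.size else len(cons.sequence)


def realign_and_call(reads, cons: ConsensusResult, region: tuple, reference,
                     config: RunConfig | None = None) -> list:
    """Realign overlapping reads to the pass-1 consensus and report
    variants (vs the original reference) at or above the threshold."""
    config = config or RunConfig()
    chrom, start, end = region
    maf = config.maf_threshold

    # per-read alignment to consensus: column bases, deletion spans, insertions
    read_alns = []
    for read in reads:
        for seg in read.segments:
            if seg.chrom != chrom or seg.cigar is None:
                continue
            if seg.ref_end <= start or seg.ref_start >= end:
                continue
            chunk = _aligned_chunk(read, seg)
            if chunk is None or not chunk:
                continue
            res = edlib.align(chunk, cons.sequence, mode="HW", task="path")
            if res["editDistance"] < 0 or not res.get("cigar"):
                continue
            t0 = res["locations"][0][0]
            cols = {}
            dels = []
            inss = {}
            qi = 0
            ti = t0
            for op, ln in _parse_ext_cigar(res["cigar"]):
                if op in "=X":
                    for _k in range(ln):
                        cols[ti] = chunk[qi]
                        qi += 1
                        ti += 1
                elif op == "I":
                    inss[ti] = inss.get(ti, "") + chunk[qi:qi + ln]
                    qi += ln
                elif op == "D":
                    dels.append((ti, ti + ln))
                    ti += ln
            read_alns.append({"read_id": read.read_id, "span": (t0, ti),
                              "cols": cols, "dels": dels, "ins": inss})
            break

    variants = []
    for cand in cons.candidates:
        ci = _cons_index(cons, cand.ref_pos)
        alt_ids, ref_ids = set(), set()
        if cand.kind == "SNV":
            for ra in read_alns:
                b = ra["cols"].get(ci)
                if b == cand.alt_allele:
                    alt_ids.add(ra["read_id"])
                elif b == cand.ref_allele:
                    ref_ids.add(ra["read_id"])
                elif b is None and any(s <= ci < e for s, e in ra["dels"]):
                    pass   # deleted in this read: neither allele
        elif cand.kind == "insertion":
            ins_len = len(cand.alt_allele) - len(cand.ref_allele)
            if cand.in_consensus:
                # consensus carries the inserted block; reads lacking it
                # align with a matching deletion
                blk_start = _ins_block_start(cons, cand)
                blk = (blk_start, blk_start + ins_len)
                # the aligner may scatter the matching deletion across a
                # tandem repeat; count deleted bases in a padded window
                pad = min(60, ins_len)
                win = (blk[0] - pad, blk[1] + pad)
                for ra in read_alns:
                    s, e = ra["span"]
                    if s > blk[0] - 1 or e < blk[1] + 1:
                        continue
                    del_cover = sum(max(0, min(de, win[1]) - max(ds, win[0]))
                                    for ds, de in ra["dels"])
                    if del_cover >= ins_len / 2:
                        ref_ids.add(ra["read_id"])
                    else:
                        alt_ids.add(ra["read_id"])
            else:
                for ra in read_alns:
                    s, e = ra["span"]
                    if s > ci - 1 or e < ci + 1:
                        continue
                    got = len(ra["ins"].get(ci, ""))
                    if got >= ins_len / 2:
                        alt_ids.add(ra["read_id"])
                    else:
                        ref_ids.add(ra["read_id"])
        elif cand.kind == "deletion":
            del_len = len(cand.ref_allele) - len(cand.alt_allele)
            if cand.in_consensus:
                # consensus lacks the block: carriers align cleanly, reads
                # with the block show an insertion at the junction
                junction = _cons_index(cons, cand.ref_pos + 1)
                for ra in read_alns:
                    s, e = ra["span"]
                    if s > junction - 1 or e < junction + 1:
                        continue
                    got = len(ra["ins"].get(junction, ""))
                    if got >= del_len / 2:
                        ref_ids.add(ra["read_id"])
                    else:
                        alt_ids.add(ra["read_id"])
            else:
                blk = (_cons_index(cons, cand.ref_pos + 1),
                       _cons_index(cons, cand.ref_pos + 1) + del_len)
                for ra in read_alns:
                    s, e = ra["span"]
                    if s > blk[0] - 1 or e < blk[1] + 1:
                        continue
                    del_cover = sum(max(0, min(de, blk[1]) - max(ds, blk[0]))
                                    for ds, de in ra["dels"])
                    if del_cover >= del_len / 2:
                        alt_ids.add(ra["read_id"])
                    else:
                        ref_ids.add(ra["read_id"])
        covered = len(alt_ids) + len(ref_ids)
        if covered == 0:
            continue
        frac = len(alt_ids) / covered
        if frac >= maf and covered >= config.min_depth:
            if cand.kind == "insertion":
                pos = start + max(cand.ref_pos - 1, 0)
            else:       # SNV at its column; deletion at its VCF anchor base
                pos = start + cand.ref_pos
            variants.append(SmallVariant(
                chrom=chrom, pos=pos,
                ref_allele=cand.ref_allele, alt_allele=cand.alt_allele,
                kind=cand.kind, allele_fraction=frac, depth=covered,
                alt_read_ids=frozenset(alt_ids), ref_read_ids=frozenset(ref_ids)))
    variants.sort(key=lambda v: (v.pos, v.kind, v.alt_allele))
    return variants


def _ins_block_start(cons: ConsensusResult, cand) -> int:
    """Consensus index where an in-consensus insertion block begins."""
    after = _cons_index(cons, cand.ref_pos)
    ins_len = len(cand.alt_allele) - len(cand.ref_allele)
    i = after - 1
    while i >= 0 and cons.cons_to_ref[i] == -1:
        i -= 1
    return i + 1


# --------------------------------------------------------------------------
# phasing
# --------------------------------------------------------------------------

def phase_variants(variants: list, config: RunConfig | None = None) -> list:
    """Group variants occurring on the same haplotype.

    Two variants share a phase group iff at least ``phase_concordance`` of
    reads covering both carry both-or-neither alternate allele, with at
    least ``phase_min_reads`` co-covering reads; transitive closure via
    union-find.  Variants with no phased partner keep a null group.
    """
    config = config or RunConfig()
    n = len(variants)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    linked = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = variants[i], variants[j]
            cov_i = vi.alt_read_ids | vi.ref_read_ids
            cov_j = vj.alt_read_ids | vj.ref_read_ids
            both = cov_i & cov_j
            if len(both) < config.phase_min_reads:
                continue
            concord = sum(1 for r in both
                          if (r in vi.alt_read_ids) == (r in vj.alt_read_ids))
            if concord / len(both) >= config.phase_concordance:
                pi, pj = find(i), find(j)
                parent[pi] = pj
                linked[i] = linked[j] = True

    groups: dict = {}
    out = []
    next_id = 1
    for i, v in enumerate(variants):
        if not linked[i]:
            out.append(v)
            continue
        root = find(i)
        if root not in groups:
            groups[root] = next_id
            next_id += 1
        out.append(SmallVariant(
            chrom=v.chrom, pos=v.pos, ref_allele=v.ref_allele,
            alt_allele=v.alt_allele, kind=v.kind,
            allele_fraction=v.allele_fraction, depth=v.depth,
            phase_group=groups[root], itd_interval=v.itd_interval,
            alt_read_ids=v.alt_read_ids, ref_read_ids=v.ref_read_ids))
    return out


# --------------------------------------------------------------------------
# FLT3-ITD
# --------------------------------------------------------------------------

def detect_itd(consensus: str, reference, region: tuple,
               config: RunConfig | None = None) -> SmallVariant | None:
    """Classify a consensus insertion as an internal tandem duplication.

    The consensus is aligned globally to the reference region; insertion
    runs (which a unit-cost aligner may scatter across a tandem repeat) are
    merged within a 60-nt reference window, and each merged event of >=9 nt
    is re-extracted exactly by a local prefix/suffix diff.  An insertion
    whose sequence matches the immediately adjacent reference segment
    (upstream or downstream) at >=80% identity is an ITD; the duplicated
    reference interval and its length are reported.  Returns the longest
    qualifying event, or None.
    """
    config = config or RunConfig()
    chrom, start, end = region
    ref = get_reference_seq(reference, chrom, start, end)
    res = edlib.align(consensus, ref, mode="NW", task="path")
    runs = []                     # (q_start, t_pos, length)
    qi = ti = 0
    for op, ln in _parse_ext_cigar(res["cigar"]):
        if op in "=X":
            qi += ln
            ti += ln
        elif op == "D":
            ti += ln
        elif op == "I":
            runs.append((qi, ti, ln))
            qi += ln
    # merge insertion runs the aligner scattered across a repeat
    clusters: list = []
    for q0, t0, ln in runs:
        if clusters and t0 - clusters[-1][-1][1] <= 60:
            clusters[-1].append((q0, t0, ln))
        else:
            clusters.append([(q0, t0, ln)])

    best: SmallVariant | None = None
    for cl in clusters:
        total = sum(ln for _q, _t, ln in cl)
        if total < 9:
            continue
        t_lo, t_hi = cl[0][1], cl[-1][1]
        q_lo = cl[0][0]
        q_hi = cl[-1][0] + cl[-1][2]
        # local exact diff: expand a window and trim the common prefix and
        # suffix; what remains in the consensus window is the insertion
        w = 3 * total + 50
        r0 = max(0, t_lo - w)
        r1 = min(len(ref), t_hi + w)
        c0 = max(0, q_lo - (t_lo - r0))
        c1 = min(len(consensus), q_hi + (r1 - t_hi))
        rw = ref[r0:r1]
        cw = consensus[c0:c1]
        dlen = len(cw) - len(rw)
        if dlen < 9:
            continue
        p = 0
        while p < min(len(rw), len(cw)) and rw[p] == cw[p]:
            p += 1
        sfx = 0
        while (sfx < min(len(rw), len(cw))
               and rw[len(rw) - 1 - sfx] == cw[len(cw) - 1 - sfx]):
            sfx += 1
        sfx = min(sfx, len(rw) - p, len(cw) - p)
        ins = cw[p:len(cw) - sfx]
        ln_ins = len(ins)
        if ln_ins != dlen:
            # residual substitutions in the window; fall back to the
            # length difference with the aligner's placement
            ins = consensus[q_lo:q_lo + total]
            ln_ins = total
        t_abs = r0 + p
        cand_interval = None
        for anchor_seq, interval in (
                (ref[max(0, t_abs - ln_ins):t_abs], (start + t_abs - ln_ins, start + t_abs)),
                (ref[t_abs:t_abs + ln_ins], (start + t_abs, start + t_abs + ln_ins))):
            if len(anchor_seq) < ln_ins:
                continue
            dist = edlib.align(ins, anchor_seq)["editDistance"]
            if dist >= 0 and 1.0 - dist / ln_ins >= config.itd_min_identity:
                cand_interval = interval
                break
        if cand_interval is not None and (
                best is None or ln_ins > len(best.alt_allele) - 1):
            anchor = ref[t_abs - 1] if t_abs > 0 else ref[0]
            best = SmallVariant(
                chrom=chrom, pos=start + max(t_abs - 1, 0),
                ref_allele=anchor, alt_allele=anchor + ins,
                kind="ITD", itd_interval=cand_interval)
    return best


# --------------------------------------------------------------------------
# in silico PCR
# --------------------------------------------------------------------------

def _best_hit(seq: str, primer: str, max_edits: int):
    res = edlib.align(primer, seq, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    return s, e + 1        # half-open

def _scan(seq: str, fwd: str, rev_rc: str, max_edits: int):
    hf = _best_hit(seq, fwd, max_edits)
    hr = _best_hit(seq, rev_rc, max_edits)
    if hf is None or hr is None:
        return None
    if hf[1] > hr[0]:      # sites out of order
        return None
    return hr[1] - hf[0]   # inclusive outer span


def insilico_pcr(reads, fwd_primer: str, rev_primer: str, reference,
                 region: tuple | None = None,
                 config: RunConfig | None = None) -> InSilicoPCRResult:
    """Virtual PCR: reads containing both primer sites sized as amplicons.

    Each read is scanned in both orientations for the forward primer and
    the reverse complement of the reverse primer at up to
    ``max_primer_edits`` edit distance; the amplicon is the inclusive span
    between the outer primer ends.  Reads gaining at least ``itd_min_gain``
    nt over the reference amplicon count as ITD, reads within the gain
    window of the reference length as wild type; the allelic ratio is
    ITD/WT.
    """
    config = config or RunConfig()
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primer sequences must be >= 15 nt")
    fwd = fwd_primer.upper()
    rev_rc = revcomp(rev_primer.upper())

    if region is not None:
        ref_seq = get_reference_seq(reference, *region)
    elif isinstance(reference, str):
        ref_seq = reference.upper()
    else:
        raise ValueError("reference region required to size the wild-type amplicon")
    wt = _scan(ref_seq, fwd, rev_rc, config.max_primer_edits)
    if wt is None:
        raise ValueError("primer sites not found in the reference region")

    lengths = []
    for read in reads:
        if read.seq is None:
            continue
        span = _scan(read.seq.upper(), fwd, rev_rc, config.max_primer_edits)
        if span is None:
            span = _scan(revcomp(read.seq.upper()), fwd, rev_rc,
                         config.max_primer_edits)
        if span is not None:
            lengths.append(int(span))

    gain = config.itd_min_gain
    itd = sum(1 for ln in lengths if ln >= wt + gain)
    wtc = sum(1 for ln in lengths if abs(ln - wt) < gain)
    if wtc == 0:
        return InSilicoPCRResult(amplicon_lengths=lengths, wt_length=wt,
                                 itd_count=itd, wt_count=0,
                                 allelic_ratio=None, infinite=itd > 0)
    return InSilicoPCRResult(amplicon_lengths=lengths, wt_length=wt,
                             itd_count=itd, wt_count=wtc,
                             allelic_ratio=itd / wtc)
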