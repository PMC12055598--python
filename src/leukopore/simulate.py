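"""Synthetic nanopore adaptive-sampling runs with known ground truth.

Generates aligned reads — channels, start/finish timestamps, adaptive
ejection, duplex-strand artifacts, split fusion/deletion molecules, and
sequence-level reads carrying SNVs and tandem duplications — directly from a
truth model, so every pipeline stage is testable at desk scale without
external data.  Alignments are emitted from the truth (CIGARs composed from
the known edit script plus the per-base error process), not recomputed by an
aligner; an optional mode writes a BAM with the metadata tags a real run
would carry.

Molecule sampling follows the copy-number mixture: a locus with blast copy
number n in a specimen of blast fraction f is sampled with density
proportional to N_normal*(1-f) + f*n, which is exactly the signal the
digital karyotype reads out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeModel, TargetPanel
from .reads import AlignmentSegment, ReadRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# --------------------------------------------------------------------------
# truth model
# --------------------------------------------------------------------------

@dataclass
class FusionTruth:
    gene_a: str
    chrom_a: str
    breakpoint_a: int
    gene_b: str
    chrom_b: str
    breakpoint_b: int
    strand_a: str = "+"
    strand_b: str = "+"
    n_molecules: int = 5


@dataclass
class DeletionTruth:
    chrom: str
    start: int
    end: int
    clonal_fraction: float = 1.0     # fraction of blast cells carrying it


@dataclass
class TruthModel:
    genome: GenomeModel
    blast_fraction: float = 1.0
    copy_numbers: dict = field(default_factory=dict)     # chrom -> blast copies
    arm_copy: dict = field(default_factory=dict)         # (chrom, 'p'|'q') -> copies
    sex: str = "XY"
    fusions: list = field(default_factory=list)
    deletions: list = field(default_factory=list)
    read_count: int = 50_000
    read_len_median: float = 8_000.0
    read_len_sigma: float = 0.6
    min_read_len: int = 300
    sequencing_rate: float = 400.0   # nt/s
    run_length: float = 14_400.0     # s
    channel_count: int = 512
    duplex_prob: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.blast_fraction <= 1.0:
            raise ValueError("blast_fraction must be in [0, 1]")
        lengths = self.genome.lengths
        for d in self.deletions:
            if d.chrom not in lengths or not 0 <= d.start < d.end <= lengths[d.chrom]:
                raise ValueError(f"deletion {d} outside genome")
            if not 0.0 <= d.clonal_fraction <= 1.0:
                raise ValueError("clonal_fraction must be in [0, 1]")
        for fz in self.fusions:
            for chrom, bp in ((fz.chrom_a, fz.breakpoint_a), (fz.chrom_b, fz.breakpoint_b)):
                if chrom not in lengths or not 0 <= bp < lengths[chrom]:
                    raise ValueError(f"fusion breakpoint {chrom}:{bp} outside genome")

    def normal_copies(self, chrom: str) -> int:
        if chrom == "chrX":
            return 1 if self.sex == "XY" else 2
        if chrom == "chrY":
            return 1 if self.sex == "XY" else 0
        return 2

    def blast_copies(self, chrom: str, arm: str | None = None) -> int:
        if arm is not None and (chrom, arm) in self.arm_copy:
            return self.arm_copy[(chrom, arm)]
        return self.copy_numbers.get(chrom, self.normal_copies(chrom))


@dataclass
class AdaptiveSamplingParams:
    """Physical model of adaptive-sampling ejection.

    A decision is made after ~1 s of data (the decision prefix); rejected
    molecules leave the pore with a total sequenced length in the eject
    range (~600-700 nt), while on-target molecules (overlapping the panel
    padded by its margin) are sequenced to full length.
    """

    decision_prefix: int = 450
    eject_len_range: tuple = (600, 700)

    def __post_init__(self):
        lo, hi = self.eject_len_range
        if not (self.decision_prefix <= lo <= hi <= self.decision_prefix + 400):
            raise ValueError("eject_len_range must lie within "
                             "[decision_prefix, decision_prefix + 400]")


# --------------------------------------------------------------------------
# read-level simulation (no sequences)
# --------------------------------------------------------------------------

def _read_lengths(truth: TruthModel, n: int, rng) -> np.ndarray:
    lens = rng.lognormal(np.log(truth.read_len_median), truth.read_len_sigma, n)
    return np.maximum(lens.astype(np.int64), truth.min_read_len)


def simulate_reads(truth: TruthModel, panel: TargetPanel | None = None,
                   adaptive: AdaptiveSamplingParams | None = None,
                   seed: int = 0):
    """Generate ReadRecords (no sequences) plus a truth-info dict.

    Background molecules are sampled arm-by-arm with copy-number-mixture
    weights; deletion-carrying haplotypes reroute spanning molecules into
    split alignments; fusion molecules are injected explicitly; duplex
    artifacts are appended last.
    """
    rng = np.random.default_rng(seed)
    f = truth.blast_fraction

    # partition each chromosome into p / centromere / q with its own weight
    parts = []       # (chrom, start, end, weight_density)
    for chrom, length in truth.genome.chromosomes:
        arms = truth.genome.arms(chrom)
        cen = truth.genome.centromere(chrom) or (length // 2, length // 2)
        nn = truth.normal_copies(chrom)
        for tag, (s, e) in (("p", arms["p"]), ("cen", cen), ("q", arms["q"])):
            if e <= s:
                continue
            nb = truth.blast_copies(chrom, None if tag == "cen" else tag)
            dens = nn * (1 - f) + f * nb
            parts.append((chrom, s, e, dens))
    w = np.array([(e - s) * d for _, s, e, d in parts], dtype=float)
    if w.sum() <= 0:
        raise ValueError("degenerate truth: zero total sampling weight")
    p = w / w.sum()

    n = truth.read_count
    part_idx = rng.choice(len(parts), size=n, p=p)
    u = rng.random(n)
    lens = _read_lengths(truth, n, rng)
    channels = rng.integers(1, truth.channel_count + 1, n)
    starts = rng.uniform(0.0, truth.run_length, n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    eject = None
    if adaptive is not None:
        lo, hi = adaptive.eject_len_range
        eject = rng.integers(lo, hi + 1, n)

    del_by_chrom: dict = {}
    for d in truth.deletions:
        del_by_chrom.setdefault(d.chrom, []).append(d)

    lengths = truth.genome.lengths
    reads: list = []
    truth_info = {"deletion_read_ids": [], "fusion_read_ids": {},
                  "duplex_twins": []}
    for i in range(n):
        chrom, s, e, dens = parts[part_idx[i]]
        pos = int(s + u[i] * (e - s))
        length = int(lens[i])
        if panel is not None and adaptive is not None:
            if not panel.on_target(chrom, pos, pos + length):
                length = min(length, int(eject[i]))
        end = min(pos + length, lengths[chrom])
        length = end - pos
        if length <= 0:
            continue
        rid = f"read{i:07d}"
        segments = None
        # deletion haplotype rerouting
        for d in del_by_chrom.get(chrom, []):
            nb = truth.blast_copies(chrom)
            p_hap = f * d.clonal_fraction / dens if dens > 0 else 0.0
            if pos < d.end and end > d.start and rng.random() < p_hap:
                segments = _deletion_segments(d, chrom, pos, length,
                                              strands[i], lengths[chrom])
                if segments and len(segments) > 1:
                    truth_info["deletion_read_ids"].append(rid)
                break
        if segments is None:
            segments = [AlignmentSegment(
                chrom=chrom, ref_start=pos, ref_end=end, strand=str(strands[i]),
                query_start=0, query_end=length, aligned_query_len=length)]
        qlen = sum(sg.query_end - sg.query_start for sg in segments)
        reads.append(ReadRecord(
            read_id=rid, read_len=qlen, segments=segments,
            channel=int(channels[i]), start_time=float(starts[i]),
            duration=qlen / truth.sequencing_rate))

    # fusion molecules
    for fz in truth.fusions:
        ids = []
        for j in range(fz.n_molecules):
            length = int(max(2_000, _read_lengths(truth, 1, rng)[0]))
            split = int(length * rng.uniform(0.3, 0.7))
            rid = f"fusion_{fz.gene_a}_{fz.gene_b}_{j:03d}"
            seg_a = _approach_segment(fz.chrom_a, fz.breakpoint_a, fz.strand_a,
                                      split, 0, lengths[fz.chrom_a])
            seg_b = _depart_segment(fz.chrom_b, fz.breakpoint_b, fz.strand_b,
                                    length - split, split, lengths[fz.chrom_b])
            reads.append(ReadRecord(
                read_id=rid, read_len=length, segments=[seg_a, seg_b],
                channel=int(rng.integers(1, truth.channel_count + 1)),
                start_time=float(rng.uniform(0.0, truth.run_length)),
                duration=length / truth.sequencing_rate))
            ids.append(rid)
        truth_info["fusion_read_ids"][f"{fz.gene_a}::{fz.gene_b}"] = ids

    if truth.duplex_prob > 0:
        reads.extend(_duplex_twins(reads, truth, rng, truth_info))

    truth_info["n_reads"] = len(reads)
    return reads, truth_info


def _deletion_segments(d: DeletionTruth, chrom, pos, length, strand, chrom_len):
    """Split a carrier molecule across the deleted interval."""
    if pos >= d.start:
        if pos < d.end:
            # the carrier haplotype has no sequence here: no molecule
            return []
        return [AlignmentSegment(chrom=chrom, ref_start=pos,
                                 ref_end=min(pos + length, chrom_len),
                                 strand=str(strand), query_start=0,
                                 query_end=min(pos + length, chrom_len) - pos,
                                 aligned_query_len=min(pos + length, chrom_len) - pos)]
    part1 = d.start - pos
    if part1 >= length:
        return [AlignmentSegment(chrom=chrom, ref_start=pos, ref_end=pos + length,
                                 strand=str(strand), query_start=0, query_end=length,
                                 aligned_query_len=length)]
    part2 = min(length - part1, chrom_len - d.end)
    segs = [AlignmentSegment(chrom=chrom, ref_start=pos, ref_end=d.start,
                             strand=str(strand), query_start=0, query_end=part1,
                             aligned_query_len=part1)]
    if part2 > 0:
        segs.append(AlignmentSegment(
            chrom=chrom, ref_start=d.end, ref_end=d.end + part2,
            strand=str(strand), query_start=part1, query_end=part1 + part2,
            aligned_query_len=part2, is_primary=False))
    return segs


def _approach_segment(chrom, bp, strand, span, q_start, chrom_len):
    if strand == "+":
        s, e = max(0, bp - span), bp
    else:
        s, e = bp, min(chrom_len, bp + span)
    span = e - s
    return AlignmentSegment(chrom=chrom, ref_start=s, ref_end=e, strand=strand,
                            query_start=q_start, query_end=q_start + span,
                            aligned_query_len=span)


def _depart_segment(chrom, bp, strand, span, q_start, chrom_len):
    if strand == "+":
        s, e = bp, min(chrom_len, bp + span)
    else:
        s, e = max(0, bp - span), bp
    span = e - s
    return AlignmentSegment(chrom=chrom, ref_start=s, ref_end=e, strand=strand,
                            query_start=q_start, query_end=q_start + span,
                            aligned_query_len=span, is_primary=False)


def _duplex_twins(reads, truth: TruthModel, rng, truth_info) -> list:
    """Complementary-strand near-duplicates on the same channel.

    Models duplex pairs the basecaller failed to collapse: the complement
    follows the template through the same pore, so the twin shares the
    channel and starts within the duplex window.
    """
    twins = []
    flip = {"+": "-", "-": "+"}
    for r in reads:
        if rng.random() >= truth.duplex_prob:
            continue
        segs = [AlignmentSegment(
            chrom=s.chrom, ref_start=s.ref_start, ref_end=s.ref_end,
            strand=flip[s.strand], query_start=s.query_start,
            query_end=s.query_end, aligned_query_len=s.aligned_query_len,
            is_primary=s.is_primary) for s in r.segments]
        start = (r.start_time or 0.0) + float(rng.uniform(2.0, 25.0))
        twin = ReadRecord(read_id=r.read_id + "_dx", read_len=r.read_len,
                          segments=segs, channel=r.channel,
                          start_time=start, duration=r.duration,
                          seq=revcomp(r.seq) if r.seq else None)
        twins.append(twin)
        truth_info["duplex_twins"].append((r.read_id, twin.read_id))
    return twins


# --------------------------------------------------------------------------
# sequence-level simulation (targeted regions)
# --------------------------------------------------------------------------

def random_reference(chrom_lengths: dict, seed: int = 0) -> dict:
    """Deterministic random reference sequences, one string per chromosome."""
    out = {}
    for chrom in sorted(chrom_lengths):
        rng = np.random.default_rng([seed, abs(hash(chrom)) % (2**31)])
        out[chrom] = rng.choice(_BASES, size=chrom_lengths[chrom]).tobytes().decode()
    return out


class Haplotype:
    """A region haplotype: reference plus an ordered set of variants.

    Events (0-based, region-local ref coordinates):
      ("snv", pos, alt_base), ("ins", pos, seq) inserted before pos,
      ("del", start, end).  A tandem duplication of [a, b) is
      ("ins", b, ref[a:b]).
    """

    def __init__(self, ref_seq: str, events=()):
        self.ref = ref_seq
        self.events = sorted(events, key=lambda e: e[1])
        self.ops: list = []       # (op, ref_len_or_seq) with op in M/I/D
        self.seq = self._build()

    def _build(self) -> str:
        pieces = []
        cursor = 0
        buf = []

        def flush_match(upto):
            nonlocal cursor
            if upto > cursor:
                seg = list(self.ref[cursor:upto])
                buf.append(("M", upto - cursor, seg))
                cursor = upto

        for ev in self.events:
            kind = ev[0]
            if kind == "snv":
                _, pos, alt = ev
                flush_match(pos)
                buf.append(("M", 1, [alt]))
                cursor = pos + 1
            elif kind == "ins":
                _, pos, seq = ev
                flush_match(pos)
                buf.append(("I", len(seq), list(seq)))
            elif kind == "del":
                _, s, e = ev
                flush_match(s)
                buf.append(("D", e - s, None))
                cursor = e
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        flush_match(len(self.ref))

        # merge adjacent M blocks into single ops, keep I/D boundaries
        for op, ln, seq in buf:
            if seq is not None:
                pieces.extend(seq)
            if self.ops and self.ops[-1][0] == op == "M":
                prev = self.ops.pop()
                self.ops.append(("M", prev[1] + ln))
            else:
                self.ops.append((op, ln))
        return "".join(pieces)


def _extract_read(hap: Haplotype, h_start: int, h_len: int):
    """Project hap[h_start : h_start+h_len) onto the reference.

    Returns (ref_start, cigar_ops, seq) where cigar_ops is a list of
    (op, length) in M/I/D over the extracted window.
    """
    h_end = min(h_start + h_len, len(hap.seq))
    ops_out: list = []
    ref_pos = 0
    q_pos = 0
    ref_start = None
    for op, ln in hap.ops:
        if op == "M":
            take_s = max(h_start, q_pos)
            take_e = min(h_end, q_pos + ln)
            if take_e > take_s:
                if ref_start is None:
                    ref_start = ref_pos + (take_s - q_pos)
                ops_out.append(("M", take_e - take_s))
            ref_pos += ln
            q_pos += ln
        elif op == "I":
            take_s = max(h_start, q_pos)
            take_e = min(h_end, q_pos + ln)
            if take_e > take_s:
                if ref_start is None:
                    ref_start = ref_pos
                ops_out.append(("I", take_e - take_s))
            q_pos += ln
        else:  # D
            if h_start < q_pos < h_end or (q_pos == h_start and ops_out):
                if ops_out:           # deletions only between aligned blocks
                    ops_out.append(("D", ln))
            ref_pos += ln
        if q_pos >= h_end:
            break
    # trim trailing D
    while ops_out and ops_out[-1][0] == "D":
        ops_out.pop()
    seq = hap.seq[h_start:h_end]
    return ref_start if ref_start is not None else 0, _merge_ops(ops_out), seq


def _merge_ops(ops):
    out = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def _apply_errors(seq: str, ops, rng, p_sub: float, p_ins: float, p_del: float):
    """Per-base error process applied to (seq, cigar) jointly.

    Substitutions leave the CIGAR untouched; insertion errors add 1-nt I
    ops; deletion errors turn an M base into D (or shorten an I).
    """
    bases = "ACGT"
    new_seq = []
    new_ops = []
    qi = 0
    for op, ln in ops:
        if op == "D":
            new_ops.append(("D", ln))
            continue
        for _ in range(ln):
            base = seq[qi]
            qi += 1
            r = rng.random()
            if r < p_del:
                if op == "M":
                    new_ops.append(("D", 1))
                continue
            if r < p_del + p_sub:
                base = bases[(bases.index(base) + rng.integers(1, 4)) % 4] \
                    if base in bases else base
            new_seq.append(base)
            new_ops.append((op, 1))
            if rng.random() < p_ins:
                new_seq.append(bases[rng.integers(0, 4)])
                new_ops.append(("I", 1))
    # trim leading/trailing D
    merged = _merge_ops(new_ops)
    while merged and merged[0][0] == "D":
        merged.pop(0)
    while merged and merged[-1][0] == "D":
        merged.pop()
    return "".join(new_seq), merged


def cigar_string(ops) -> str:
    return "".join(f"{ln}{op}" for op, ln in ops)


def parse_cigar(cig: str):
    ops = []
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def simulate_region_reads(ref_seq: str, chrom: str, region_start: int,
                          hap_events: dict, hap_fractions: dict,
                          n_reads: int, read_len_mean: float = 3_000.0,
                          error_sub: float = 0.01, error_ins: float = 0.005,
                          error_del: float = 0.005, seed: int = 0,
                          sequencing_rate: float = 400.0,
                          channel_count: int = 512,
                          run_length: float = 14_400.0) -> list:
    """Sequence-bearing reads over one target region.

    ``ref_seq`` is the region's reference sequence (region-local coordinate
    0 maps to ``region_start`` on ``chrom``); ``hap_events`` maps haplotype
    id to its event list and ``hap_fractions`` to molecule fractions.
    """
    rng = np.random.default_rng(seed)
    haps = {h: Haplotype(ref_seq, evs) for h, evs in hap_events.items()}
    hids = sorted(hap_fractions)
    pvec = np.array([hap_fractions[h] for h in hids], dtype=float)
    pvec = pvec / pvec.sum()
    reads = []
    for i in range(n_reads):
        h = hids[int(rng.choice(len(hids), p=pvec))]
        hap = haps[h]
        length = int(np.clip(rng.normal(read_len_mean, read_len_mean / 4),
                             300, len(hap.seq)))
        start = int(rng.integers(0, max(1, len(hap.seq) - length + 1)))
        ref_off, ops, seq = _extract_read(hap, start, length)
        seq, ops = _apply_errors(seq, ops, rng, error_sub, error_ins, error_del)
        if not seq or not ops:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        ref_len = sum(ln for op, ln in ops if op in "MD")
        q_len = len(seq)
        seg = AlignmentSegment(
            chrom=chrom, ref_start=region_start + ref_off,
            ref_end=region_start + ref_off + ref_len, strand=strand,
            query_start=0, query_end=q_len,
            aligned_query_len=sum(ln for op, ln in ops if op == "M"),
            cigar=cigar_string(ops))
        reads.append(ReadRecord(
            read_id=f"rread{i:05d}_h{h}", read_len=q_len, segments=[seg],
            channel=int(rng.integers(1, channel_count + 1)),
            start_time=float(rng.uniform(0.0, run_length)),
            duration=q_len / sequencing_rate,
            seq=seq if strand == "+" else revcomp(seq)))
    return reads


# --------------------------------------------------------------------------
# enrichment expectation and BAM output
# --------------------------------------------------------------------------

def expected_enrichment(truth: TruthModel,
                        adaptive: AdaptiveSamplingParams | None) -> float:
    """Analytic fold enrichment of on-target base coverage.

    On-target molecules are sequenced to full length, ejected molecules to
    the eject range, so base-coverage enrichment is the ratio of mean kept
    to mean ejected length (molecule sampling itself stays uniform — that is
    the whole point of read-center counting).
    """
    if adaptive is None:
        return 1.0
    mean_kept = truth.read_len_median * float(np.exp(truth.read_len_sigma ** 2 / 2))
    mean_ejected = float(np.mean(adaptive.eject_len_range))
    return mean_kept / mean_ejected


def write_bam(reads, genome: GenomeModel, path, reference: dict | None = None,
              config=None) -> None:
    """Write ReadRecords as a coordinate-unsorted BAM with ch/st/du tags."""
    import pysam

    ch_tag = getattr(config, "channel_tag", "ch")
    st_tag = getattr(config, "time_tag", "st")
    du_tag = getattr(config, "duration_tag", "du")
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": l} for c, l in genome.chromosomes]}
    tid = {c: i for i, (c, _) in enumerate(genome.chromosomes)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            segs = r.segments or []
            sa_parts = []
            for s in segs:
                cig = s.cigar or f"{s.query_end - s.query_start}M"
                sa_parts.append(f"{s.chrom},{s.ref_start + 1},{s.strand},{cig},60,0")
            for idx, s in enumerate(segs):
                a = pysam.AlignedSegment()
                a.query_name = r.read_id
                a.reference_id = tid[s.chrom]
                a.reference_start = s.ref_start
                a.mapping_quality = 60
                flag = 0
                if s.strand == "-":
                    flag |= 16
                if idx > 0:
                    flag |= 2048
                a.flag = flag
                left = s.query_start
                right = r.read_len - s.query_end
                if s.strand == "-":
                    left, right = right, left
                core = s.cigar or f"{s.query_end - s.query_start}M"
                clip = "H" if idx > 0 else "S"
                cig = ""
                if left:
                    cig += f"{left}{clip}"
                cig += core
                if right:
                    cig += f"{right}{clip}"
                a.cigarstring = cig
                if r.seq is not None and idx == 0:
                    a.query_sequence = r.seq if s.strand == "+" else revcomp(r.seq)
                tags = []
                if r.channel is not None:
                    tags.append((ch_tag, int(r.channel)))
                if r.start_time is not None:
                    tags.append((st_tag, float(r.start_time)))
                if r.duration is not None:
                    tags.append((du_tag, float(r.duration)))
                if len(segs) > 1:
                    others = [sa_parts[j] for j in range(len(segs)) if j != idx]
                    tags.append(("SA", ";".join(others) + ";"))
                a.set_tags(tags)
                bam.write(a)


def simulate_run(truth: TruthModel, out_dir,
                 panel: TargetPanel | None = None,
                 adaptive: AdaptiveSamplingParams | None = None,
                 seed: int = 0, config=None) -> dict:
    """Simulate a run and write BAM + truth JSON into ``out_dir``.

    Returns the truth-info dict.  Identical inputs (including seed) yield
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads, info = simulate_reads(truth, panel=panel, adaptive=adaptive, seed=seed)
    write_bam(reads, truth.genome, out_dir / "run.bam", config=config)
    info_out = {
        "seed": seed,
        "blast_fraction": truth.blast_fraction,
        "sex": truth.sex,
        "copy_numbers": dict(truth.copy_numbers),
        "arm_copy": {f"{c}:{a}": v for (c, a), v in truth.arm_copy.items()},
        "fusions": [f"{fz.gene_a}::{fz.gene_b}" for fz in truth.fusions],
        "deletions": [[d.chrom, d.start, d.end, d.clonal_fraction]
                      for d in truth.deletions],
        "n_reads": info["n_reads"],
        "fusion_read_ids": info["fusion_read_ids"],
        "deletion_read_ids": info["deletion_read_ids"],
        "duplex_twins": info["duplex_twins"],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(info_out, fh, indent=1, sort_keys=True)
    return info_out
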