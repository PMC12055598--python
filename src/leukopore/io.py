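"""Readers and writers for the pipeline's external formats.

BAM/SAM via pysam (primary + supplementary records merged into one
ReadRecord per molecule), BED3/BED4 panels and masks, VCF 4.2 for small
variants (the single 0-based -> 1-based conversion point), BEDPE + TSV for
fusions, JSON for karyotype and timing reports.
"""

from __future__ import annotations

import json
import logging
import re
from datetime import datetime
from pathlib import Path

import pysam

from .config import RunConfig
from .genome import GenomeModel, MaskSet, PanelGene, TargetPanel
from .reads import AlignmentSegment, ReadRecord, revcomp

log = logging.getLogger(__name__)

_QUERY_CONSUMING = set("MIS=X")
_REF_CONSUMING = set("MDN=X")


def _parse_time(value) -> float | None:
    """Seconds from a float/int or an ISO-8601 timestamp."""
    if value is None:
        return None
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value)
    try:
        return float(s)
    except ValueError:
        pass
    try:
        return datetime.fromisoformat(s.replace("Z", "+00:00")).timestamp()
    except ValueError:
        return None


_KV_RE = re.compile(r"(\w+)=([^\s;]+)")


def parse_ont_metadata(text: str, config: RunConfig | None = None) -> dict:
    """key=value pairs from an ONT-style FASTQ description or read name.

    Recognizes ``ch=``, ``start_time=`` and ``duration=`` tokens (real runs
    embed them in the FASTQ header; some pipelines carry them into the read
    name or a CO tag).
    """
    out = {}
    for key, val in _KV_RE.findall(text or ""):
        if key == "ch":
            try:
                out["channel"] = int(val)
            except ValueError:
                pass
        elif key == "start_time":
            t = _parse_time(val)
            if t is not None:
                out["start_time"] = t
        elif key == "duration":
            t = _parse_time(val)
            if t is not None:
                out["duration"] = t
    return out


def _segment_from_alignment(aln) -> AlignmentSegment:
    cig = aln.cigartuples or []
    ops = "MIDNSHP=XB"
    qlen = sum(l for op, l in cig if ops[op] in _QUERY_CONSUMING)
    qlen += sum(l for op, l in cig if ops[op] == "H")
    left = 0
    for op, l in cig:
        if ops[op] in "SH":
            left += l
        else:
            break
    right = 0
    for op, l in reversed(cig):
        if ops[op] in "SH":
            right += l
        else:
            break
    aligned = sum(l for op, l in cig if ops[op] in "M=X")
    q_span = sum(l for op, l in cig if ops[op] in "MI=X")
    if aln.is_reverse:
        q_start = right
    else:
        q_start = left
    core = "".join(f"{l}{ops[op]}" for op, l in cig if ops[op] not in "SH")
    return AlignmentSegment(
        chrom=aln.reference_name,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        query_start=q_start,
        query_end=q_start + q_span,
        aligned_query_len=aligned,
        cigar=core,
        is_primary=not aln.is_supplementary,
    )


def load_alignments(bam_path, config: RunConfig | None = None,
                    genome: GenomeModel | None = None) -> list:
    """One ReadRecord per physical molecule from a BAM/SAM file.

    Primary and supplementary alignments sharing a read name merge into one
    record's segments; secondary alignments are discarded.  Channel, start
    time and duration come from the configured tags (default ch/st/du) or
    from ONT key=value metadata in the name/CO tag; when duration is absent
    it falls back to read_len / sequencing_rate (~400 nt per second of pore
    time).  Reads with missing channel/time metadata are retained with null
    metadata (warned once) and excluded only from duplex- and
    time-dependent analyses.
    """
    config = config or RunConfig()
    path = str(bam_path)
    mode = "r" if path.endswith(".sam") else "rb"
    by_name: dict = {}
    try:
        bam = pysam.AlignmentFile(path, mode, check_sq=False)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read alignment file {path!r}: {exc}") from exc

    warned_missing = False
    with bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_secondary:
                continue
            entry = by_name.setdefault(aln.query_name, {
                "segments": [], "channel": None, "start_time": None,
                "duration": None, "seq": None, "read_len": 0})
            if not aln.is_unmapped:
                try:
                    entry["segments"].append(_segment_from_alignment(aln))
                except ValueError as exc:
                    raise ValueError(
                        f"malformed alignment for read {aln.query_name!r} "
                        f"in {path!r}: {exc}") from exc
            qlen = aln.infer_read_length() or (
                len(aln.query_sequence) if aln.query_sequence else 0)
            entry["read_len"] = max(entry["read_len"], qlen or 0)
            if not aln.is_supplementary and aln.query_sequence:
                seq = aln.query_sequence
                entry["seq"] = revcomp(seq) if aln.is_reverse else seq
            meta = {}
            if aln.has_tag(config.channel_tag):
                meta["channel"] = int(aln.get_tag(config.channel_tag))
            if aln.has_tag(config.time_tag):
                t = _parse_time(aln.get_tag(config.time_tag))
                if t is not None:
                    meta["start_time"] = t
            if aln.has_tag(config.duration_tag):
                meta["duration"] = float(aln.get_tag(config.duration_tag))
            fallback_text = aln.query_name
            if aln.has_tag("CO"):
                fallback_text += " " + str(aln.get_tag("CO"))
            for key, val in parse_ont_metadata(fallback_text, config).items():
                meta.setdefault(key, val)
            for key in ("channel", "start_time", "duration"):
                if meta.get(key) is not None and entry[key] is None:
                    entry[key] = meta[key]

    reads = []
    for name, e in sorted(by_name.items()):
        duration = e["duration"]
        if duration is None and e["start_time"] is not None:
            duration = e["read_len"] / config.sequencing_rate
        if (e["channel"] is None or e["start_time"] is None) and not warned_missing:
            log.warning("some reads lack channel/time metadata; they are "
                        "excluded from duplex and timing analyses only")
            warned_missing = True
        reads.append(ReadRecord(
            read_id=name, read_len=e["read_len"],
            segments=sorted(e["segments"], key=lambda s: s.query_start),
            channel=e["channel"], start_time=e["start_time"],
            duration=duration, seq=e["seq"]))
    return reads


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------

def load_bed(path, genome: GenomeModel | None = None, kind: str = "auto",
             panel_margin: int = 50_000, anchor_margin: int = 5_000):
    """Parse a BED3/BED4(+strand) file into a TargetPanel or MaskSet.

    ``kind`` is "panel", "mask" or "auto" (panel iff a 4th name column is
    present on every line).  Intervals are validated against the genome
    when one is supplied; errors name the offending line.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            if genome is not None:
                if chrom not in genome.lengths:
                    raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
                if end > genome.length(chrom):
                    raise ValueError(
                        f"{path}:{ln}: interval end {end} beyond "
                        f"{chrom} length {genome.length(chrom)}")
            name = parts[3] if len(parts) > 3 else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            rows.append((chrom, start, end, name, strand))

    if kind == "auto":
        kind = "panel" if rows and all(r[3] for r in rows) else "mask"
    if kind == "panel":
        missing = [i for i, r in enumerate(rows) if not r[3]]
        if missing:
            raise ValueError(f"{path}: panel BED requires a name column "
                             f"(missing on data line {missing[0] + 1})")
        entries = [PanelGene(gene=r[3], chrom=r[0], start=r[1], end=r[2],
                             strand=r[4]) for r in rows]
        panel = TargetPanel(entries=entries, panel_margin=panel_margin,
                            anchor_margin=anchor_margin)
        if genome is not None:
            panel.validate_against(genome)
        return panel
    mask = MaskSet()
    for chrom, start, end, _name, _strand in rows:
        mask.add(chrom, start, end)
    return mask


def write_bed(panel_or_mask, path) -> None:
    with open(path, "w") as fh:
        if isinstance(panel_or_mask, TargetPanel):
            for e in panel_or_mask.entries:
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.gene}\t0\t{e.strand}\n")
        else:
            for chrom in panel_or_mask.chromosomes():
                for s, e in panel_or_mask.intervals(chrom):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">
##INFO=<ID=PS,Number=1,Type=Integer,Description="Phase group (variants sharing a value are in cis)">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="ITD for internal tandem duplications">
##INFO=<ID=ITDLEN,Number=1,Type=Integer,Description="Duplicated segment length">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants, path) -> None:
    """SmallVariants as VCF 4.2; internal 0-based coordinates shift to
    1-based POS here and nowhere else."""
    lines = []
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt_allele)):
        info = [f"AF={v.allele_fraction:.4f}", f"DP={v.depth}"]
        if v.phase_group is not None:
            info.append(f"PS={v.phase_group}")
        if v.kind == "ITD":
            info.append("SVTYPE=ITD")
            if v.itd_interval is not None:
                info.append(f"ITDLEN={v.itd_interval[1] - v.itd_interval[0]}")
        lines.append(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                     f"\t.\tPASS\t{';'.join(info)}")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_vcf(path) -> list:
    """Re-parse a VCF written by :func:`write_vcf` into SmallVariants."""
    from .smallvar import SmallVariant

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=") for kv in info.split(";") if "=" in kv)
            kind = "ITD" if fields.get("SVTYPE") == "ITD" else (
                "SNV" if len(ref) == len(alt) == 1 else
                ("insertion" if len(alt) > len(ref) else "deletion"))
            out.append(SmallVariant(
                chrom=chrom, pos=int(pos) - 1, ref_allele=ref, alt_allele=alt,
                kind=kind, allele_fraction=float(fields["AF"]),
                depth=int(fields["DP"]),
                phase_group=int(fields["PS"]) if "PS" in fields else None))
    return out


def write_fusions(calls, bedpe_path, tsv_path=None, json_path=None) -> None:
    with open(bedpe_path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.gene_a, c.gene_b, c.breakpoint_a)):
            fh.write(f"{c.chrom_a}\t{max(0, c.breakpoint_a - 1)}\t{c.breakpoint_a + 1}"
                     f"\t{c.chrom_b}\t{max(0, c.breakpoint_b - 1)}\t{c.breakpoint_b + 1}"
                     f"\t{c.name}\t{c.support_count}\t{c.strand_a}\t{c.strand_b}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("gene_a\tgene_b\tchrom_a\tbreakpoint_a\tchrom_b\tbreakpoint_b"
                     "\tstrand_a\tstrand_b\tsupport\torientation\tdetection_time_s"
                     "\tread_ids\n")
            for c in sorted(calls, key=lambda c: (c.gene_a, c.gene_b, c.breakpoint_a)):
                dt = "" if c.detection_time is None else f"{c.detection_time:.1f}"
                rids = ",".join(s.read_id for s in c.supporting_reads)
                fh.write(f"{c.gene_a}\t{c.gene_b}\t{c.chrom_a}\t{c.breakpoint_a}"
                         f"\t{c.chrom_b}\t{c.breakpoint_b}\t{c.strand_a}\t{c.strand_b}"
                         f"\t{c.support_count}\t{c.orientation}\t{dt}\t{rids}\n")
    if json_path is not None:
        payload = [{
            "gene_a": c.gene_a, "gene_b": c.gene_b,
            "chrom_a": c.chrom_a, "chrom_b": c.chrom_b,
            "breakpoint_a": c.breakpoint_a, "breakpoint_b": c.breakpoint_b,
            "strand_a": c.strand_a, "strand_b": c.strand_b,
            "support_count": c.support_count,
            "orientation": c.orientation,
            "detection_time": c.detection_time,
            "supporting_reads": [{
                "read_id": s.read_id, "junction_a": s.junction_a,
                "junction_b": s.junction_b, "channel": s.channel,
                "start_time": s.start_time, "finish_time": s.finish_time,
                "strand_a": s.strand_a, "strand_b": s.strand_b,
            } for s in c.supporting_reads],
        } for c in sorted(calls, key=lambda c: (c.gene_a, c.gene_b, c.breakpoint_a))]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def read_fusions_json(path) -> list:
    from .fusion import FusionCall, SupportingRead

    with open(path) as fh:
        payload = json.load(fh)
    calls = []
    for d in payload:
        calls.append(FusionCall(
            gene_a=d["gene_a"], gene_b=d["gene_b"],
            chrom_a=d["chrom_a"], chrom_b=d["chrom_b"],
            breakpoint_a=d["breakpoint_a"], breakpoint_b=d["breakpoint_b"],
            strand_a=d["strand_a"], strand_b=d["strand_b"],
            support_count=d["support_count"], orientation=d["orientation"],
            detection_time=d["detection_time"],
            supporting_reads=[SupportingRead(
                read_id=s["read_id"], junction_a=s["junction_a"],
                junction_b=s["junction_b"], strand_a=s["strand_a"],
                strand_b=s["strand_b"], channel=s["channel"],
                start_time=s["start_time"], finish_time=s["finish_time"],
            ) for s in d["supporting_reads"]]))
    return calls


def karyotype_to_dict(call, genome: GenomeModel) -> dict:
    return {
        "iscn": call.iscn(genome),
        "total_count": call.total_count,
        "sex": call.sex,
        "aneuploidy_class": call.aneuploidy_class,
        "blast_fraction": call.blast_fraction,
        "per_copy_depth": call.per_copy_depth,
        "copy_number": dict(call.copy_number),
        "arm_events": [{
            "chrom": e.chrom, "arm": e.arm, "copies": e.copies,
            "delta": e.delta, "ks_p": e.ks_p, "divergence": e.divergence,
        } for e in call.arm_events],
        "residual": call.residual,
        "low_confidence": call.low_confidence,
        "notes": list(call.notes),
    }


def write_cnv_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tcopy_estimate\tclonal_fraction"
                 "\tsplit_support\tdepth_ratio\tlow_confidence\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end)):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\t{c.copy_estimate}"
                     f"\t{c.clonal_fraction:.3f}\t{c.split_support}"
                     f"\t{c.depth_ratio:.3f}\t{int(c.low_confidence)}\n")


def write_reports(out_dir, genome: GenomeModel, karyotype=None, fusions=None,
                  cnvs=None, variants=None, pcr=None, timeline=None) -> dict:
    """Write every supplied call set under ``out_dir`` with deterministic
    field order; returns the mapping of report name to path."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {out_dir}: {exc}") from exc
    written = {}
    if karyotype is not None:
        d = karyotype_to_dict(karyotype, genome)
        p = out_dir / "karyotype.json"
        with open(p, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
        t = out_dir / "karyotype.txt"
        with open(t, "w") as fh:
            fh.write(d["iscn"] + "\n")
            fh.write(f"class: {d['aneuploidy_class']}\n")
            fh.write(f"blast fraction: {d['blast_fraction']:.2f}\n")
        written["karyotype"] = p
    if fusions is not None:
        write_fusions(fusions, out_dir / "fusions.bedpe",
                      out_dir / "fusions.tsv", out_dir / "fusions.json")
        written["fusions"] = out_dir / "fusions.bedpe"
    if cnvs is not None:
        write_cnv_tsv(cnvs, out_dir / "cnv.tsv")
        with open(out_dir / "cnv.bed", "w") as fh:
            for c in sorted(cnvs, key=lambda c: (c.chrom, c.start, c.end)):
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\n")
        written["cnv"] = out_dir / "cnv.tsv"
    if variants is not None:
        write_vcf(variants, out_dir / "smallvar.vcf")
        written["smallvar"] = out_dir / "smallvar.vcf"
    if pcr is not None:
        with open(out_dir / "insilico_pcr.json", "w") as fh:
            json.dump(pcr.to_dict(), fh, indent=1, sort_keys=True)
        with open(out_dir / "insilico_pcr.tsv", "w") as fh:
            fh.write("amplicon_length\n")
            for ln in pcr.amplicon_lengths:
                fh.write(f"{ln}\n")
        written["insilico_pcr"] = out_dir / "insilico_pcr.json"
    if timeline is not None:
        with open(out_dir / "timeline.json", "w") as fh:
            json.dump(timeline, fh, indent=1, sort_keys=True)
        written["timeline"] = out_dir / "timeline.json"
    return written
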