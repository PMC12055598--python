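"""Read-level domain types: one sequenced molecule and its (split) alignments."""

from __future__ import annotations

from dataclasses import dataclass, field

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(slots=True)
class AlignmentSegment:
    """One aligned block of a read (a primary or supplementary alignment).

    ``query_start``/``query_end`` are positions in the read's original
    orientation; ``aligned_query_len`` counts read bases aligned to the
    reference (CIGAR M/=/X), which is the quantity tested against the
    500-nt anchoring rule.
    """

    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    query_start: int
    query_end: int
    aligned_query_len: int
    cigar: str | None = None
    is_primary: bool = True

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        if self.query_start >= self.query_end:
            raise ValueError("query_start must be < query_end")
        if self.aligned_query_len > self.query_end - self.query_start:
            raise ValueError("aligned_query_len exceeds query span")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def ref_mid(self) -> int:
        return (self.ref_start + self.ref_end) // 2


@dataclass(slots=True)
class ReadRecord:
    """One physical molecule: id, channel/time metadata, split alignments.

    ``channel``/``start_time`` may be ``None`` when the source lacked
    metadata; such reads participate in every static call but are skipped by
    duplex collapsing (treated as independent) and by timing analyses.
    """

    read_id: str
    read_len: int
    segments: list = field(default_factory=list)
    channel: int | None = None
    start_time: float | None = None
    duration: float | None = None
    seq: str | None = None

    def __post_init__(self):
        if self.duration is not None and self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def finish_time(self) -> float | None:
        if self.start_time is None or self.duration is None:
            return None
        return self.start_time + self.duration

    @property
    def has_time(self) -> bool:
        return self.start_time is not None and self.duration is not None

    def longest_segment(self) -> AlignmentSegment | None:
        if not self.segments:
            return None
        return max(self.segments, key=lambda s: s.aligned_query_len)

    def center(self):
        """(chrom, position) of the longest segment's reference midpoint.

        The longest segment (not the whole-read span) anchors the molecule so
        split fusion reads never double-count in the binned depth profile.
        """
        seg = self.longest_segment()
        if seg is None:
            return None
        return seg.chrom, seg.ref_mid
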