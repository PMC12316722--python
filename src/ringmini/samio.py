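"""SAM-backed alignment records.

Reading goes through :mod:`pysam`; writing emits plain-text SAM directly so
that a fixed simulation seed yields a byte-identical stream.  Only the
fields the pipeline consumes are modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_reference_span(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string."""
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in "MDN=X")


def cigar_left_clip(cigar: str) -> int:
    m = re.match(r"^(\d+)[SH]", cigar)
    return int(m.group(1)) if m else 0


def cigar_right_clip(cigar: str) -> int:
    m = re.search(r"(\d+)[SH]$", cigar)
    return int(m.group(1)) if m else 0


@dataclass
class AlignmentRecord:
    """One mapped read segment — possibly one of several segments of a split read."""

    qname: str
    flag: int
    chrom: str
    pos: int  # 1-based leftmost mapped position
    mapq: int
    cigar: str
    seq: str
    rnext: str = "="
    pnext: int = 0
    tlen: int = 0
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_primary(self) -> bool:
        return not (self.is_unmapped or self.is_secondary or self.is_supplementary)

    @property
    def mate_ordinal(self) -> int:
        """0 for an unpaired/first read, 1 for the second of a pair."""
        return 1 if self.flag & FLAG_SECOND else 0

    @property
    def end(self) -> int:
        """1-based inclusive rightmost mapped position."""
        return self.pos + cigar_reference_span(self.cigar) - 1

    @property
    def left_clip(self) -> int:
        return cigar_left_clip(self.cigar)

    def to_sam_line(self) -> str:
        tags = "".join(f"\t{k}:Z:{v}" for k, v in sorted(self.tags.items()))
        qual = "I" * len(self.seq)
        return (
            f"{self.qname}\t{self.flag}\t{self.chrom}\t{self.pos}\t{self.mapq}\t"
            f"{self.cigar}\t{self.rnext}\t{self.pnext}\t{self.tlen}\t{self.seq}\t{qual}{tags}"
        )


def write_sam(
    records: list[AlignmentRecord],
    path: str | Path,
    chrom_lengths: dict[str, int],
) -> None:
    """Write records as plain-text SAM with an @HD/@SQ header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for rec in records:
            fh.write(rec.to_sam_line() + "\n")


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read mapped records from a SAM file via pysam.

    Malformed optional fields are ignored; unmapped records are skipped.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            tags = {}
            try:
                sa = aln.get_tag("SA")
                tags["SA"] = str(sa)
            except KeyError:
                pass
            out.append(
                AlignmentRecord(
                    qname=aln.query_name or "",
                    flag=aln.flag,
                    chrom=aln.reference_name,
                    pos=aln.reference_start + 1,
                    mapq=aln.mapping_quality,
                    cigar=aln.cigarstring or f"{len(aln.query_sequence or '')}M",
                    seq=aln.query_sequence or "",
                    rnext="=" if aln.next_reference_id == aln.reference_id else (aln.next_reference_name or "*"),
                    pnext=(aln.next_reference_start + 1) if aln.next_reference_start >= 0 else 0,
                    tlen=aln.template_length,
                    tags=tags,
                )
            )
    return out


def chrom_lengths_from_sam(path: str | Path) -> dict[str, int]:
    """@SQ chromosome lengths of a SAM file."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return dict(zip(fh.references, fh.lengths))
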