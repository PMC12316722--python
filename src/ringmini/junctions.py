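"""Novel DNA junction discovery from split-read alignments.

A read whose alignment is split between two reference loci at least
``min_separation`` apart (default 2000 bp, or any inter-chromosomal split)
is evidence for a novel adjacency.  Evidence is clustered into candidate
junctions, which must then clear two filters: a per-sample minimum support
derived from "pseudo-junctions" (ordinary bin boundaries, whose mean
crossing coverage halved estimates the support expected of a single-copy
true junction), and carrier exclusivity (support in at least one carrier,
complete absence from every control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import numpy as np
from scipy import stats

from .mini import orientation_of
from .samio import AlignmentRecord

logger = logging.getLogger(__name__)

MIN_SEPARATION = 2000  # bp between split segments for a novel junction
PSEUDO_JUNCTION_BIN = 5000  # bin size whose boundaries act as pseudo-junctions


@dataclass(frozen=True)
class Breakpoint:
    """One side of a junction; ``side`` is the retained flank."""

    chrom: str
    pos: int
    side: str  # "left" | "right"


@dataclass
class SplitReadEvidence:
    """One split read supporting a putative adjacency of two loci."""

    read_id: str
    sample_id: str
    segment_a: tuple[str, int, int, int]  # chrom, start, end, strand
    segment_b: tuple[str, int, int, int]
    breakpoint_a: Breakpoint
    breakpoint_b: Breakpoint

    @property
    def orientation(self) -> str:
        return orientation_of(self.breakpoint_a.side, self.breakpoint_b.side)


@dataclass
class CandidateJunction:
    """A clustered candidate adjacency with per-sample support."""

    breakpoint_a: Breakpoint
    breakpoint_b: Breakpoint
    orientation: str
    evidence: list[SplitReadEvidence] = field(default_factory=list)
    carrier_exclusive: bool | None = None
    above_threshold: bool | None = None
    validated: bool | None = None

    @property
    def support(self) -> int:
        return len(self.evidence)

    def support_by_sample(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.evidence:
            out[ev.sample_id] = out.get(ev.sample_id, 0) + 1
        return out

    @property
    def accepted(self) -> bool:
        return bool(self.carrier_exclusive) and bool(self.above_threshold)


def _segment_breakpoint(rec: AlignmentRecord, read_end: str) -> Breakpoint:
    """Breakpoint implied by the clipped end of one split segment.

    ``read_end`` says which end of the *sequenced read* abuts the junction:
    "end" for the segment read first, "start" for the segment read next.
    """
    fwd = not rec.is_reverse
    if read_end == "end":
        # junction follows this segment in read order
        return (
            Breakpoint(rec.chrom, rec.end, "left")
            if fwd
            else Breakpoint(rec.chrom, rec.pos, "right")
        )
    return (
        Breakpoint(rec.chrom, rec.pos, "right")
        if fwd
        else Breakpoint(rec.chrom, rec.end, "left")
    )


def _read_order_key(rec: AlignmentRecord) -> int:
    """Offset of the mapped segment within the sequenced read."""
    return rec.left_clip if not rec.is_reverse else len(rec.seq) - (rec.left_clip + _mapped_len(rec))


def _mapped_len(rec: AlignmentRecord) -> int:
    return rec.end - rec.pos + 1


def extract_split_alignments(
    alignments: list[AlignmentRecord],
    min_separation: int = MIN_SEPARATION,
    sample_id: str = "sample",
) -> list[SplitReadEvidence]:
    """Collect split reads whose segments map ``>= min_separation`` apart.

    Segments of one read (primary + supplementaries sharing the read id and
    mate) are ordered by their offset in the sequenced read; each
    consecutive pair whose breakpoint loci are at least ``min_separation``
    apart (boundary inclusive) or on different chromosomes yields one
    evidence item, with breakpoints at the clipped segment ends.
    """
    by_read: dict[tuple[str, int], list[AlignmentRecord]] = {}
    skipped = 0
    for rec in alignments:
        if rec.is_secondary or rec.is_unmapped:
            continue
        if not rec.seq or rec.pos <= 0:
            skipped += 1
            continue
        by_read.setdefault((rec.qname, rec.mate_ordinal), []).append(rec)
    if skipped:
        logger.warning("skipped %d records without sequence/position", skipped)

    out: list[SplitReadEvidence] = []
    for (read_id, mate), recs in by_read.items():
        if len(recs) < 2:
            continue
        recs = sorted(recs, key=_read_order_key)
        for a, b in zip(recs, recs[1:]):
            bp_a = _segment_breakpoint(a, "end")
            bp_b = _segment_breakpoint(b, "start")
            if bp_a.chrom == bp_b.chrom and abs(bp_a.pos - bp_b.pos) < min_separation:
                continue
            out.append(
                SplitReadEvidence(
                    read_id=f"{read_id}/{mate + 1}",
                    sample_id=sample_id,
                    segment_a=(a.chrom, a.pos, a.end, -1 if a.is_reverse else 1),
                    segment_b=(b.chrom, b.pos, b.end, -1 if b.is_reverse else 1),
                    breakpoint_a=bp_a,
                    breakpoint_b=bp_b,
                )
            )
    return out


def _canonical_pair(ev: SplitReadEvidence) -> tuple[Breakpoint, Breakpoint]:
    a, b = ev.breakpoint_a, ev.breakpoint_b
    return (a, b) if (a.chrom, a.pos, a.side) <= (b.chrom, b.pos, b.side) else (b, a)


def cluster_evidence(
    evidence: list[SplitReadEvidence],
    tolerance: int = 10,
) -> list[CandidateJunction]:
    """Merge evidence agreeing within ``tolerance`` bp on both breakpoints.

    Evidence must share orientation and breakpoint sides; the candidate
    position is the median of member positions on each side.
    """
    groups: dict[tuple, list[tuple[tuple[Breakpoint, Breakpoint], SplitReadEvidence]]] = {}
    for ev in evidence:
        a, b = _canonical_pair(ev)
        key = (a.chrom, a.side, b.chrom, b.side)
        groups.setdefault(key, []).append(((a, b), ev))

    out: list[CandidateJunction] = []
    for (chrom_a, side_a, chrom_b, side_b), members in groups.items():
        members.sort(key=lambda m: (m[0][0].pos, m[0][1].pos))
        clusters: list[list[tuple[tuple[Breakpoint, Breakpoint], SplitReadEvidence]]] = []
        for pair, ev in members:
            placed = False
            for cl in clusters:
                ref_a = median(p[0].pos for p, _ in cl)
                ref_b = median(p[1].pos for p, _ in cl)
                if abs(pair[0].pos - ref_a) <= tolerance and abs(pair[1].pos - ref_b) <= tolerance:
                    cl.append((pair, ev))
                    placed = True
                    break
            if not placed:
                clusters.append([(pair, ev)])
        for cl in clusters:
            pos_a = int(round(median(p[0].pos for p, _ in cl)))
            pos_b = int(round(median(p[1].pos for p, _ in cl)))
            bp_a = Breakpoint(chrom_a, pos_a, side_a)
            bp_b = Breakpoint(chrom_b, pos_b, side_b)
            out.append(
                CandidateJunction(
                    breakpoint_a=bp_a,
                    breakpoint_b=bp_b,
                    orientation=orientation_of(side_a, side_b),
                    evidence=[ev for _, ev in cl],
                )
            )
    out.sort(key=lambda c: (c.breakpoint_a.chrom, c.breakpoint_a.pos, c.breakpoint_b.pos))
    return out


def pseudo_junction_threshold(
    alignments: list[AlignmentRecord],
    chrom_lengths: dict[str, int],
    bin_size: int = PSEUDO_JUNCTION_BIN,
) -> float:
    """Minimum cross-junction support from ordinary bin-boundary coverage.

    Boundaries between consecutive bins act as pseudo-junctions; the mean
    count of primary alignments spanning a boundary, divided by 2 (the
    genome is diploid but a novel junction affects one copy), is the
    support floor a real single-copy junction should reach.
    """
    if not chrom_lengths or all(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("zero-length genome")
    spans = 0
    n_boundaries = 0
    boundary_counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        nb = max(0, (length - 1) // bin_size)
        n_boundaries += nb
        boundary_counts[chrom] = np.zeros(nb, dtype=np.int64)
    if n_boundaries == 0:
        raise ValueError("no internal bin boundaries; genome shorter than one bin")
    for rec in alignments:
        if not rec.is_primary:
            continue
        counts = boundary_counts.get(rec.chrom)
        if counts is None:
            continue
        # boundary k sits between bases k*bin_size and k*bin_size+1
        first = rec.pos // bin_size + (0 if rec.pos % bin_size == 0 else 1)
        last = (rec.end - 1) // bin_size
        if first <= last:
            counts[first - 1 : last] += 1
        spans += max(0, last - first + 1)
    return spans / n_boundaries / 2.0


def filter_junctions(
    candidates: list[CandidateJunction],
    carrier_ids: set[str],
    control_ids: set[str],
    threshold: float | dict[str, float],
) -> list[CandidateJunction]:
    """Apply carrier-exclusivity and minimum-support filters.

    A candidate is accepted iff its support reaches the (per-sample or
    global) threshold in at least one carrier AND it has zero supporting
    reads in every control.  Flags are set on all candidates; the accepted
    subset is returned.
    """
    if not control_ids:
        logger.warning("no control samples: carrier-exclusivity passes vacuously")
    accepted = []
    for cand in candidates:
        support = cand.support_by_sample()
        cand.carrier_exclusive = all(support.get(c, 0) == 0 for c in control_ids)
        cand.above_threshold = any(
            support.get(c, 0)
            >= (threshold[c] if isinstance(threshold, dict) else threshold)
            for c in carrier_ids
        )
        if cand.accepted:
            accepted.append(cand)
    return accepted


def orientation_chisq(junctions: list[CandidateJunction]) -> tuple[float, float]:
    """Chi-square goodness of fit of orientations against uniformity.

    Counts over the three joining-orientation classes are compared with a
    uniform expectation (df = 2); returns (statistic, upper-tail p).
    """
    if not junctions:
        raise ValueError("orientation test undefined for zero junctions")
    classes = ("head_to_tail", "tail_to_tail", "head_to_head")
    counts = np.array([sum(1 for j in junctions if j.orientation == c) for c in classes])
    stat, p = stats.chisquare(counts)
    return float(stat), float(p)
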