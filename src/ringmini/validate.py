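"""In-silico validation of candidate junctions.

Cross-junction reads are assembled into a contig with a deterministic
greedy overlap assembler (reads are short and essentially error-free, and
each contig spans a single junction, so a full OLC assembler is not
needed).  A junction is validated when the two ends of its contig align to
the expected reference flanks, in the expected orientation; a contig that
aligns contiguously to a single locus is a false candidate.  Finally,
diagnostic SNPs covered by the junction's reads assign the junction to the
mini haplotype or the background genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .junctions import Breakpoint, CandidateJunction
from .mini import revcomp
from .samio import AlignmentRecord


@dataclass
class Contig:
    """Assembled cross-junction contig and its reference end-alignments."""

    sequence: str
    read_ids: list[str]
    fragmentary: bool = False
    validated: bool | None = None
    end_alignments: list[tuple[str, int, int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HaplotypeCall:
    """Haplotype of origin of a junction, from diagnostic SNP alleles."""

    call: str  # mini_haplotype | background | indeterminate
    informative_snps: int
    reads_mini: int
    reads_background: int


def collect_cross_junction_reads(
    junction: CandidateJunction,
    alignments: list[AlignmentRecord],
) -> list[tuple[str, str]]:
    """Full sequences of the reads contributing split evidence to a junction.

    Returns ``(read_id, sequence)`` pairs; sequences are taken from the
    primary record (reference-forward orientation — the assembler is
    orientation-aware).
    """
    wanted = {ev.read_id for ev in junction.evidence}
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in alignments:
        if not rec.is_primary:
            continue
        rid = f"{rec.qname}/{rec.mate_ordinal + 1}"
        if rid in wanted and rid not in seen:
            out.append((rid, rec.seq))
            seen.add(rid)
    return out


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest exact suffix(a)/prefix(b) overlap of at least ``min_overlap``."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a.endswith(b[:k]):
            return k
    return 0


def assemble_contig(
    reads: list[tuple[str, str]] | list[str],
    min_overlap: int = 20,
) -> Contig:
    """Greedy merge of reads by maximal exact suffix-prefix overlap.

    Contained reads (substrings of another read, in either orientation) are
    absorbed first.  At each step the highest-overlap merge is applied
    (ties broken lexicographically for determinism); reverse-complement
    orientations are considered.  Returns the longest assembled sequence;
    if two or more reads never overlap by ``min_overlap`` the result is
    flagged fragmentary.
    """
    if not reads:
        raise ValueError("assembly needs at least one read")
    if isinstance(reads[0], str):
        items = [(f"read{i}", s) for i, s in enumerate(reads)]  # type: ignore[arg-type]
    else:
        items = list(reads)  # type: ignore[assignment]

    pieces: list[tuple[str, list[str]]] = []  # (sequence, member read ids)
    for rid, seq in sorted(items, key=lambda t: (-len(t[1]), t[0])):
        seq = seq.upper()
        placed = False
        for i, (cur, ids) in enumerate(pieces):
            if seq in cur or revcomp(seq) in cur:
                pieces[i] = (cur, ids + [rid])
                placed = True
                break
        if not placed:
            pieces.append((seq, [rid]))

    n_input_pieces = len(pieces)
    while len(pieces) > 1:
        best = None  # (overlap, i, j, flip_i, flip_j)
        for i, (a, _) in enumerate(pieces):
            for j, (b, _) in enumerate(pieces):
                if i == j:
                    continue
                for flip_a in (False, True):
                    aa = revcomp(a) if flip_a else a
                    for flip_b in (False, True):
                        bb = revcomp(b) if flip_b else b
                        k = _best_overlap(aa, bb, min_overlap)
                        if k and (best is None or k > best[0]):
                            best = (k, i, j, flip_a, flip_b)
        if best is None:
            break
        k, i, j, flip_a, flip_b = best
        a, ids_a = pieces[i]
        b, ids_b = pieces[j]
        aa = revcomp(a) if flip_a else a
        bb = revcomp(b) if flip_b else b
        merged = aa + bb[k:]
        pieces = [p for idx, p in enumerate(pieces) if idx not in (i, j)]
        # re-absorb anything now contained in the merged sequence
        pieces.append((merged, ids_a + ids_b))
        pieces.sort(key=lambda p: -len(p[0]))

    seq, ids = max(pieces, key=lambda p: len(p[0]))
    fragmentary = len(pieces) > 1 and n_input_pieces > 1
    return Contig(sequence=seq, read_ids=sorted(ids), fragmentary=fragmentary)


def _flank_into(sequences: dict[str, str], bp: Breakpoint, w: int) -> str:
    """Reference sequence read *toward* the junction, ending at the breakpoint."""
    seq = sequences[bp.chrom]
    if bp.side == "left":
        return seq[max(0, bp.pos - w) : bp.pos]
    return revcomp(seq[bp.pos - 1 : bp.pos - 1 + w])


def _flank_outof(sequences: dict[str, str], bp: Breakpoint, w: int) -> str:
    """Reference sequence read *away* from the junction, starting at the breakpoint."""
    seq = sequences[bp.chrom]
    if bp.side == "right":
        return seq[bp.pos - 1 : bp.pos - 1 + w]
    return revcomp(seq[max(0, bp.pos - w) : bp.pos])


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -4
    al.extend_gap_score = -1
    return al


def _local_identity(aligner: Align.PairwiseAligner, query: str, target: str) -> tuple[float, int, tuple[int, int]]:
    """(identity, aligned query length, target span) of the best local alignment."""
    if not query or not target:
        return 0.0, 0, (0, 0)
    aln = aligner.align(target, query)
    if len(aln) == 0:
        return 0.0, 0, (0, 0)
    best = aln[0]
    counts = best.counts()
    aligned = counts.identities + counts.mismatches
    ident = counts.identities / aligned if aligned else 0.0
    q0, q1 = best.aligned[1][0][0], best.aligned[1][-1][-1]
    t0, t1 = best.aligned[0][0][0], best.aligned[0][-1][-1]
    return ident, q1 - q0, (t0, t1)


def validate_contig(
    contig: Contig,
    sequences: dict[str, str],
    junction: CandidateJunction,
    *,
    anchor: int = 30,
    min_identity: float = 0.95,
    tolerance: int = 50,
) -> bool:
    """Check that both contig ends align to the junction's expected flanks.

    The expected chimeric sequence is reconstructed from the reference
    around the two breakpoints (respecting sides/orientation, with
    ``tolerance`` bp of positional slack).  The contig validates when it
    aligns to that chimera at ``min_identity`` with at least ``anchor``
    bases on each side of the junction point — and does *not* align
    contiguously to a single reference locus, which marks a false
    candidate.  Sets ``contig.validated`` and records end alignments.
    """
    n = len(contig.sequence)
    if n < 2 * anchor:
        contig.validated = False
        return False
    aligner = _aligner()
    bp_a, bp_b = junction.breakpoint_a, junction.breakpoint_b

    # contiguous decoy check around each breakpoint
    for bp in (bp_a, bp_b):
        seq = sequences[bp.chrom]
        lo = max(0, bp.pos - n - tolerance)
        window = seq[lo : bp.pos + n + tolerance]
        for q in (contig.sequence, revcomp(contig.sequence)):
            ident, alen, _ = _local_identity(aligner, q, window)
            if alen >= 0.95 * n and ident >= min_identity:
                contig.validated = False
                return False

    w = n + tolerance
    chimera = _flank_into(sequences, bp_a, w) + _flank_outof(sequences, bp_b, w)
    mid = len(_flank_into(sequences, bp_a, w))
    ok = False
    for q in (contig.sequence, revcomp(contig.sequence)):
        ident, alen, (t0, t1) = _local_identity(aligner, q, chimera)
        if (
            ident >= min_identity
            and alen >= 0.9 * n
            and t0 <= mid - anchor
            and t1 >= mid + anchor
        ):
            ok = True
            left_len = mid - t0
            right_len = t1 - mid
            contig.end_alignments = [
                _flank_coords(bp_a, "into", left_len) + (ident,),
                _flank_coords(bp_b, "outof", right_len) + (ident,),
            ]
            break
    contig.validated = ok
    return ok


def _flank_coords(bp: Breakpoint, direction: str, length: int) -> tuple[str, int, int, int]:
    """Reference coordinates of a flank of given aligned length."""
    if (direction == "into") == (bp.side == "left"):
        return (bp.chrom, max(1, bp.pos - length + 1), bp.pos, 1 if bp.side == "left" else -1)
    return (bp.chrom, bp.pos, bp.pos + length - 1, 1 if bp.side == "right" else -1)


def assign_haplotype(
    junction: CandidateJunction,
    snp_table: list[tuple[int, str, str]],
    alignments: list[AlignmentRecord],
    window: int = 1000,
    min_reads: int = 2,
) -> HaplotypeCall:
    """Assign a junction's haplotype of origin from diagnostic SNP alleles.

    Reads carrying split evidence for the junction — plus their mates —
    that align within ``window`` of either breakpoint are inspected at
    diagnostic SNP sites.  The junction is called ``mini_haplotype`` when
    at least ``min_reads`` reads carry mini alleles and none carry the
    background allele (symmetrically for ``background``); anything else,
    including zero informative SNPs, is ``indeterminate``.
    """
    split_reads = {ev.read_id for ev in junction.evidence}
    qnames = {rid.rsplit("/", 1)[0] for rid in split_reads}
    bps = [junction.breakpoint_a, junction.breakpoint_b]
    snp_by_pos = {pos: (bg, mini) for pos, bg, mini in snp_table}

    reads_mini = 0
    reads_bg = 0
    informative_sites: set[int] = set()
    per_read: dict[str, tuple[int, int]] = {}
    for rec in alignments:
        if not rec.is_primary or rec.qname not in qnames:
            continue
        near = any(
            rec.chrom == bp.chrom and rec.pos <= bp.pos + window and rec.end >= bp.pos - window
            for bp in bps
        )
        if not near:
            continue
        mini_hits, bg_hits = per_read.get(rec.qname, (0, 0))
        mapped_len = rec.end - rec.pos + 1
        for pos in range(rec.pos, rec.end + 1):
            alleles = snp_by_pos.get(pos)
            if alleles is None:
                continue
            idx = rec.left_clip + (pos - rec.pos)
            if idx >= len(rec.seq) or pos - rec.pos >= mapped_len:
                continue
            base = rec.seq[idx]
            bg, mini = alleles
            if base == mini:
                mini_hits += 1
                informative_sites.add(pos)
            elif base == bg:
                bg_hits += 1
                informative_sites.add(pos)
        per_read[rec.qname] = (mini_hits, bg_hits)

    for mini_hits, bg_hits in per_read.values():
        if mini_hits and not bg_hits:
            reads_mini += 1
        elif bg_hits and not mini_hits:
            reads_bg += 1

    if len(informative_sites) == 0:
        call = "indeterminate"
    elif reads_mini >= min_reads and reads_bg == 0:
        call = "mini_haplotype"
    elif reads_bg >= min_reads and reads_mini == 0:
        call = "background"
    else:
        call = "indeterminate"
    return HaplotypeCall(call, len(informative_sites), reads_mini, reads_bg)
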