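"""Ring minichromosome structure model.

A mini is represented as a circular chain of oriented segments of the source
chromosome.  Every adjacency between consecutive segments that is not
reference-adjacent is a novel junction: the circularization site that closed
the ring, the adjacency created by the large internal deletion of the
deleted form, and any extra rearrangement junctions injected on top.

Junction orientation follows the three-class taxonomy used for breakpoint
diagrams: ``head_to_tail`` joins colinear flanks (left+right), while
``tail_to_tail`` (left+left) and ``head_to_head`` (right+right) join flanks
of the same polarity and imply an inverted segment.  An inversion therefore
contributes *two* adjacencies, and callers inject it as two extra junctions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .intervals import Interval
from .reference import ReferenceBundle

Side = str  # "left" | "right": which flank of the breakpoint is retained

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def orientation_of(side_a: Side, side_b: Side) -> str:
    """Three-class joining orientation of an adjacency."""
    if {side_a, side_b} == {"left", "right"}:
        return "head_to_tail"
    return "tail_to_tail" if side_a == "left" else "head_to_head"


@dataclass(frozen=True)
class Adjacency:
    """One oriented novel adjacency: flank at ``pos_a`` joined to flank at ``pos_b``."""

    chrom: str
    pos_a: int
    side_a: Side
    pos_b: int
    side_b: Side
    kind: str = "extra"  # circularization | deletion | extra

    def __post_init__(self) -> None:
        for side in (self.side_a, self.side_b):
            if side not in ("left", "right"):
                raise ValueError(f"invalid breakpoint side {side!r}")

    @property
    def orientation(self) -> str:
        return orientation_of(self.side_a, self.side_b)

    def canonical(self) -> tuple:
        """Order-independent key (the two ends sorted)."""
        ends = sorted([(self.pos_a, self.side_a), (self.pos_b, self.side_b)])
        return (self.chrom, *ends[0], *ends[1])


class MiniType(enum.Enum):
    """The six structural classes of a sample's minichromosome complement."""

    NO_MINI = (0, 0)
    ONE_FULL = (1, 0)
    TWO_FULL = (2, 0)
    ONE_DELETED = (0, 1)
    TWO_DELETED = (0, 2)
    FULL_PLUS_DELETED = (1, 1)

    @property
    def n_full(self) -> int:
        return self.value[0]

    @property
    def n_deleted(self) -> int:
        return self.value[1]


@dataclass
class MiniConfig:
    """Copy-number/structure configuration of one individual's minis.

    ``extra_junctions`` are oriented adjacencies carried by the deleted form,
    as ``(pos_a, side_a, pos_b, side_b)`` on the mini source chromosome.
    """

    n_full: int = 0
    n_deleted: int = 0
    deletion_interval: Interval | None = None
    extra_junctions: list[tuple[int, Side, int, Side]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_full not in (0, 1, 2) or self.n_deleted not in (0, 1, 2):
            raise ValueError("copy numbers must be in {0,1,2}")
        if self.n_full + self.n_deleted > 2:
            raise ValueError("at most two mini copies per individual")

    @property
    def mini_type(self) -> MiniType:
        return MiniType((self.n_full, self.n_deleted))


@dataclass
class MiniStructure:
    """A composed circular mini: its sequence, segment chain, and junctions.

    ``segments`` are ``(start, end, strand)`` on the source chromosome,
    1-based inclusive, in circle order starting at the segment that begins
    the canonical linearization; ``junctions`` lists every novel adjacency
    including the circularization site.
    """

    chrom: str
    sequence: str
    segments: list[tuple[int, int, int]]  # strand +1 / -1
    junctions: list[Adjacency]

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_offsets(self) -> list[int]:
        """Circle offset (0-based) at which each segment starts."""
        offs, total = [], 0
        for s, e, _ in self.segments:
            offs.append(total)
            total += e - s + 1
        return offs

    def blocks_for(self, start: int, length: int) -> list[tuple[int, int, int]]:
        """Reference-coordinate blocks covered by circle slice [start, start+length).

        Wraps around the origin.  Each block is ``(ref_start, ref_end, strand)``
        with 1-based inclusive coordinates, in read order along the circle.
        """
        n = len(self.sequence)
        if length > n:
            raise ValueError("slice longer than the circle")
        offs = self.segment_offsets()
        blocks: list[tuple[int, int, int]] = []
        remaining, pos = length, start % n
        while remaining > 0:
            # segment containing circle offset `pos`
            idx = max(i for i, o in enumerate(offs) if o <= pos)
            seg_s, seg_e, strand = self.segments[idx]
            seg_len = seg_e - seg_s + 1
            within = pos - offs[idx]
            take = min(remaining, seg_len - within)
            if strand == 1:
                blocks.append((seg_s + within, seg_s + within + take - 1, 1))
            else:
                blocks.append((seg_e - within - take + 1, seg_e - within, -1))
            remaining -= take
            pos = (pos + take) % n
        return blocks


class InvalidConfiguration(ValueError):
    """Raised when a mini configuration cannot be composed into one circle."""


def _walk_circle(
    region: Interval, adjacencies: list[Adjacency]
) -> list[tuple[int, int, int]]:
    """Trace the circular segment chain implied by a set of adjacencies.

    Starting at the region start moving rightwards, traversal stops at each
    breakpoint whose retained flank is being read, jumps to the partner
    flank, and continues in the direction that flank implies.  A valid
    configuration uses every adjacency exactly once, never leaves the
    region, and closes the circle.
    """
    end_map: dict[tuple[int, Side], tuple[int, Side, Adjacency]] = {}
    for adj in adjacencies:
        for (p, s), (q, t) in [
            ((adj.pos_a, adj.side_a), (adj.pos_b, adj.side_b)),
            ((adj.pos_b, adj.side_b), (adj.pos_a, adj.side_a)),
        ]:
            if (p, s) in end_map:
                raise InvalidConfiguration(
                    f"breakpoint flank ({p},{s}) used by more than one junction"
                )
            end_map[(p, s)] = (q, t, adj)
        for p in (adj.pos_a, adj.pos_b):
            if not (region[0] <= p <= region[1]):
                raise InvalidConfiguration(f"breakpoint {p} outside mini region {region}")

    left_stops = sorted(p for (p, s) in end_map if s == "left")
    right_stops = sorted(p for (p, s) in end_map if s == "right")

    segments: list[tuple[int, int, int]] = []
    used: set[int] = set()
    cur, direction = region[0], 1
    for _ in range(2 * len(adjacencies) + 2):
        if direction == 1:
            stops = [p for p in left_stops if p >= cur]
            if not stops:
                raise InvalidConfiguration("ran off the right edge of the mini region")
            stop = stops[0]
            segments.append((cur, stop, 1))
            key = (stop, "left")
        else:
            stops = [p for p in right_stops if p <= cur]
            if not stops:
                raise InvalidConfiguration("ran off the left edge of the mini region")
            stop = stops[-1]
            segments.append((stop, cur, -1))
            key = (stop, "right")
        q, t, adj = end_map[key]
        if id(adj) in used:
            raise InvalidConfiguration("junction traversed twice; extras overlap")
        used.add(id(adj))
        if (q, t) == (region[0], "right") and len(used) == len(adjacencies):
            # closed the circle through the circularization flank
            _check_disjoint(segments)
            return segments
        cur, direction = q, (1 if t == "right" else -1)
    raise InvalidConfiguration("junction set does not compose into a single circle")


def _check_disjoint(segments: list[tuple[int, int, int]]) -> None:
    ivs = sorted((s, e) for s, e, _ in segments)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise InvalidConfiguration("composed segments overlap on the reference")


def _mini_source_sequence(ref: ReferenceBundle) -> str:
    """Source chromosome sequence with mini-haplotype alleles substituted."""
    seq = list(ref.sequences[ref.mini_chrom])
    for pos, _bg, mini_allele in ref.snp_table:
        seq[pos - 1] = mini_allele
    return "".join(seq)


def build_mini(
    ref: ReferenceBundle,
    config: MiniConfig,
    form: str = "full",
) -> MiniStructure | None:
    """Compose one mini form ("full" or "deleted") into a circular structure.

    Returns ``None`` when the config carries zero copies of the requested
    form.  The full form is the excised, circularized mini region (exactly
    one novel junction: the circularization site).  The deleted form
    additionally lacks ``deletion_interval`` and carries every extra
    junction.  The mini sequence carries the mini-haplotype SNP alleles.
    """
    region = ref.mini_region
    chrom = ref.mini_chrom
    if form == "full":
        if config.n_full == 0:
            return None
        adjacencies = [
            Adjacency(chrom, region[1], "left", region[0], "right", "circularization")
        ]
    elif form == "deleted":
        if config.n_deleted == 0:
            return None
        deletion = config.deletion_interval
        if deletion is None:
            raise InvalidConfiguration("deleted form requires a deletion_interval")
        if not (region[0] < deletion[0] <= deletion[1] < region[1]):
            raise InvalidConfiguration(
                f"deletion_interval {deletion} not strictly inside mini region {region}"
            )
        adjacencies = [
            Adjacency(chrom, region[1], "left", region[0], "right", "circularization"),
            Adjacency(chrom, deletion[0] - 1, "left", deletion[1] + 1, "right", "deletion"),
        ]
        adjacencies += [
            Adjacency(chrom, pa, sa, pb, sb, "extra")
            for pa, sa, pb, sb in config.extra_junctions
        ]
    else:
        raise ValueError(f"unknown mini form {form!r}")

    segments = _walk_circle(region, adjacencies)
    source = _mini_source_sequence(ref)
    parts = [
        source[s - 1 : e] if strand == 1 else revcomp(source[s - 1 : e])
        for s, e, strand in segments
    ]
    return MiniStructure(chrom, "".join(parts), segments, adjacencies)


def truth_junctions(ref: ReferenceBundle, config: MiniConfig) -> list[Adjacency]:
    """Every novel adjacency present in an individual with this config."""
    seen: dict[tuple, Adjacency] = {}
    for form in ("full", "deleted"):
        mini = build_mini(ref, config, form)
        if mini is not None:
            for adj in mini.junctions:
                seen.setdefault(adj.canonical(), adj)
    return list(seen.values())
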