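"""Paired-end short-read simulator with minichromosome haplotypes.

Each individual is a diploid background genome (two copies of every
chromosome) plus zero, one, or two ring-mini copies.  Reads are 150 bp
paired-end at ~10x by default, mirroring the sequencing design the pipeline
is built for.  Reads sampled from a mini that cross one of its novel
junctions are emitted the way a real aligner reports them: a soft-clipped
primary alignment plus a supplementary alignment at the partner locus, with
an SA tag linking the segments.

The simulator is the ground-truth engine of the test suite: every
individual comes with a :class:`TruthRecord` naming its structural type and
every novel adjacency, so each downstream stage can be scored without any
external file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mini import Adjacency, MiniConfig, MiniStructure, MiniType, build_mini, revcomp, truth_junctions
from .reference import DEFAULT_DELETION, ReferenceBundle
from .samio import (
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    FLAG_SECOND,
    FLAG_SUPPLEMENTARY,
    AlignmentRecord,
)

#: Minimum mapped length of a split-read segment; shorter remainders are
#: soft-clipped without a supplementary record, as short-read aligners do.
MIN_SPLIT_SEGMENT = 20


@dataclass
class TruthRecord:
    """Ground truth for one simulated individual."""

    sample_id: str
    mini_config: MiniConfig
    true_junctions: list[Adjacency]
    true_mini_type: MiniType


def _circle_slice(seq: str, start: int, length: int) -> str:
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: start + length - n]


def _fragment_lengths(rng: np.random.Generator, n: int, insert_mean: float, read_len: int, max_len: int) -> np.ndarray:
    frags = rng.normal(insert_mean, 0.1 * insert_mean, size=n)
    return np.clip(np.rint(frags), read_len, max_len).astype(np.int64)


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if hits.size:
        subs = rng.integers(0, 4, size=hits.size)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        arr[hits] = bases[subs]
    return arr.tobytes().decode()


def _background_records(
    rng: np.random.Generator,
    chrom: str,
    seq: str,
    depth: float,
    read_len: int,
    insert_mean: float,
    sample_id: str,
    error_rate: float,
) -> list[AlignmentRecord]:
    L = len(seq)
    n_frags = int(round(depth * L / (2 * read_len)))
    frags = _fragment_lengths(rng, n_frags, insert_mean, read_len, min(L, int(3 * insert_mean)))
    starts = 1 + np.floor(rng.random(n_frags) * (L - frags + 1)).astype(np.int64)
    cigar = f"{read_len}M"
    out: list[AlignmentRecord] = []
    for i in range(n_frags):
        s, f = int(starts[i]), int(frags[i])
        p2 = s + f - read_len
        qname = f"{sample_id}.bg.{chrom}.{i}"
        r1 = _apply_errors(rng, seq[s - 1 : s - 1 + read_len], error_rate)
        r2_fwd = _apply_errors(rng, seq[p2 - 1 : p2 - 1 + read_len], error_rate)
        out.append(
            AlignmentRecord(qname, FLAG_PAIRED | FLAG_PROPER | FLAG_MATE_REVERSE | FLAG_FIRST,
                            chrom, s, 60, cigar, r1, "=", p2, f)
        )
        out.append(
            AlignmentRecord(qname, FLAG_PAIRED | FLAG_PROPER | FLAG_REVERSE | FLAG_SECOND,
                            chrom, p2, 60, cigar, r2_fwd, "=", s, -f)
        )
    return out


def _split_read_records(
    mini: MiniStructure,
    circle_start: int,
    read_len: int,
    sequenced_forward: bool,
    qname: str,
    mate_flag_bits: int,
) -> list[AlignmentRecord]:
    """SAM records for one read sampled from the mini circle.

    ``sequenced_forward`` is True for the first mate (read bases follow the
    circle) and False for the second (read is the reverse complement of its
    circle slice).  A read spanning k segments yields up to k records; the
    longest mapped piece is primary.
    """
    circle = mini.sequence
    raw = _circle_slice(circle, circle_start, read_len)
    read = raw if sequenced_forward else revcomp(raw)

    blocks = mini.blocks_for(circle_start, read_len)
    if not sequenced_forward:
        blocks = [(s, e, -st) for (s, e, st) in reversed(blocks)]

    # read-offset extents of each block, in sequenced-read order
    pieces = []
    off = 0
    for s, e, st in blocks:
        ln = e - s + 1
        pieces.append((off, off + ln, s, e, st))
        off += ln

    mapped = [p for p in pieces if p[1] - p[0] >= MIN_SPLIT_SEGMENT]
    if not mapped:
        mapped = [max(pieces, key=lambda p: p[1] - p[0])]
    primary = max(mapped, key=lambda p: p[1] - p[0])

    def sa_entry(p) -> str:
        r0, r1, s, e, st = p
        cig = _piece_cigar(r0, r1, st, read_len)
        return f"{mini.chrom},{s},{'+' if st == 1 else '-'},{cig},60,0;"

    records = []
    for p in mapped:
        r0, r1, s, e, st = p
        cigar = _piece_cigar(r0, r1, st, read_len)
        seq_field = read if st == 1 else revcomp(read)
        flag = FLAG_PAIRED | FLAG_PROPER | mate_flag_bits
        if st == -1:
            flag |= FLAG_REVERSE
        if p is not primary:
            flag |= FLAG_SUPPLEMENTARY
        tags = {}
        others = [q for q in mapped if q is not p]
        if others:
            tags["SA"] = "".join(sa_entry(q) for q in others)
        records.append(AlignmentRecord(qname, flag, mini.chrom, s, 60, cigar, seq_field, tags=tags))
    return records


def _piece_cigar(r0: int, r1: int, strand: int, read_len: int) -> str:
    left = r0 if strand == 1 else read_len - r1
    right = read_len - r1 if strand == 1 else r0
    parts = []
    if left:
        parts.append(f"{left}S")
    parts.append(f"{r1 - r0}M")
    if right:
        parts.append(f"{right}S")
    return "".join(parts)


def _mini_records(
    rng: np.random.Generator,
    mini: MiniStructure,
    copies: int,
    depth: float,
    read_len: int,
    insert_mean: float,
    sample_id: str,
    form: str,
    error_rate: float,
) -> list[AlignmentRecord]:
    n = len(mini.sequence)
    per_copy_depth = depth / 2.0  # background diploid depth `depth` = 2 copies
    n_frags = int(round(copies * per_copy_depth * n / (2 * read_len)))
    frags = _fragment_lengths(rng, n_frags, insert_mean, read_len, min(n, int(3 * insert_mean)))
    starts = np.floor(rng.random(n_frags) * n).astype(np.int64)
    out: list[AlignmentRecord] = []
    for i in range(n_frags):
        o, f = int(starts[i]), int(frags[i])
        qname = f"{sample_id}.{form}.{i}"
        recs = _split_read_records(mini, o, read_len, True, qname, FLAG_FIRST | FLAG_MATE_REVERSE)
        recs += _split_read_records(mini, o + f - read_len, read_len, False, qname, FLAG_SECOND)
        prim = {r.mate_ordinal: r for r in recs if not r.is_supplementary}
        for r in recs:
            mate = prim.get(1 - r.mate_ordinal)
            if mate is not None:
                r.pnext = mate.pos
        if error_rate > 0:
            for r in recs:
                r.seq = _apply_errors(rng, r.seq, error_rate)
        out.extend(recs)
    return out


def simulate_individual(
    ref: ReferenceBundle,
    config: MiniConfig,
    *,
    depth: float = 10.0,
    read_len: int = 150,
    insert_mean: float = 400.0,
    seed: int,
    sample_id: str = "sample",
    error_rate: float = 0.0,
) -> tuple[list[AlignmentRecord], TruthRecord]:
    """Simulate one individual's alignments plus its ground truth.

    The diploid background is emitted at ``depth``; each mini copy at
    ``depth/2`` (one background copy's worth), so the expected normalized
    dosage over retained mini bins is ``2 + copies``.  Deterministic per
    seed: identical arguments yield an identical record stream.
    """
    if depth <= 0 or read_len <= 0:
        raise ValueError("depth and read_len must be positive")
    if insert_mean < read_len:
        raise ValueError("insert_mean must be at least read_len")
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    for chrom, seq in ref.sequences.items():
        records += _background_records(
            rng, chrom, seq, depth, read_len, insert_mean, sample_id, error_rate
        )
    for form, copies in (("full", config.n_full), ("deleted", config.n_deleted)):
        if copies == 0:
            continue
        mini = build_mini(ref, config, form)
        assert mini is not None
        records += _mini_records(
            rng, mini, copies, depth, read_len, insert_mean, sample_id, form, error_rate
        )
    records.sort(key=lambda r: (r.chrom, r.pos, r.flag, r.qname))
    truth = TruthRecord(sample_id, config, truth_junctions(ref, config), config.mini_type)
    return records, truth


def default_cohort_configs(
    deletion_interval: tuple[int, int] = DEFAULT_DELETION,
    extra_junctions: list[tuple[int, str, int, str]] | None = None,
) -> dict[MiniType, MiniConfig]:
    """One config per structural type, using the default deletion analog."""
    extras = extra_junctions or []
    out: dict[MiniType, MiniConfig] = {}
    for mt in MiniType:
        out[mt] = MiniConfig(
            n_full=mt.n_full,
            n_deleted=mt.n_deleted,
            deletion_interval=deletion_interval if mt.n_deleted else None,
            extra_junctions=list(extras) if mt.n_deleted else [],
        )
    return out


def simulate_cohort(
    ref: ReferenceBundle,
    configs: dict[str, MiniConfig],
    *,
    depth: float = 10.0,
    read_len: int = 150,
    insert_mean: float = 400.0,
    seed: int,
    error_rate: float = 0.0,
) -> tuple[dict[str, list[AlignmentRecord]], dict[str, TruthRecord]]:
    """Simulate a named cohort; per-sample seeds are derived from ``seed``."""
    alignments: dict[str, list[AlignmentRecord]] = {}
    truths: dict[str, TruthRecord] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(configs))
    for (sample_id, config), child in zip(sorted(configs.items()), child_seeds):
        recs, truth = simulate_individual(
            ref,
            config,
            depth=depth,
            read_len=read_len,
            insert_mean=insert_mean,
            seed=int(child % (2**31)),
            sample_id=sample_id,
            error_rate=error_rate,
        )
        alignments[sample_id] = recs
        truths[sample_id] = truth
    return alignments, truths
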