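"""Contig assembly, junction validation, haplotype assignment."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import ringmini as rm
from ringmini.mini import revcomp
from ringmini.samio import AlignmentRecord
from tests.conftest import small_config


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ------------------------------------------------------------- assembler


def test_single_read_is_its_own_contig():
    contig = rm.assemble_contig(["ACGTACGTACGTACGTACGTACGT"], min_overlap=5)
    assert contig.sequence == "ACGTACGTACGTACGTACGTACGT"
    assert not contig.fragmentary


def test_two_reads_with_fifty_base_overlap_give_250(rng):
    s = _random_seq(rng, 250)
    contig = rm.assemble_contig([s[:150], s[100:]], min_overlap=20)
    assert contig.sequence in (s, revcomp(s))
    assert len(contig) == 250


def test_tiled_reads_reconstruct_400bp_chimera_exactly(rng):
    """Error-free 150 bp reads tiling a 400 bp junction sequence reassemble it."""
    chimera = _random_seq(rng, 400)
    starts = np.linspace(0, 250, 12).astype(int)
    reads = [chimera[s : s + 150] for s in starts]
    # mix in reverse-complement orientations, as paired-end data would
    reads = [revcomp(r) if i % 3 == 0 else r for i, r in enumerate(reads)]
    contig = rm.assemble_contig(reads, min_overlap=20)
    assert contig.sequence in (chimera, revcomp(chimera))
    assert not contig.fragmentary


def test_disjoint_reads_flagged_fragmentary(rng):
    a, b = _random_seq(rng, 150), _random_seq(rng, 150)
    contig = rm.assemble_contig([a, b], min_overlap=20)
    assert contig.fragmentary
    assert len(contig) == 150


def _oracle_min_superstring(reads, min_overlap):
    """Exhaustive merge-order/orientation search for the shortest merge result."""
    best = None
    for perm in itertools.permutations(reads):
        for flips in itertools.product([False, True], repeat=len(perm)):
            seqs = [revcomp(s) if f else s for s, f in zip(perm, flips)]
            cur = seqs[0]
            ok = True
            for nxt in seqs[1:]:
                if nxt in cur:
                    continue
                k = 0
                for kk in range(min(len(cur), len(nxt)), min_overlap - 1, -1):
                    if cur.endswith(nxt[:kk]):
                        k = kk
                        break
                if k == 0:
                    ok = False
                    break
                cur = cur + nxt[k:]
            if ok and (best is None or len(cur) < best):
                best = len(cur)
    return best


def test_greedy_matches_exhaustive_merge_order_oracle(rng):
    """On small inputs the greedy result length equals the exhaustive optimum."""
    for trial in range(5):
        src = _random_seq(rng, 220)
        starts = sorted(rng.integers(0, 120, size=5))
        reads = [src[s : s + 100] for s in starts]
        greedy = rm.assemble_contig(reads, min_overlap=15)
        oracle = _oracle_min_superstring(reads, min_overlap=15)
        assert oracle is not None
        assert len(greedy) == oracle


# ------------------------------------------------------- validation round-trip


def _junction_setup(small_ref, small_lengths):
    alignments, truths = rm.simulate_cohort(
        small_ref,
        {
            "car": small_config(rm.MiniType.TWO_DELETED),
            "ctl": small_config(rm.MiniType.NO_MINI),
        },
        seed=300,
    )
    ev = rm.extract_split_alignments(alignments["car"], 2000, "car")
    cands = rm.cluster_evidence(ev)
    return alignments, truths, cands


@pytest.fixture(scope="module")
def junction_world(small_ref, small_lengths):
    return _junction_setup(small_ref, small_lengths)


def test_collect_cross_junction_reads_counts(junction_world):
    alignments, _, cands = junction_world
    for cand in cands:
        reads = rm.collect_cross_junction_reads(cand, alignments["car"])
        assert len(reads) == cand.support
        assert all(len(seq) == 150 for _, seq in reads)
    empty = rm.CandidateJunction(
        rm.Breakpoint("Chr1", 10, "left"), rm.Breakpoint("Chr1", 9_000, "right"), "head_to_tail"
    )
    assert rm.collect_cross_junction_reads(empty, alignments["car"]) == []


def test_truth_junction_contigs_validate(small_ref, junction_world):
    alignments, truths, cands = junction_world
    validated = 0
    for cand in cands:
        if cand.support < 4:
            continue
        reads = rm.collect_cross_junction_reads(cand, alignments["car"])
        contig = rm.assemble_contig(reads)
        assert rm.validate_contig(contig, small_ref.sequences, cand)
        validated += 1
    assert validated >= 2  # at least circularization + deletion junction


def test_contiguous_decoy_contig_never_validates(small_ref, junction_world, rng):
    _, _, cands = junction_world
    cand = max(cands, key=lambda c: c.support)
    seq = small_ref.sequences[small_ref.mini_chrom]
    decoy = rm.Contig(sequence=seq[700_000:700_400], read_ids=[])
    assert rm.validate_contig(decoy, small_ref.sequences, cand) is False
    # one real end, one random end: still not validated
    half_real = rm.Contig(
        sequence=seq[cand.breakpoint_a.pos - 200 : cand.breakpoint_a.pos] + _random_seq(rng, 200),
        read_ids=[],
    )
    assert rm.validate_contig(half_real, small_ref.sequences, cand) is False


# ------------------------------------------------------------- haplotype


def test_haplotype_of_mini_junctions_is_mini(small_ref, junction_world):
    """Junction flanks on the mini carry Col-0-analog (mini) SNP alleles."""
    alignments, _, cands = junction_world
    calls = []
    for cand in cands:
        hap = rm.assign_haplotype(cand, small_ref.snp_table, alignments["car"])
        calls.append(hap.call)
        assert hap.call != "background"
        if hap.call == "mini_haplotype":
            assert hap.informative_snps >= 1 and hap.reads_background == 0
    assert "mini_haplotype" in calls


def test_haplotype_no_snps_in_window_is_indeterminate(junction_world):
    alignments, _, cands = junction_world
    cand = max(cands, key=lambda c: c.support)
    hap = rm.assign_haplotype(cand, [], alignments["car"])
    assert hap.call == "indeterminate" and hap.informative_snps == 0


def test_haplotype_conflicting_reads_are_indeterminate():
    """Reads split 50/50 between alleles yield no call."""
    bp_a = rm.Breakpoint("c", 5_000, "left")
    bp_b = rm.Breakpoint("c", 20_000, "right")
    ev = [
        rm.SplitReadEvidence(f"q{i}/1", "s", ("c", 1, 1, 1), ("c", 1, 1, 1), bp_a, bp_b)
        for i in range(4)
    ]
    cand = rm.CandidateJunction(bp_a, bp_b, "head_to_tail", ev)
    snps = [(4_950, "A", "G")]
    recs = []
    for i in range(4):
        base = "G" if i % 2 == 0 else "A"
        seq = "C" * 49 + base + "C" * 100
        recs.append(AlignmentRecord(f"q{i}", 0, "c", 4_901, 60, "150M", seq))
    hap = rm.assign_haplotype(cand, snps, recs)
    assert hap.call == "indeterminate"
    assert hap.reads_mini == 2 and hap.reads_background == 2
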