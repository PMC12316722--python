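"""Junction detection: separation rule, clustering, threshold, filters, orientation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import ringmini as rm
from ringmini.junctions import pseudo_junction_threshold
from ringmini.samio import FLAG_SUPPLEMENTARY, AlignmentRecord
from tests.conftest import small_config


def _split_pair(pos_a, pos_b, qname="r1", chrom="c", mapped=75, read_len=150):
    """A primary + supplementary pair: first half maps at pos_a, second at pos_b."""
    seq = "A" * read_len
    primary = AlignmentRecord(
        qname, 0, chrom, pos_a, 60, f"{mapped}M{read_len - mapped}S", seq
    )
    supp = AlignmentRecord(
        qname, FLAG_SUPPLEMENTARY, chrom, pos_b, 60, f"{mapped}S{read_len - mapped}M", seq
    )
    return [primary, supp]


def test_min_separation_boundary_is_inclusive():
    """Breakpoints 1,999 apart are excluded; exactly 2,000 apart are included."""
    # primary ends at pos_a + mapped - 1; breakpoint A at that end, B at pos_b
    recs = _split_pair(100_000 - 74, 101_999)
    assert rm.extract_split_alignments(recs, 2000) == []
    recs = _split_pair(100_000 - 74, 102_000)
    ev = rm.extract_split_alignments(recs, 2000)
    assert len(ev) == 1
    assert (ev[0].breakpoint_a.pos, ev[0].breakpoint_b.pos) == (100_000, 102_000)
    assert (ev[0].breakpoint_a.side, ev[0].breakpoint_b.side) == ("left", "right")
    assert ev[0].orientation == "head_to_tail"


def test_synthetic_junction_yields_one_evidence_per_crossing_read(deleted_cohort):
    alignments, truths = deleted_cohort
    recs = alignments["car1"]
    ev = rm.extract_split_alignments(recs, 2000, "car1")
    # every evidence item must sit on a true junction of this sample
    truth_pairs = {
        tuple(sorted((j.pos_a, j.pos_b))) for j in truths["car1"].true_junctions
    }
    for e in ev:
        pair = tuple(sorted((e.breakpoint_a.pos, e.breakpoint_b.pos)))
        assert any(
            abs(pair[0] - t[0]) <= 5 and abs(pair[1] - t[1]) <= 5 for t in truth_pairs
        )
    # and each crossing read contributes exactly one item
    assert len({e.read_id for e in ev}) == len(ev)


def test_cluster_evidence_merging_and_median():
    base = _split_pair(1_000, 50_000, "a") + _split_pair(1_000, 50_000, "b")
    ev = rm.extract_split_alignments(base, 2000)
    cands = rm.cluster_evidence(ev)
    assert len(cands) == 1 and cands[0].support == 2

    far = _split_pair(1_000, 50_000, "a") + _split_pair(1_000 + 50, 50_000, "b")
    cands = rm.cluster_evidence(rm.extract_split_alignments(far, 2000))
    assert len(cands) == 2

    jittered = []
    rng = np.random.default_rng(1)
    for i, off in enumerate(rng.integers(-3, 4, size=8)):
        jittered += _split_pair(1_000 + int(off), 50_000 + int(off), f"r{i}")
    cands = rm.cluster_evidence(rm.extract_split_alignments(jittered, 2000))
    assert len(cands) == 1
    assert abs(cands[0].breakpoint_a.pos - 1_074) <= 5
    assert abs(cands[0].breakpoint_b.pos - 50_000) <= 5


def test_pseudo_junction_threshold_exact_and_empty():
    lengths = {"c": 50_000}
    assert pseudo_junction_threshold([], lengths, 5_000) == 0.0
    # 30 reads spanning every one of the 9 internal boundaries
    recs = []
    for k in range(1, 10):
        for i in range(30):
            recs.append(
                AlignmentRecord(f"b{k}r{i}", 0, "c", k * 5_000 - 75, 60, "150M", "A" * 150)
            )
    assert pseudo_junction_threshold(recs, lengths, 5_000) == 15.0
    with pytest.raises(ValueError):
        pseudo_junction_threshold([], {"c": 0}, 5_000)


def test_threshold_tracks_depth_and_poisson_oracle(small_ref, small_lengths):
    """Threshold ~ point depth / 2, and doubles when depth doubles (+-10%)."""
    cfg = small_config(rm.MiniType.NO_MINI)
    recs10, _ = rm.simulate_individual(small_ref, cfg, depth=10, seed=51)
    recs20, _ = rm.simulate_individual(small_ref, cfg, depth=20, seed=52)
    t10 = pseudo_junction_threshold(recs10, small_lengths)
    t20 = pseudo_junction_threshold(recs20, small_lengths)
    assert abs(t10 - 5.0) <= 1.0  # expected point depth 10 -> threshold 5
    assert abs(t20 / t10 - 2.0) <= 0.2


def _candidate(support_by_sample):
    bp_a = rm.Breakpoint("c", 1_000, "left")
    bp_b = rm.Breakpoint("c", 50_000, "right")
    evidence = [
        rm.SplitReadEvidence(f"{sid}.{i}/1", sid, ("c", 1, 75, 1), ("c", 50_000, 50_075, 1), bp_a, bp_b)
        for sid, n in support_by_sample.items()
        for i in range(n)
    ]
    return rm.CandidateJunction(bp_a, bp_b, "head_to_tail", evidence)


def test_filter_rules():
    # a single control read kills the candidate
    cand = _candidate({"car": 12, "ctl": 1})
    assert rm.filter_junctions([cand], {"car"}, {"ctl"}, 5.0) == []
    assert cand.carrier_exclusive is False
    # below threshold
    cand = _candidate({"car": 1})
    assert rm.filter_junctions([cand], {"car"}, {"ctl"}, 5.0) == []
    # carrier-exclusive and above threshold
    cand = _candidate({"car": 12})
    assert rm.filter_junctions([cand], {"car"}, {"ctl"}, 5.0) == [cand]
    # empty control set: exclusivity passes vacuously
    cand = _candidate({"car": 12})
    assert rm.filter_junctions([cand], {"car"}, set(), 5.0) == [cand]
    # per-sample thresholds use each carrier's own value
    cand = _candidate({"carA": 6, "carB": 6})
    accepted = rm.filter_junctions([cand], {"carA", "carB"}, set(), {"carA": 10.0, "carB": 5.0})
    assert accepted == [cand]


def test_orientation_chisq_examples():
    def with_counts(ht, tt, hh):
        cands = []
        for orient, n in (("head_to_tail", ht), ("tail_to_tail", tt), ("head_to_head", hh)):
            for _ in range(n):
                c = _candidate({"s": 1})
                c.orientation = orient
                cands.append(c)
        return cands

    stat, p = rm.orientation_chisq(with_counts(3, 3, 3))
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    stat, p = rm.orientation_chisq(with_counts(7, 2, 1))
    # hand-computed: sum((o-e)^2/e) with e=10/3 -> 6.2
    assert stat == pytest.approx(6.2, abs=0.01)
    assert p == pytest.approx(stats.chi2.sf(6.2, 2), abs=1e-6)
    assert 0.04 < p < 0.05

    _, p = rm.orientation_chisq(with_counts(4, 3, 3))
    assert p > 0.9

    with pytest.raises(ValueError):
        rm.orientation_chisq([])


def test_accepted_junctions_stay_inside_mini_region(small_ref, small_lengths, deleted_cohort):
    alignments, truths = deleted_cohort
    ev, thresholds = [], {}
    for sid, recs in alignments.items():
        ev += rm.extract_split_alignments(recs, 2000, sid)
        thresholds[sid] = pseudo_junction_threshold(recs, small_lengths)
    cands = rm.cluster_evidence(ev)
    accepted = rm.filter_junctions(
        cands, {"car1", "car2", "car3"}, {"ctl1", "ctl2"}, thresholds
    )
    assert accepted, "expected at least one accepted junction"
    lo, hi = small_ref.mini_region
    for cand in accepted:
        assert lo <= cand.breakpoint_a.pos <= hi
        assert lo <= cand.breakpoint_b.pos <= hi
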