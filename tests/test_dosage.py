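"""Dosage profiling: binning, normalization, dip finding, type calling."""

from __future__ import annotations

import numpy as np
import pytest

import ringmini as rm
from ringmini.samio import AlignmentRecord
from tests.conftest import SMALL_DELETION, SMALL_REGION, profile_for, small_config


def _read(pos, chrom="c", flag=0, seq="A" * 150):
    return AlignmentRecord("q", flag, chrom, pos, 60, f"{len(seq)}M", seq)


def test_empty_and_point_mass_binning():
    lengths = {"c": 100_000}
    cov = rm.bin_coverage([], 10_000, lengths)
    assert cov.total == 0 and cov.counts["c"].sum() == 0
    reads = [_read(35_001) for _ in range(100)]
    cov = rm.bin_coverage(reads, 10_000, lengths)
    assert cov.counts["c"][3] == 100
    assert cov.counts["c"].sum() == 100


def test_supplementary_segments_not_double_counted():
    lengths = {"c": 100_000}
    recs = [_read(5_000), _read(50_000, flag=0x800)]
    cov = rm.bin_coverage(recs, 10_000, lengths)
    assert cov.total == 1


def test_normalization_identity_is_exactly_two(carrier_pair, small_lengths):
    (_, _), (recs_ctl, _) = carrier_pair
    cov = rm.bin_coverage(recs_ctl, 2_500, small_lengths)
    prof = rm.normalize_dosage(cov, cov)
    vals = np.concatenate(list(prof.values.values()))
    assert np.nanmax(np.abs(vals - 2.0)) == 0.0


def test_scale_invariance_of_dosage(carrier_pair, small_lengths):
    (recs_car, _), (recs_ctl, _) = carrier_pair
    s = rm.bin_coverage(recs_car, 2_500, small_lengths)
    c = rm.bin_coverage(recs_ctl, 2_500, small_lengths)
    scaled = rm.CoverageVector(s.bin_size, {k: v * 7 for k, v in s.counts.items()}, s.total * 7)
    a = rm.normalize_dosage(s, c)
    b = rm.normalize_dosage(scaled, c)
    for chrom in a.values:
        np.testing.assert_allclose(a.values[chrom], b.values[chrom])


def test_one_full_carrier_mini_region_sits_at_three(carrier_pair, small_lengths, small_ref):
    (recs_car, _), (recs_ctl, _) = carrier_pair
    prof = profile_for(recs_car, recs_ctl, small_lengths)
    vals = prof.region_values(small_ref.mini_chrom, small_ref.mini_region)
    assert abs(np.nanmean(vals) - 3.0) <= 0.15


def test_per_bin_scatter_follows_poisson_oracle(carrier_pair, small_lengths, small_ref):
    """Outside the mini region, per-bin dosage is 2 with Poisson-limited spread."""
    (recs_car, _), (recs_ctl, _) = carrier_pair
    prof = profile_for(recs_car, recs_ctl, small_lengths)
    vals = prof.values[small_ref.mini_chrom].copy()
    first = (small_ref.mini_region[0] - 1) // 2_500
    last = (small_ref.mini_region[1] - 1) // 2_500
    outside = np.delete(vals, np.arange(first, last + 1))
    outside = outside[np.isfinite(outside)]
    lam = 10.0 * 2_500 / 150  # expected reads per bin at 10x
    # read pairs within one bin roughly double the count variance
    sd = 2.0 * np.sqrt(2 * 2 / lam)
    assert abs(np.mean(outside) - 2.0) < 0.05
    assert np.std(outside) < 1.5 * sd
    assert np.all(np.abs(outside - 2.0) < 6 * sd)


def test_two_deleted_carrier_copy_arithmetic(small_ref, small_lengths, deleted_cohort):
    """Retained mini bins ~4.0, deletion-interval bins ~2.0 for 2x-deleted carriers."""
    alignments, _ = deleted_cohort
    prof = profile_for(alignments["car1"], alignments["ctl1"], small_lengths)
    region_vals = prof.region_values(small_ref.mini_chrom, small_ref.mini_region)
    del_first = (SMALL_DELETION[0] - 1) // 2_500 - (SMALL_REGION[0] - 1) // 2_500
    del_last = (SMALL_DELETION[1] - 1) // 2_500 - (SMALL_REGION[0] - 1) // 2_500
    deletion_vals = region_vals[del_first : del_last + 1]
    retained_vals = np.delete(region_vals, np.arange(del_first, del_last + 1))
    # extra junctions remove two further small slices; use medians
    assert abs(np.nanmedian(retained_vals) - 4.0) <= 0.2
    assert abs(np.nanmedian(deletion_vals) - 2.0) <= 0.2


def test_deleted_interval_estimation_trivial_and_truth():
    bs = 2_500
    region = (1, 100 * bs)
    flat = rm.DosageProfile(bs, {"c": np.full(100, 3.0)})
    assert rm.estimate_deleted_interval(flat, "c", region) is None
    dipped = rm.DosageProfile(bs, {"c": np.full(100, 3.0)})
    dipped.values["c"][40:50] = 2.0
    est = rm.estimate_deleted_interval(dipped, "c", region)
    assert est == (40 * bs + 1, 50 * bs)


def test_deleted_interval_matches_truth_with_high_jaccard(
    small_ref, small_lengths, deleted_cohort
):
    from ringmini.intervals import jaccard

    alignments, truths = deleted_cohort
    prof = profile_for(alignments["car2"], alignments["ctl1"], small_lengths)
    est = rm.estimate_deleted_interval(prof, small_ref.mini_chrom, small_ref.mini_region)
    assert est is not None
    assert jaccard(est, SMALL_DELETION) >= 0.8


@pytest.mark.parametrize(
    "retained,in_deletion,expected",
    [
        (2.0, 2.0, rm.MiniType.NO_MINI),
        (3.0, 3.0, rm.MiniType.ONE_FULL),
        (4.0, 4.0, rm.MiniType.TWO_FULL),
        (3.0, 2.0, rm.MiniType.ONE_DELETED),
        (4.0, 2.0, rm.MiniType.TWO_DELETED),
        (4.0, 3.0, rm.MiniType.FULL_PLUS_DELETED),
    ],
)
def test_template_classification_on_constructed_profiles(retained, in_deletion, expected):
    bs = 2_500
    length = 400 * bs
    region = (100 * bs + 1, 300 * bs)
    deletion = (180 * bs + 1, 220 * bs)
    vals = np.full(400, 2.0)
    first, last = 100, 299
    vals[first : last + 1] = retained
    vals[180:220] = in_deletion
    prof = rm.DosageProfile(bs, {"c": vals})
    mt, dist = rm.classify_mini_type(prof, "c", region, deletion)
    assert mt == expected
    assert dist < 0.05


def test_unclassifiable_when_too_many_bins_missing():
    bs = 2_500
    vals = np.full(100, 2.0)
    vals[:30] = np.nan
    prof = rm.DosageProfile(bs, {"c": vals})
    mt, dist = rm.classify_mini_type(prof, "c", (1, 100 * bs), None)
    assert mt is None and np.isnan(dist)


def test_pca_cluster_trivial_cases(small_lengths):
    bs = 2_500
    region = (1, 100 * bs)
    flat = [rm.DosageProfile(bs, {"c": np.full(100, 2.0)}) for _ in range(4)]
    labels, xy = rm.pca_cluster(flat, "c", region)
    assert len(set(labels)) == 1
    assert xy.shape == (4, 2)
    gain = [rm.DosageProfile(bs, {"c": np.full(100, 3.0)}) for _ in range(4)]
    labels, _ = rm.pca_cluster(flat + gain, "c", region)
    assert len(set(labels)) == 2
    first = set(labels[:4])
    assert len(first) == 1 and first.isdisjoint(set(labels[4:]))
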