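"""Feature enrichment around breakpoints against a resampled null.

For each breakpoint a window is centered on its position and the fraction
of window bases covered by a feature track (genes or repeats) is its
density.  The null is built by repeatedly drawing pseudo-breakpoints
uniformly from a control region (the pericentromeric analog the real
breakpoints live in) and recording the mean density per repetition; the
enrichment ratio is the mean real density divided by the grand mean of the
null, and a two-sided one-sample t-test compares the per-breakpoint real
densities with that null mean.  A separate binomial test asks whether the
number of breakpoints falling inside gene bodies exceeds chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import Interval, merge_intervals

N_PSEUDO = 10_000  # pseudo-breakpoints per repetition
N_REPS = 1_000  # repetitions of the resampling


@dataclass
class EnrichmentResult:
    """Enrichment of one feature track around the real breakpoints."""

    feature: str
    window: int
    n_breakpoints: int
    ratio: float
    p_value: float
    null_mean: float
    null_sd: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _coverage_prefix(feature_intervals: list[Interval], length: int) -> np.ndarray:
    """Prefix sums of the feature indicator over positions 1..length."""
    cov = np.zeros(length + 1, dtype=np.int64)
    for s, e in merge_intervals(feature_intervals):
        s, e = max(1, s), min(length, e)
        if s <= e:
            cov[s - 1] += 1
            cov[e] -= 1
    return np.concatenate([[0], np.cumsum(np.cumsum(cov)[:-1])])


def feature_density(
    breakpoint_pos: int,
    feature_intervals: list[Interval],
    window: int,
    chrom_length: int,
) -> float:
    """Fraction of the breakpoint-centered window covered by the feature.

    The window is ``[pos - window/2, pos + window/2)``, truncated at
    chromosome ends with the denominator adjusted.
    """
    if not (1 <= breakpoint_pos <= chrom_length):
        raise ValueError(f"breakpoint {breakpoint_pos} outside chromosome 1..{chrom_length}")
    if window <= 0:
        raise ValueError("window must be positive")
    half = window // 2
    start = max(1, breakpoint_pos - half)
    end = min(chrom_length, breakpoint_pos + half - 1)
    denom = end - start + 1
    covered = 0
    for s, e in merge_intervals(feature_intervals):
        lo, hi = max(s, start), min(e, end)
        if lo <= hi:
            covered += hi - lo + 1
    return covered / denom


def _densities(
    positions: np.ndarray,
    prefix: np.ndarray,
    window: int,
    chrom_length: int,
) -> np.ndarray:
    half = window // 2
    starts = np.maximum(1, positions - half)
    ends = np.minimum(chrom_length, positions + half - 1)
    return (prefix[ends] - prefix[starts - 1]) / (ends - starts + 1)


def resample_null(
    feature_intervals: list[Interval],
    control_region: Interval,
    chrom_length: int,
    window: int,
    n_pseudo: int = N_PSEUDO,
    reps: int = N_REPS,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of mean feature densities at random positions.

    Each repetition draws ``n_pseudo`` positions uniformly from the control
    region and records the mean window density; the ``reps``-length array
    is returned.  Deterministic for a fixed seed.
    """
    lo, hi = control_region
    if hi <= lo:
        raise ValueError("control region must have positive span")
    rng = np.random.default_rng(seed)
    prefix = _coverage_prefix(feature_intervals, chrom_length)
    out = np.empty(reps)
    for r in range(reps):
        positions = rng.integers(lo, hi + 1, size=n_pseudo)
        out[r] = _densities(positions, prefix, window, chrom_length).mean()
    return out


def enrichment_test(
    real_breakpoints: list[int],
    feature_intervals: list[Interval],
    window: int,
    null: np.ndarray,
    chrom_length: int,
    feature_name: str = "feature",
) -> EnrichmentResult:
    """Enrichment ratio and one-sample t-test against the null grand mean.

    ratio = mean real density / grand mean of the null distribution;
    p = two-sided one-sample t-test of the per-breakpoint densities against
    the null grand mean.  With zero variance among real densities the test
    is degenerate and p is reported as 1 with a warning flag.
    """
    if len(real_breakpoints) < 2:
        raise ValueError("enrichment t-test needs at least two breakpoints")
    prefix = _coverage_prefix(feature_intervals, chrom_length)
    real = _densities(np.asarray(real_breakpoints), prefix, window, chrom_length)
    null_mean = float(np.mean(null))
    ratio = float(np.mean(real) / null_mean) if null_mean > 0 else float("inf")
    degenerate = bool(np.ptp(real) == 0)
    if degenerate:
        warnings.warn("all real breakpoint densities identical; t-test degenerate")
        p = 1.0
        stat = float("nan")
    else:
        stat, p = stats.ttest_1samp(real, popmean=null_mean)
        p = float(p)
    return EnrichmentResult(
        feature=feature_name,
        window=window,
        n_breakpoints=len(real_breakpoints),
        ratio=ratio,
        p_value=p,
        null_mean=null_mean,
        null_sd=float(np.std(null)),
        degenerate=degenerate,
    )


def gene_disruption_test(
    breakpoints: list[int],
    gene_intervals: list[Interval],
    region: Interval,
) -> tuple[int, int, float]:
    """Binomial test for breakpoints falling inside gene bodies.

    ``k`` breakpoints of ``n`` land inside a gene body; under the null each
    lands in a gene with probability equal to the gene-body base fraction
    of the region.  Returns ``(k, n, upper-tail p of >= k successes)``.
    """
    lo, hi = region
    if hi < lo:
        raise ValueError("empty region")
    merged = merge_intervals(gene_intervals)
    frac = sum(min(e, hi) - max(s, lo) + 1 for s, e in merged if min(e, hi) >= max(s, lo)) / (
        hi - lo + 1
    )
    n = len(breakpoints)
    k = sum(1 for p in breakpoints if any(s <= p <= e for s, e in merged))
    p_val = float(stats.binom.sf(k - 1, n, frac)) if n else 1.0
    return k, n, p_val
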