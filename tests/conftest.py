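"""Shared fixtures: a compact synthetic world reused across test modules.

The "small" world is a 1 Mb chromosome with a 300 kb mini region — the same
proportions as the default 2 Mb world but ~2x faster to simulate; tests
that exercise the published-scale defaults build the default world
explicitly.
"""

from __future__ import annotations

import numpy as np
import pytest

import ringmini as rm

SMALL_LENGTH = 1_000_000
SMALL_REGION = (650_001, 950_000)
SMALL_CEN = (750_001, 850_000)
SMALL_DELETION = (800_001, 865_000)


@pytest.fixture(scope="session")
def small_ref() -> rm.ReferenceBundle:
    return rm.generate_reference(
        length=SMALL_LENGTH, mini_region=SMALL_REGION, seed=42
    )


@pytest.fixture(scope="session")
def small_lengths(small_ref) -> dict[str, int]:
    return {c: len(s) for c, s in small_ref.sequences.items()}


def small_config(mt: rm.MiniType, extras=()) -> rm.MiniConfig:
    return rm.MiniConfig(
        n_full=mt.n_full,
        n_deleted=mt.n_deleted,
        deletion_interval=SMALL_DELETION if mt.n_deleted else None,
        extra_junctions=list(extras) if mt.n_deleted else [],
    )


@pytest.fixture(scope="session")
def carrier_pair(small_ref):
    """A ONE_FULL carrier and a NO_MINI control at 10x, with truths."""
    recs_car, truth_car = rm.simulate_individual(
        small_ref, small_config(rm.MiniType.ONE_FULL), seed=101, sample_id="carrier"
    )
    recs_ctl, truth_ctl = rm.simulate_individual(
        small_ref, small_config(rm.MiniType.NO_MINI), seed=102, sample_id="control"
    )
    return (recs_car, truth_car), (recs_ctl, truth_ctl)


@pytest.fixture(scope="session")
def deleted_cohort(small_ref):
    """Three 2x-deleted carriers with two extra junctions, plus two controls."""
    extras = [(700_000, "left", 710_000, "right"), (880_000, "left", 900_000, "right")]
    cfg = small_config(rm.MiniType.TWO_DELETED, extras)
    configs = {
        "car1": cfg,
        "car2": cfg,
        "car3": cfg,
        "ctl1": small_config(rm.MiniType.NO_MINI),
        "ctl2": small_config(rm.MiniType.NO_MINI),
    }
    return rm.simulate_cohort(small_ref, configs, seed=77)


def profile_for(recs, control_recs, lengths, bin_size=2_500):
    sample = rm.bin_coverage(recs, bin_size, lengths)
    control = rm.bin_coverage(control_recs, bin_size, lengths)
    return rm.normalize_dosage(sample, control)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
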