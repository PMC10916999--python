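import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tapcog.keystroke_io import EDUCATION_LEVELS, Hand, KeyEvent, TappingBlock, TestType

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_block(
    downs,
    dwell=60,
    keys=None,
    test_type=TestType.SINGLE_KEY,
    hand=Hand.DOMINANT,
    block_index=1,
    duration_s=None,
):
    """Build a TappingBlock from key-down times (ms); dwell scalar or list."""
    downs = list(downs)
    if np.isscalar(dwell):
        dwell = [dwell] * len(downs)
    if keys is None:
        keys = ["space"] * len(downs)
    if duration_s is None:
        duration_s = 10.0 if TestType(test_type) is TestType.SINGLE_KEY else 30.0
    events = [
        KeyEvent(key_label=k, down_ms=int(d), up_ms=int(d) + int(w))
        for k, d, w in zip(keys, downs, dwell)
    ]
    return TappingBlock(
        test_type=test_type,
        hand=hand,
        block_index=block_index,
        duration_s=duration_s,
        events=events,
    )


@pytest.fixture
def block_factory():
    return make_block


def full_protocol_blocks(rate_ms=180):
    """A complete 4+2 protocol of rhythmic blocks."""
    blocks = [
        make_block(range(0, 9800, rate_ms), block_index=b) for b in (1, 2, 3, 4)
    ]
    for hand in (Hand.DOMINANT, Hand.NON_DOMINANT):
        downs = list(range(0, 29500, 450))
        keys = ["s" if i % 2 == 0 else "semicolon" for i in range(len(downs))]
        blocks.append(
            make_block(
                downs,
                keys=keys,
                test_type=TestType.ALTERNATE_KEY,
                hand=hand,
                block_index=1,
            )
        )
    return blocks


@pytest.fixture
def protocol_blocks():
    return full_protocol_blocks()


def make_participant(pid="p1", blocks=None, **overrides):
    from tapcog.keystroke_io import ParticipantRecord

    kwargs = dict(
        participant_id=pid,
        age_years=66.0,
        sex="female",
        education_level="undergraduate",
        hads_anxiety=4,
        hads_depression=3,
        memory_change=False,
        dementia_dx=False,
        memory_impairment_dx=False,
        pd_dx=False,
        ms_dx=False,
        paltea6=4,
        swmbe6=3,
        swms=8,
        blocks=blocks if blocks is not None else full_protocol_blocks(),
    )
    kwargs.update(overrides)
    return ParticipantRecord(**kwargs)


@pytest.fixture
def participant_factory():
    return make_participant


def random_covariate_frame(rng, n):
    """Covariates-only analysis frame with all six education levels present."""
    df = pd.DataFrame(
        {
            "age_years": rng.uniform(52, 88, n).round(1),
            "sex": np.where(rng.random(n) < 0.7, "female", "male"),
            "education_level": rng.choice(EDUCATION_LEVELS, n),
            "hads_anxiety": rng.integers(0, 15, n),
            "hads_depression": rng.integers(0, 12, n),
        }
    )
    # guarantee every level appears so dummies are never all-zero
    df.loc[: len(EDUCATION_LEVELS) - 1, "education_level"] = list(EDUCATION_LEVELS)
    return df


@pytest.fixture
def covariate_frame_factory():
    return random_covariate_frame


@pytest.fixture(scope="session")
def small_synthetic_cohort():
    """A small seeded cohort with a few injected exclusion flags, shared across tests."""
    from tapcog.synthetic_cohort import ExclusionInjection, SimConfig, simulate_cohort

    cfg = SimConfig(
        n_participants=60,
        seed=20,
        exclusions=ExclusionInjection(n_symptomatic=4, n_pd=1, n_ms=2, n_incomplete=3),
    )
    return cfg, simulate_cohort(cfg)
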