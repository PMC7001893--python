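import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swaykit import skeleton_io as sio
from swaykit import synthetic_data as syn

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def subject():
    return syn.SubjectMeta(subject_id="S001", height_cm=172.0, mass_kg=75.1)


def make_standing_sequence(n_frames=10, rate_hz=30.0, jitter_rng=None, **meta):
    """A plausible standing skeleton: template pose, optionally jittered."""
    template = syn._TEMPLATE * 1.72  # metres
    pos = np.broadcast_to(template, (n_frames, 25, 3)).copy()
    if jitter_rng is not None:
        pos = pos + jitter_rng.normal(0, 0.01, size=pos.shape)
    meta.setdefault("height_cm", 172.0)
    return sio.SkeletonSequence(
        timestamps=np.arange(n_frames) / rate_hz,
        positions=pos,
        states=np.full((n_frames, 25), sio.TrackingState.tracked, dtype=np.uint8),
        rate_hz=rate_hz,
        **meta,
    )


@pytest.fixture
def standing_seq():
    return make_standing_sequence(n_frames=60)


@pytest.fixture
def jittered_seq(rng):
    return make_standing_sequence(n_frames=60, jitter_rng=rng)


@pytest.fixture(scope="session")
def null_study():
    """One zero-injected-bias paired study reused across analysis tests."""
    return syn.generate_study(20, repeats=2, seed=0)
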