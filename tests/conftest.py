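import numpy as np
import pytest
from hypothesis import settings

from popkin.session import (
    AccelSample,
    BubbleTrack,
    GameConfig,
    PopEvent,
    SessionRecord,
    TouchSample,
    TouchTrace,
)
from popkin.simulate import AgentProfile, nt_profile, simulate_session

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> GameConfig:
    return GameConfig()


def make_trace(touch_id, points, t0=1.0, dt=1 / 60):
    """Build a touch trace from (x, y) points starting at time t0."""
    return TouchTrace(
        touch_id=touch_id,
        samples=[
            TouchSample(t=t0 + k * dt, x_mm=float(x), y_mm=float(y), touch_id=touch_id)
            for k, (x, y) in enumerate(points)
        ],
    )


def make_bubble(bubble_id="B0", lane=2, character_id=3, spawn_t=0.0,
                center_x_mm=80.0, y0_mm=220.0, speed_mm_s=20.0,
                end_t=10.0, end_reason="exited"):
    return BubbleTrack(bubble_id=bubble_id, lane=lane, character_id=character_id,
                       spawn_t=spawn_t, center_x_mm=center_x_mm, y0_mm=y0_mm,
                       speed_mm_s=speed_mm_s, end_t=end_t, end_reason=end_reason)


def minimal_record(config=GameConfig(), session_id="s0", **kw) -> SessionRecord:
    """A tiny hand-built valid record: one touch popping one bubble."""
    bubble = make_bubble(end_t=5.0, end_reason="popped")
    # bubble center at t=5: (80, 220 - 20*5) = (80, 120)
    trace = make_trace("T0", [(82.0, 121.0), (83.0, 122.0)], t0=5.0)
    pop = PopEvent(t=5.0, bubble_id="B0", touch_id="T0",
                   distance_to_center_mm=float(np.hypot(2.0, 1.0)))
    accel = [AccelSample(t=k / 60, ax=0.0, ay=0.0, az=9.81) for k in range(1200)]
    defaults = dict(
        session_id=session_id, group="NT", age_months=24.0, config=config,
        touches=[trace], accel=accel, bubbles=[bubble], pops=[pop],
    )
    defaults.update(kw)
    return SessionRecord(**defaults)


def random_small_session(seed: int) -> SessionRecord:
    """A simulated session from a randomised agent profile (for oracles)."""
    rng = np.random.default_rng(seed)
    profile = AgentProfile(
        aim_sd_mm=float(rng.uniform(5, 25)),
        touch_duration_mean_s=float(rng.uniform(0.1, 0.5)),
        touch_duration_sd_s=float(rng.uniform(0.0, 0.25)),
        path_length_scale_mm=float(rng.uniform(0, 15)),
        inter_touch_mean_s=float(rng.uniform(0.4, 2.0)),
        touches_per_target_mean=float(rng.uniform(1.0, 3.0)),
        repeat_prob=float(rng.uniform(0, 1)),
        force_scale=float(rng.uniform(0, 2)),
        double_touch_prob=float(rng.uniform(0, 0.3)),
        accel_noise_sd=float(rng.uniform(0, 0.2)),
    )
    age = float(rng.uniform(18, 36))
    return simulate_session(profile, age, seed=int(rng.integers(2 ** 31)),
                            session_id=f"rand_{seed}")


@pytest.fixture(scope="session")
def nt_session() -> SessionRecord:
    return simulate_session(nt_profile(), 27.0, seed=11, session_id="nt_11")
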