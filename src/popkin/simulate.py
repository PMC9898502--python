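"""Synthetic bubble-popping sessions: game dynamics plus a parametric child agent.

The game shows one bubble per vertical lane, rising at constant speed from the
bottom of the screen.  A popped bubble is replaced, in the same lane, by a
bubble with the same cartoon character; a bubble that exits the top is
replaced by a random character.  The agent repeatedly targets a bubble
(preferring the one it just popped with probability ``repeat_prob``), touches
the screen with isotropic Gaussian aim error around the bubble's instantaneous
center, lingers for a lognormal duration while its finger drifts along a
random-walk path, and occasionally produces rapid double touches.  Touch
impacts excite a Gaussian-shaped acceleration impulse on the device's normal
axis, on top of gravity and sensor noise.

Group differences, age trends and clinical-score correlations are all induced
generatively: group profiles differ in aim error, touch duration, path length,
attempts per target and repeat preference; an age model tilts profile
parameters linearly in age; clinical scores load linearly on a latent motor
skill (defined as the negative standardised aim error) plus Gaussian noise.

Everything is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .session import (
    AccelSample,
    BubbleTrack,
    GameConfig,
    PopEvent,
    SessionRecord,
    TouchSample,
    TouchTrace,
)

__all__ = [
    "AgentProfile",
    "AgeModel",
    "CohortSpec",
    "simulate_bubbles",
    "simulate_agent_touches",
    "synthesize_accel",
    "simulate_session",
    "simulate_cohort",
    "nt_profile",
    "case_profile",
    "default_age_model",
    "default_cohort_spec",
]

N_CHARACTERS = 10
IMPULSE_SIGMA_S = 0.02  # Gaussian impulse scale; +/-2 sigma spans 80 ms
LANE_STAGGER_S = 0.25  # successive lanes start this much later, desynchronising them


@dataclass(frozen=True)
class AgentProfile:
    """Generative parameters of one child-agent's touch behavior."""

    aim_sd_mm: float = 10.0
    touch_duration_mean_s: float = 0.25
    touch_duration_sd_s: float = 0.10
    path_length_scale_mm: float = 6.0
    inter_touch_mean_s: float = 0.8
    touches_per_target_mean: float = 1.5
    repeat_prob: float = 0.4
    force_scale: float = 1.0
    double_touch_prob: float = 0.10
    accel_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("aim_sd_mm", "touch_duration_sd_s", "path_length_scale_mm",
                     "force_scale", "accel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"AgentProfile.{name} must be >= 0")
        for name in ("touch_duration_mean_s", "inter_touch_mean_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"AgentProfile.{name} must be > 0")
        if not self.touches_per_target_mean >= 1.0:
            raise ValueError("touches_per_target_mean must be >= 1 (geometric mean)")
        for name in ("repeat_prob", "double_touch_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"AgentProfile.{name} must be in [0, 1]")


# lower bounds keeping age-adjusted parameters in their legal domains
_PROFILE_FLOORS = {
    "aim_sd_mm": 0.5,
    "touch_duration_mean_s": 0.05,
    "touch_duration_sd_s": 0.0,
    "path_length_scale_mm": 0.0,
    "inter_touch_mean_s": 0.15,
    "touches_per_target_mean": 1.0,
    "repeat_prob": 0.0,
    "force_scale": 0.0,
    "double_touch_prob": 0.0,
    "accel_noise_sd": 0.0,
}


@dataclass(frozen=True)
class AgeModel:
    """Linear per-month adjustment of profile parameters around a reference age.

    ``adjusted = profile.param + slope * (age_months - reference)``, clipped to
    the parameter's legal domain.  The default slopes make older children
    faster (shorter gaps and touch durations), more accurate (smaller aim
    error) and steadier (shorter drag paths), which induces the canonical age
    trends: more touches and pops, smaller distance-to-center, shorter touch
    duration/length.
    """

    slopes: Mapping[str, float] = field(default_factory=lambda: {
        "aim_sd_mm": -0.15,
        "touch_duration_mean_s": -0.006,
        "touch_duration_sd_s": -0.002,
        "path_length_scale_mm": -0.15,
        "inter_touch_mean_s": -0.018,
    })
    age_range_months: tuple[float, float] = (18.0, 36.0)
    reference_age_months: Optional[float] = None

    @property
    def reference(self) -> float:
        if self.reference_age_months is not None:
            return self.reference_age_months
        lo, hi = self.age_range_months
        return 0.5 * (lo + hi)

    def adjust(self, profile: AgentProfile, age_months: float) -> AgentProfile:
        delta = age_months - self.reference
        updates = {}
        for name, slope in self.slopes.items():
            base = getattr(profile, name)
            val = base + slope * delta
            lo = _PROFILE_FLOORS.get(name, 0.0)
            hi = 1.0 if name in ("repeat_prob", "double_touch_prob") else math.inf
            updates[name] = float(min(max(val, lo), hi))
        return replace(profile, **updates)


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``groups`` maps a group label to (profile, n_participants).
    ``clinical_score_model`` maps a score name to (loading, noise_sd): the
    score is ``loading * latent_skill + N(0, noise_sd)`` where latent skill is
    the negative of the cohort-standardised aim error.
    """

    groups: Mapping[str, tuple[AgentProfile, int]]
    age_model: AgeModel = field(default_factory=AgeModel)
    iq_model: Optional[Mapping[str, tuple[float, float]]] = None
    clinical_score_model: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    config: GameConfig = field(default_factory=GameConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, (_, n) in self.groups.items():
            if n < 1:
                raise ValueError(f"group {label!r} needs n_participants >= 1")
        for name, (_, sd) in self.clinical_score_model.items():
            if sd < 0:
                raise ValueError(f"clinical score {name!r} noise SD must be >= 0")


# ---------------------------------------------------------------------------
# Bubble dynamics


def lane_center_x(config: GameConfig, lane: int) -> float:
    return (lane + 0.5) * config.screen_width_mm / config.n_lanes


def _travel_time(config: GameConfig) -> float:
    # center starts at the bottom edge and exits once it clears the top
    return (config.screen_height_mm + config.bubble_radius_mm) / config.bubble_speed_mm_s


def simulate_bubbles(
    config: GameConfig,
    pop_times_by_bubble: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[BubbleTrack]:
    """Build the lane-by-lane bubble schedule for a fixed set of pop times.

    Bubble ids are deterministic (``L{lane}B{k}``), so callers can key
    ``pop_times_by_bubble`` on them.  A popped bubble respawns in the same
    lane with the same character one sensor frame later; an exited bubble is
    followed by a uniformly random character.
    """
    pops = dict(pop_times_by_bubble or {})
    rng = np.random.default_rng(seed)
    T = config.session_duration_s
    frame = 1.0 / config.sensor_rate_hz
    tracks: list[BubbleTrack] = []
    for lane in range(config.n_lanes):
        t = lane * LANE_STAGGER_S
        k = 0
        char = int(rng.integers(N_CHARACTERS))
        while t < T - 1e-9:
            bid = f"L{lane}B{k}"
            exit_t = t + _travel_time(config)
            natural_end = min(exit_t, T)
            if bid in pops:
                pop_t = pops[bid]
                if not (t < pop_t <= natural_end):
                    raise ValueError(
                        f"pop time {pop_t} for {bid} outside on-screen interval "
                        f"({t}, {natural_end}]"
                    )
                tracks.append(BubbleTrack(
                    bubble_id=bid, lane=lane, character_id=char, spawn_t=t,
                    center_x_mm=lane_center_x(config, lane),
                    y0_mm=config.screen_height_mm,
                    speed_mm_s=config.bubble_speed_mm_s,
                    end_t=pop_t, end_reason="popped",
                ))
                t = pop_t + frame + config.spawn_gap_s
                # same character respawns after a pop
            else:
                tracks.append(BubbleTrack(
                    bubble_id=bid, lane=lane, character_id=char, spawn_t=t,
                    center_x_mm=lane_center_x(config, lane),
                    y0_mm=config.screen_height_mm,
                    speed_mm_s=config.bubble_speed_mm_s,
                    end_t=natural_end, end_reason="exited",
                ))
                t = exit_t + config.spawn_gap_s
                char = int(rng.integers(N_CHARACTERS))
            k += 1
    return tracks


# ---------------------------------------------------------------------------
# Agent behavior


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    if sd <= 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _make_trace(
    rng: np.random.Generator,
    touch_id: str,
    onset_t: float,
    onset_xy: tuple[float, float],
    profile: AgentProfile,
    config: GameConfig,
) -> TouchTrace:
    mu, sigma = _lognormal_params(profile.touch_duration_mean_s,
                                  profile.touch_duration_sd_s)
    duration = float(rng.lognormal(mu, sigma)) if sigma > 0 else profile.touch_duration_mean_s
    fs = config.sensor_rate_hz
    n = max(1, int(round(duration * fs)) + 1)
    # keep every sample inside the session window
    while n > 1 and onset_t + (n - 1) / fs > config.session_duration_s:
        n -= 1
    x, y = onset_xy
    x = float(min(max(x, 0.0), config.screen_width_mm))
    y = float(min(max(y, 0.0), config.screen_height_mm))
    samples = [TouchSample(t=onset_t, x_mm=x, y_mm=y, touch_id=touch_id)]
    if n > 1:
        total_len = profile.path_length_scale_mm * float(rng.uniform(0.5, 1.5))
        step = total_len / (n - 1)
        angles = rng.uniform(0.0, 2.0 * math.pi, n - 1)
        for k in range(1, n):
            ang = angles[k - 1]
            x = min(max(x + step * math.cos(ang), 0.0), config.screen_width_mm)
            y = min(max(y + step * math.sin(ang), 0.0), config.screen_height_mm)
            samples.append(TouchSample(t=onset_t + k / fs, x_mm=x, y_mm=y,
                                       touch_id=touch_id))
    return TouchTrace(touch_id=touch_id, samples=samples)


def nearest_on_screen(
    bubbles: Sequence[BubbleTrack],
    t: float,
    xy: tuple[float, float],
    popped: set[str] | None = None,
) -> tuple[Optional[BubbleTrack], float]:
    """Nearest on-screen (and not already popped) bubble at instant ``t``.

    Ties are broken by spawn time then bubble id, so the choice is total.
    """
    best: Optional[BubbleTrack] = None
    best_key: tuple[float, float, str] | None = None
    for b in bubbles:
        if popped and b.bubble_id in popped:
            continue
        if not b.on_screen(t):
            continue
        cx, cy = b.center_at(t)
        d = math.hypot(xy[0] - cx, xy[1] - cy)
        key = (d, b.spawn_t, b.bubble_id)
        if best_key is None or key < best_key:
            best, best_key = b, key
    return best, (best_key[0] if best_key is not None else math.inf)


def simulate_agent_touches(
    profile: AgentProfile,
    bubbles: Sequence[BubbleTrack],
    config: GameConfig,
    seed: int = 0,
) -> tuple[list[TouchTrace], list[PopEvent]]:
    """Generate agent touches against a *fixed* bubble schedule.

    The schedule is not rewritten when a pop occurs (use
    :func:`simulate_session` for the closed loop in which pops trigger
    respawns); popped bubbles are simply unavailable to later touches.
    A pop is emitted iff a touch onset lands within ``pop_radius_mm`` of the
    nearest available bubble.
    """
    rng = np.random.default_rng(seed)
    T = config.session_duration_s
    traces: list[TouchTrace] = []
    pops: list[PopEvent] = []
    popped: set[str] = set()
    last_pop_lane: Optional[int] = None
    cursor = (config.screen_width_mm / 2.0, config.screen_height_mm / 2.0)
    t = float(rng.uniform(0.1, max(0.2, profile.inter_touch_mean_s)))
    idx = 0
    attempts_left = 0
    target_lane: Optional[int] = None
    while t < T - 1e-9:
        if attempts_left <= 0:
            if last_pop_lane is not None and rng.uniform() < profile.repeat_prob:
                target_lane = last_pop_lane
            else:
                b, _ = nearest_on_screen(bubbles, t, cursor, popped)
                target_lane = b.lane if b is not None else None
            p_geo = 1.0 / profile.touches_per_target_mean
            attempts_left = int(rng.geometric(p_geo))
        # aim at the targeted lane's current bubble, if any
        target = None
        if target_lane is not None:
            for b in bubbles:
                if b.lane == target_lane and b.on_screen(t) and b.bubble_id not in popped:
                    target = b
                    break
        if target is None:
            target, _ = nearest_on_screen(bubbles, t, cursor, popped)
        if target is None:  # nothing on screen: wait for the next spawn
            t += 0.1
            attempts_left = 0
            continue
        cx, cy = target.center_at(t)
        aim = (cx + rng.normal(0.0, profile.aim_sd_mm),
               cy + rng.normal(0.0, profile.aim_sd_mm))
        trace = _make_trace(rng, f"T{idx}", t, aim, profile, config)
        idx += 1
        traces.append(trace)
        cursor = (trace.offset.x_mm, trace.offset.y_mm)
        attempts_left -= 1
        hit, d = nearest_on_screen(bubbles, t, (trace.onset.x_mm, trace.onset.y_mm), popped)
        if hit is not None and d <= config.pop_radius_mm:
            pops.append(PopEvent(t=t, bubble_id=hit.bubble_id,
                                 touch_id=trace.touch_id,
                                 distance_to_center_mm=d))
            popped.add(hit.bubble_id)
            last_pop_lane = hit.lane
            attempts_left = 0
        gap = float(rng.exponential(profile.inter_touch_mean_s))
        if rng.uniform() < profile.double_touch_prob:
            gap = float(rng.uniform(0.03, 0.8 * config.double_touch_window_s))
        t = trace.offset.t + max(gap, 1.5 / config.sensor_rate_hz)
    return traces, pops


def synthesize_accel(
    traces: Sequence[TouchTrace],
    profile: AgentProfile,
    config: GameConfig,
    seed: int = 0,
) -> list[AccelSample]:
    """Device inertial stream: gravity + sensor noise + touch-impact impulses.

    Each touch onset adds a Gaussian-shaped impulse on the screen-normal (z)
    axis with peak ``force_scale`` (m/s^2) and scale ``IMPULSE_SIGMA_S``
    (20 ms, i.e. ~80 ms of support).
    """
    rng = np.random.default_rng(seed)
    fs = config.sensor_rate_hz
    n = int(round(config.session_duration_s * fs))
    t = np.arange(n) / fs
    ax = rng.normal(0.0, profile.accel_noise_sd, n)
    ay = rng.normal(0.0, profile.accel_noise_sd, n)
    az = 9.81 + rng.normal(0.0, profile.accel_noise_sd, n)
    if profile.force_scale > 0:
        for trace in traces:
            t0 = trace.onset.t
            lo = np.searchsorted(t, t0 - 6 * IMPULSE_SIGMA_S)
            hi = np.searchsorted(t, t0 + 6 * IMPULSE_SIGMA_S)
            az[lo:hi] += profile.force_scale * np.exp(
                -0.5 * ((t[lo:hi] - t0) / IMPULSE_SIGMA_S) ** 2
            )
    return [AccelSample(t=float(ti), ax=float(a), ay=float(b), az=float(c))
            for ti, a, b, c in zip(t, ax, ay, az)]


# ---------------------------------------------------------------------------
# Closed-loop session simulation


def simulate_session(
    profile: AgentProfile,
    age_months: float,
    config: GameConfig | None = None,
    seed: int = 0,
    session_id: str = "session",
    group: str = "NT",
    iq: Optional[float] = None,
    clinical_scores: Optional[dict[str, float]] = None,
) -> SessionRecord:
    """Simulate one full session with the pop→respawn loop closed.

    The agent's pops end bubble tracks and trigger same-character respawns in
    the same lane one sensor frame later, so the emitted record satisfies both
    the pop-distance rule and respawn conservation.
    """
    config = config or GameConfig()
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17])
    agent_seed, accel_seed, char_seed = [int(s) for s in
                                         ss.generate_state(3) % (2 ** 31)]
    rng = np.random.default_rng(agent_seed)
    char_rng = np.random.default_rng(char_seed)
    T = config.session_duration_s
    frame = 1.0 / config.sensor_rate_hz

    tracks: list[BubbleTrack] = []
    # per-lane state of the currently rising bubble
    active: list[BubbleTrack] = []
    counters = [0] * config.n_lanes

    def spawn(lane: int, char: int, t0: float) -> BubbleTrack:
        bid = f"L{lane}B{counters[lane]}"
        counters[lane] += 1
        b = BubbleTrack(
            bubble_id=bid, lane=lane, character_id=char, spawn_t=t0,
            center_x_mm=lane_center_x(config, lane),
            y0_mm=config.screen_height_mm,
            speed_mm_s=config.bubble_speed_mm_s,
            end_t=min(t0 + _travel_time(config), T), end_reason="exited",
        )
        tracks.append(b)
        return b

    for lane in range(config.n_lanes):
        active.append(spawn(lane, int(char_rng.integers(N_CHARACTERS)),
                            lane * LANE_STAGGER_S))

    def refresh(now: float) -> None:
        """Replace exited bubbles (random character) up to time ``now``."""
        for lane in range(config.n_lanes):
            b = active[lane]
            while b is not None and b.end_reason == "exited" and b.end_t < now:
                nxt = b.end_t + config.spawn_gap_s
                if b.end_t >= T - 1e-9 or nxt >= T - 1e-9:
                    active[lane] = None
                    b = None
                else:
                    b = spawn(lane, int(char_rng.integers(N_CHARACTERS)), nxt)
                    active[lane] = b

    traces: list[TouchTrace] = []
    pops: list[PopEvent] = []
    last_pop_lane: Optional[int] = None
    cursor = (config.screen_width_mm / 2.0, config.screen_height_mm / 2.0)
    t = float(rng.uniform(0.1, max(0.2, profile.inter_touch_mean_s)))
    idx = 0
    attempts_left = 0
    target_lane: Optional[int] = None
    while t < T - 1e-9:
        refresh(t)
        on_screen = [b for b in active if b is not None and b.on_screen(t)]
        if attempts_left <= 0:
            if last_pop_lane is not None and rng.uniform() < profile.repeat_prob:
                target_lane = last_pop_lane
            else:
                b, _ = nearest_on_screen(on_screen, t, cursor)
                target_lane = b.lane if b is not None else None
            attempts_left = int(rng.geometric(1.0 / profile.touches_per_target_mean))
        target = active[target_lane] if target_lane is not None else None
        if target is None or not target.on_screen(t):
            target, _ = nearest_on_screen(on_screen, t, cursor)
        if target is None:  # nothing on screen right now: wait briefly
            t += 0.1
            attempts_left = 0
            continue
        cx, cy = target.center_at(t)
        aim = (cx + rng.normal(0.0, profile.aim_sd_mm),
               cy + rng.normal(0.0, profile.aim_sd_mm))
        trace = _make_trace(rng, f"T{idx}", t, aim, profile, config)
        idx += 1
        traces.append(trace)
        cursor = (trace.offset.x_mm, trace.offset.y_mm)
        attempts_left -= 1
        hit, d = nearest_on_screen(on_screen, t, (trace.onset.x_mm, trace.onset.y_mm))
        if hit is not None and d <= config.pop_radius_mm:
            hit.end_t = t
            hit.end_reason = "popped"
            pops.append(PopEvent(t=t, bubble_id=hit.bubble_id,
                                 touch_id=trace.touch_id,
                                 distance_to_center_mm=d))
            last_pop_lane = hit.lane
            attempts_left = 0
            respawn_t = t + frame + config.spawn_gap_s
            if respawn_t < T - 1e-9:
                active[hit.lane] = spawn(hit.lane, hit.character_id, respawn_t)
            else:
                active[hit.lane] = None
        gap = float(rng.exponential(profile.inter_touch_mean_s))
        if rng.uniform() < profile.double_touch_prob:
            gap = float(rng.uniform(0.03, 0.8 * config.double_touch_window_s))
        t = trace.offset.t + max(gap, 1.5 * frame)

    tracks = [b for b in tracks if b.end_t > b.spawn_t]
    tracks.sort(key=lambda b: (b.spawn_t, b.lane))
    accel = synthesize_accel(traces, profile, config, seed=accel_seed)
    return SessionRecord(
        session_id=session_id,
        group=group,
        age_months=float(age_months),
        iq=iq,
        clinical_scores=dict(clinical_scores or {}),
        config=config,
        touches=traces,
        accel=accel,
        bubbles=tracks,
        pops=pops,
    )


# ---------------------------------------------------------------------------
# Cohorts


def nt_profile() -> AgentProfile:
    """Default neurotypical-like agent."""
    return AgentProfile()


def case_profile(
    aim_scale: float = 1.5,
    duration_scale: float = 1.5,
    path_scale: float = 1.5,
) -> AgentProfile:
    """Default autistic-like agent: less accurate, slower, longer drag paths.

    The multipliers (default +50% on aim error, touch duration and path
    length) set the planted effect sizes used throughout the simulation
    studies; attempts per target and variability scale with them.
    """
    base = nt_profile()
    return replace(
        base,
        aim_sd_mm=base.aim_sd_mm * aim_scale,
        touch_duration_mean_s=base.touch_duration_mean_s * duration_scale,
        touch_duration_sd_s=base.touch_duration_sd_s * duration_scale,
        path_length_scale_mm=base.path_length_scale_mm * path_scale,
        touches_per_target_mean=2.0,
        repeat_prob=0.55,
    )


def default_age_model() -> AgeModel:
    return AgeModel()


def default_cohort_spec(
    n_control: int = 60,
    n_case: int = 60,
    seed: int = 0,
    null: bool = False,
    with_scores: bool = True,
) -> CohortSpec:
    """Two-group toddler cohort (NT-like vs autistic-like agents).

    With ``null=True`` both groups share the NT profile — an exchangeable
    cohort for type-I-error calibration.
    """
    case = nt_profile() if null else case_profile()
    scores = {"fine_motor_t": (8.0, 6.0), "elc": (6.0, 8.0)} if with_scores else {}
    return CohortSpec(
        groups={"NT": (nt_profile(), n_control), "autistic": (case, n_case)},
        age_model=default_age_model(),
        iq_model={"NT": (100.0, 15.0), "autistic": (90.0, 18.0)},
        clinical_score_model=scores,
        seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[SessionRecord], pd.DataFrame]:
    """Simulate every participant of a cohort; reproducible from ``spec.seed``.

    Returns the session records plus the cohort metadata table
    (``session_id, group, age_months, iq, <clinical scores>``).
    """
    ss = np.random.SeedSequence(int(spec.seed) & 0x7FFFFFFF)
    rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = spec.age_model.age_range_months

    participants = []
    for label, (profile, n) in spec.groups.items():
        for i in range(n):
            participants.append((label, i, profile))

    ages = rng.uniform(lo, hi, len(participants))
    session_seeds = rng.integers(0, 2 ** 31, len(participants))
    adj_profiles = [
        spec.age_model.adjust(profile, age)
        for (_, _, profile), age in zip(participants, ages)
    ]

    aims = np.array([p.aim_sd_mm for p in adj_profiles])
    sd = aims.std()
    skill = -(aims - aims.mean()) / (sd if sd > 0 else 1.0)

    records: list[SessionRecord] = []
    rows = []
    for j, ((label, i, _), prof) in enumerate(zip(participants, adj_profiles)):
        iq = None
        if spec.iq_model and label in spec.iq_model:
            mu, sigma = spec.iq_model[label]
            iq = float(rng.normal(mu, sigma))
        scores = {
            name: float(loading * skill[j] + rng.normal(0.0, noise_sd))
            for name, (loading, noise_sd) in spec.clinical_score_model.items()
        }
        sid = f"{label}_{i:03d}"
        rec = simulate_session(
            prof, ages[j], spec.config, seed=int(session_seeds[j]),
            session_id=sid, group=label, iq=iq, clinical_scores=scores,
        )
        records.append(rec)
        rows.append({"session_id": sid, "group": label,
                     "age_months": float(ages[j]), "iq": iq, **scores})
    meta = pd.DataFrame(rows)
    return records, meta
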