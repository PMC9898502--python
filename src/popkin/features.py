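"""Touch- and inertial-derived motor features of one game session.

Nineteen feature families summarise a session: engagement counts (touches,
pops, popping rate), repetitive-versus-exploratory play (repeat percentage,
lane transitions, screen exploration), per-touch kinematics (duration, path
length, velocity), an inertial force proxy (integral of squared high-passed
device acceleration over each touch), and target-level measures built from
*target episodes* — maximal runs of consecutive touches associated with the
same bubble, ending at the bubble's pop or exit (touches per target, touch
frequency, time on target, popping accuracy and its variability).

Rates and percentages are stored as proportions in [0, 1]; accuracies in
[0, 100].  Standard-deviation summaries are sample SDs (n-1) and are NaN when
fewer than two observations exist, as are means/medians of empty sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session import BubbleTrack, GameConfig, PopEvent, SessionRecord, TouchTrace

__all__ = [
    "TouchKinematics",
    "TargetEpisode",
    "AccuracyProfile",
    "FEATURE_COLUMNS",
    "touch_kinematics",
    "detect_double_touches",
    "detect_pops",
    "associate_targets",
    "popping_accuracy",
    "applied_force",
    "exploration_percentage",
    "extract_features",
    "features_table",
]

FEATURE_COLUMNS: list[str] = [
    "number_of_touches",
    "number_of_pops",
    "bubble_popping_rate",
    "double_touch_rate",
    "screen_exploratory_percentage",
    "number_of_targeted_bubbles",
    "number_of_transitions",
    "repeat_percentage",
    "touch_duration_mean", "touch_duration_median", "touch_duration_std",
    "touch_length_mean", "touch_length_median", "touch_length_std",
    "touch_velocity_mean", "touch_velocity_median", "touch_velocity_std",
    "applied_force_mean", "applied_force_median", "applied_force_std",
    "distance_to_center_mean", "distance_to_center_median", "distance_to_center_std",
    "popping_accuracy_mean", "popping_accuracy_median", "popping_accuracy_std",
    "accuracy_variation_mean",
    "accuracy_mean_variability",
    "accuracy_max_variability",
    "touches_per_target_mean", "touches_per_target_std",
    "touch_frequency_mean", "touch_frequency_median", "touch_frequency_std",
    "time_on_target_mean", "time_on_target_median", "time_on_target_std",
]


@dataclass(frozen=True)
class TouchKinematics:
    touch_id: str
    duration_s: float
    length_mm: float
    velocity_mm_s: float  # NaN for zero-duration traces
    onset_xy: tuple[float, float]
    is_double: bool = False


@dataclass
class TargetEpisode:
    bubble_id: str
    touch_ids: list[str]
    start_t: float
    end_t: float

    @property
    def n_touches(self) -> int:
        return len(self.touch_ids)

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


@dataclass
class AccuracyProfile:
    touch_id: str
    per_sample_accuracy: list[float]
    mean_pct: float
    max_pct: float
    std_pct: float  # NaN for single-sample traces


def _mean(xs: Sequence[float]) -> float:
    return float(np.mean(xs)) if len(xs) else math.nan


def _median(xs: Sequence[float]) -> float:
    return float(np.median(xs)) if len(xs) else math.nan


def _std(xs: Sequence[float]) -> float:
    return float(np.std(xs, ddof=1)) if len(xs) >= 2 else math.nan


def touch_kinematics(trace: TouchTrace) -> TouchKinematics:
    """Duration, path length and velocity of one touch trace."""
    if not trace.samples:
        raise ValueError("empty trace")
    s = trace.samples
    duration = s[-1].t - s[0].t
    length = sum(
        math.hypot(b.x_mm - a.x_mm, b.y_mm - a.y_mm) for a, b in zip(s, s[1:])
    )
    velocity = length / duration if duration > 0 else math.nan
    return TouchKinematics(
        touch_id=trace.touch_id,
        duration_s=duration,
        length_mm=length,
        velocity_mm_s=velocity,
        onset_xy=(s[0].x_mm, s[0].y_mm),
    )


def detect_double_touches(
    traces: Sequence[TouchTrace], config: GameConfig
) -> list[bool]:
    """Flag touches that follow the previous one quickly and nearby.

    Touch i+1 is a double touch iff its onset comes within
    ``double_touch_window_s`` of touch i's offset and its onset lies within
    ``double_touch_radius_mm`` of touch i's onset.
    """
    flags = [False] * len(traces)
    for i in range(1, len(traces)):
        prev, cur = traces[i - 1], traces[i]
        dt = cur.onset.t - prev.offset.t
        dd = math.hypot(cur.onset.x_mm - prev.onset.x_mm,
                        cur.onset.y_mm - prev.onset.y_mm)
        flags[i] = (dt <= config.double_touch_window_s
                    and dd <= config.double_touch_radius_mm)
    return flags


def _nearest_available(
    bubbles: Sequence[BubbleTrack],
    t: float,
    xy: tuple[float, float],
    unavailable: set[str],
) -> tuple[Optional[BubbleTrack], float]:
    best = None
    best_key = None
    for b in bubbles:
        if b.bubble_id in unavailable or not b.on_screen(t):
            continue
        cx, cy = b.center_at(t)
        d = math.hypot(xy[0] - cx, xy[1] - cy)
        key = (d, b.spawn_t, b.bubble_id)
        if best_key is None or key < best_key:
            best, best_key = b, key
    return best, (best_key[0] if best_key is not None else math.inf)


def detect_pops(
    traces: Sequence[TouchTrace],
    bubbles: Sequence[BubbleTrack],
    config: GameConfig,
) -> list[PopEvent]:
    """Recompute pop events from touches and bubble trajectories.

    For each touch onset (in time order) the nearest on-screen bubble not yet
    popped in this recomputation pops iff the onset lies within
    ``pop_radius_mm`` (inclusive) of its center.  On simulator output this
    reproduces the logged pops exactly.
    """
    ordered = sorted(traces, key=lambda tr: tr.onset.t)
    popped: set[str] = set()
    pops: list[PopEvent] = []
    for tr in ordered:
        onset = tr.onset
        hit, d = _nearest_available(bubbles, onset.t, (onset.x_mm, onset.y_mm), popped)
        if hit is not None and d <= config.pop_radius_mm:
            pops.append(PopEvent(t=onset.t, bubble_id=hit.bubble_id,
                                 touch_id=tr.touch_id, distance_to_center_mm=d))
            popped.add(hit.bubble_id)
    return pops


def associate_targets(
    traces: Sequence[TouchTrace],
    bubbles: Sequence[BubbleTrack],
    config: GameConfig,
) -> list[TargetEpisode]:
    """Group touches into target episodes.

    Each touch is assigned to the nearest bubble within
    ``targeting_radius_mm`` of its onset (unassigned otherwise); consecutive
    *assigned* touches sharing a bubble merge into one episode, which ends at
    the bubble's pop/exit or the last touch's offset, whichever comes first.
    """
    by_id = {b.bubble_id: b for b in bubbles}
    ordered = sorted(traces, key=lambda tr: tr.onset.t)
    assigned: list[tuple[TouchTrace, str]] = []
    for tr in ordered:
        onset = tr.onset
        hit, d = _nearest_available(bubbles, onset.t, (onset.x_mm, onset.y_mm), set())
        if hit is not None and d <= config.targeting_radius_mm:
            assigned.append((tr, hit.bubble_id))
    episodes: list[TargetEpisode] = []
    for tr, bid in assigned:
        if episodes and episodes[-1].bubble_id == bid and (
            not _episode_closed(episodes[-1], by_id[bid], tr.onset.t)
        ):
            ep = episodes[-1]
            ep.touch_ids.append(tr.touch_id)
            ep.end_t = min(by_id[bid].end_t, tr.offset.t)
        else:
            episodes.append(TargetEpisode(
                bubble_id=bid, touch_ids=[tr.touch_id],
                start_t=tr.onset.t, end_t=min(by_id[bid].end_t, tr.offset.t),
            ))
    return episodes


def _episode_closed(ep: TargetEpisode, bubble: BubbleTrack, t: float) -> bool:
    # the episode's bubble already popped/exited before this touch
    return bubble.end_t < t


def popping_accuracy(
    trace: TouchTrace, bubble: BubbleTrack, config: GameConfig
) -> AccuracyProfile:
    """Per-sample spatial accuracy of a touch against its episode's bubble.

    100% inside the bubble disc; beyond the edge the accuracy decays linearly
    over ``accuracy_decay_mm`` and floors at 0.  The bubble is evaluated at
    each sample's timestamp (a moving target), with its position frozen at
    the track's endpoints outside its lifetime.
    """
    acc = []
    for s in trace.samples:
        t = min(max(s.t, bubble.spawn_t), bubble.end_t)
        cx, cy = bubble.center_at(t)
        d_edge = max(0.0, math.hypot(s.x_mm - cx, s.y_mm - cy) - config.bubble_radius_mm)
        acc.append(100.0 * max(0.0, 1.0 - d_edge / config.accuracy_decay_mm))
    return AccuracyProfile(
        touch_id=trace.touch_id,
        per_sample_accuracy=acc,
        mean_pct=_mean(acc),
        max_pct=float(max(acc)),
        std_pct=_std(acc),
    )


def _highpass_magnitude(accel, config: GameConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis centred running-median (1 s window, shrinking at the edges)
    removal, then magnitude."""
    arr = np.asarray(accel, dtype=float)  # AccelSample rows: t, ax, ay, az
    t, A = arr[:, 0], arr[:, 1:4]
    win = int(round(config.sensor_rate_hz)) | 1  # odd window ~= 1 s
    med = (
        pd.DataFrame(A).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    hp = A - med
    return t, np.sqrt((hp ** 2).sum(axis=1))


def applied_force(
    trace: TouchTrace,
    accel: Sequence,
    config: GameConfig,
    _precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Force proxy: integral of squared high-passed acceleration magnitude
    over the touch's duration (trapezoid on the piecewise-linear signal).

    Gravity (and any slow device tilt) is removed per axis by subtracting a
    centred 1 s running median before squaring.  Zero for zero-duration
    touches.  Raises if the inertial stream does not cover the touch window
    (more than two sensor frames of overhang).
    """
    if trace.onset.t == trace.offset.t:
        return 0.0
    t, mag = _precomputed if _precomputed is not None else _highpass_magnitude(accel, config)
    if len(t) == 0:
        raise ValueError("no inertial samples")
    slack = 2.0 / config.sensor_rate_hz
    t0, t1 = trace.onset.t, trace.offset.t
    if t0 < t[0] - slack or t1 > t[-1] + slack:
        raise ValueError(
            f"inertial stream [{t[0]}, {t[-1]}] does not cover touch [{t0}, {t1}]"
        )
    t0 = min(max(t0, t[0]), t[-1])
    t1 = min(max(t1, t[0]), t[-1])
    if t1 <= t0:
        return 0.0
    m2 = mag ** 2
    inside = (t > t0) & (t < t1)
    ts = np.concatenate(([t0], t[inside], [t1]))
    vs = np.concatenate(([np.interp(t0, t, m2)], m2[inside], [np.interp(t1, t, m2)]))
    return float(np.trapezoid(vs, ts))


def exploration_percentage(
    traces: Sequence[TouchTrace], config: GameConfig
) -> float:
    """Fraction of screen grid cells containing at least one touch sample."""
    cell = config.exploration_cell_mm
    ncols = math.ceil(config.screen_width_mm / cell)
    nrows = math.ceil(config.screen_height_mm / cell)
    seen: set[tuple[int, int]] = set()
    for tr in traces:
        for s in tr.samples:
            i = min(int(s.x_mm // cell), ncols - 1)
            j = min(int(s.y_mm // cell), nrows - 1)
            seen.add((i, j))
    return len(seen) / (ncols * nrows)


def extract_features(record: SessionRecord) -> dict[str, float]:
    """Compute the full feature vector of one session.

    Counts are exact integers (stored as floats); rates are proportions;
    undefined quantities (e.g. SDs with <2 observations, ratios with empty
    denominators) are NaN.
    """
    cfg = record.config
    traces = sorted(record.touches, key=lambda tr: tr.onset.t)
    pops = sorted(record.pops, key=lambda p: p.t)
    by_bubble = {b.bubble_id: b for b in record.bubbles}
    by_touch = {tr.touch_id: tr for tr in traces}

    n_touches = len(traces)
    n_pops = len(pops)
    f: dict[str, float] = {c: math.nan for c in FEATURE_COLUMNS}
    f["number_of_touches"] = float(n_touches)
    f["number_of_pops"] = float(n_pops)
    f["bubble_popping_rate"] = n_pops / n_touches if n_touches else math.nan

    flags = detect_double_touches(traces, cfg)
    f["double_touch_rate"] = (sum(flags) / n_touches) if n_touches else math.nan
    f["screen_exploratory_percentage"] = exploration_percentage(traces, cfg)

    # consecutive-pop structure: lane transitions and same-bubble repeats
    if n_pops >= 2:
        pairs = list(zip(pops, pops[1:]))
        lanes = {p.bubble_id: by_bubble[p.bubble_id].lane for p in pops}
        chars = {p.bubble_id: by_bubble[p.bubble_id].character_id for p in pops}
        f["number_of_transitions"] = float(sum(
            lanes[a.bubble_id] != lanes[b.bubble_id] for a, b in pairs
        ))
        f["repeat_percentage"] = sum(
            lanes[a.bubble_id] == lanes[b.bubble_id]
            and chars[a.bubble_id] == chars[b.bubble_id]
            for a, b in pairs
        ) / (n_pops - 1)
    elif n_pops in (0, 1):
        f["number_of_transitions"] = 0.0
        # repeat_percentage stays NaN (<2 pops)

    kin = [touch_kinematics(tr) for tr in traces]
    durations = [k.duration_s for k in kin]
    lengths = [k.length_mm for k in kin]
    velocities = [k.velocity_mm_s for k in kin if not math.isnan(k.velocity_mm_s)]
    f["touch_duration_mean"] = _mean(durations)
    f["touch_duration_median"] = _median(durations)
    f["touch_duration_std"] = _std(durations)
    f["touch_length_mean"] = _mean(lengths)
    f["touch_length_median"] = _median(lengths)
    f["touch_length_std"] = _std(lengths)
    f["touch_velocity_mean"] = _mean(velocities)
    f["touch_velocity_median"] = _median(velocities)
    f["touch_velocity_std"] = _std(velocities)

    if record.accel and traces:
        pre = _highpass_magnitude(record.accel, cfg)
        forces = [applied_force(tr, record.accel, cfg, _precomputed=pre)
                  for tr in traces]
        f["applied_force_mean"] = _mean(forces)
        f["applied_force_median"] = _median(forces)
        f["applied_force_std"] = _std(forces)

    dists = [p.distance_to_center_mm for p in pops]
    f["distance_to_center_mean"] = _mean(dists)
    f["distance_to_center_median"] = _median(dists)
    f["distance_to_center_std"] = _std(dists)

    episodes = associate_targets(traces, record.bubbles, cfg)
    f["number_of_targeted_bubbles"] = float(len(episodes))
    per_target = [float(ep.n_touches) for ep in episodes]
    f["touches_per_target_mean"] = _mean(per_target)
    f["touches_per_target_std"] = _std(per_target)
    times = [ep.duration_s for ep in episodes]
    f["time_on_target_mean"] = _mean(times)
    f["time_on_target_median"] = _median(times)
    f["time_on_target_std"] = _std(times)
    freqs = [ep.n_touches / ep.duration_s for ep in episodes if ep.duration_s > 0]
    f["touch_frequency_mean"] = _mean(freqs)
    f["touch_frequency_median"] = _median(freqs)
    f["touch_frequency_std"] = _std(freqs)

    # popping accuracy over targeted touches (those belonging to an episode)
    profiles: list[AccuracyProfile] = []
    for ep in episodes:
        bubble = by_bubble[ep.bubble_id]
        for tid in ep.touch_ids:
            profiles.append(popping_accuracy(by_touch[tid], bubble, cfg))
    touch_means = [p.mean_pct for p in profiles]
    touch_maxes = [p.max_pct for p in profiles]
    touch_stds = [p.std_pct for p in profiles if not math.isnan(p.std_pct)]
    f["popping_accuracy_mean"] = _mean(touch_means)
    f["popping_accuracy_median"] = _median(touch_means)
    f["popping_accuracy_std"] = _std(touch_means)
    f["accuracy_variation_mean"] = _mean(touch_stds)
    f["accuracy_mean_variability"] = _std(touch_means)
    f["accuracy_max_variability"] = _std(touch_maxes)
    return f


def features_table(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    """One row per session: metadata columns followed by the canonical
    feature columns; NaN encodes missing values."""
    ids = [r.session_id for r in sessions]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate session_id(s): {dup}")
    rows = []
    score_names: list[str] = []
    for r in sessions:
        for name in r.clinical_scores:
            if name not in score_names:
                score_names.append(name)
    for r in sessions:
        row: dict[str, object] = {
            "session_id": r.session_id,
            "group": r.group,
            "age_months": r.age_months,
            "iq": r.iq if r.iq is not None else math.nan,
        }
        for name in score_names:
            row[name] = r.clinical_scores.get(name, math.nan)
        row.update(extract_features(r))
        rows.append(row)
    cols = ["session_id", "group", "age_months", "iq", *score_names, *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=cols)
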