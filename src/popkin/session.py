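"""Session-log data model, JSON persistence, validation and engagement QC.

A *session* is one child's 20-second run of the bubble-popping game: the
per-touch coordinate traces sampled by the touchscreen, the device's inertial
stream, the bubble trajectories shown on screen, the pop events, and the
participant metadata (diagnostic group, age, optional IQ and clinical scores).

Coordinates are stored in millimetres with the origin at the top-left corner
of the screen, x rightward and y downward; bubbles rising therefore means y
decreasing over time.  Sessions are persisted as one JSON document each
(``schema_version`` 1); a cohort is a directory of such documents plus a CSV
metadata table.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, NamedTuple, Optional

SCHEMA_VERSION = 1

__all__ = [
    "GameConfig",
    "TouchSample",
    "TouchTrace",
    "AccelSample",
    "BubbleTrack",
    "PopEvent",
    "SessionRecord",
    "Violation",
    "validate_session",
    "write_session",
    "read_session",
    "qc_filter",
    "SessionValidationError",
    "SchemaError",
]


class SessionValidationError(ValueError):
    """Raised when an operation requires a valid record but validation fails."""


class SchemaError(ValueError):
    """Raised when a session JSON document does not conform to the schema."""


@dataclass(frozen=True)
class GameConfig:
    """Geometry and timing of the game plus analysis thresholds.

    The defaults encode the published protocol: a 20 s analysis window, 60 Hz
    sensors, 5 vertical lanes, and a pop registered when a touch *onset* lands
    within 18.5 mm of a bubble's center.  ``targeting_radius_mm`` (the "close
    enough" radius defining a targeted bubble) defaults to 1.5x the pop
    radius; ``accuracy_decay_mm`` is the distance beyond the bubble edge over
    which popping accuracy decays linearly from 100% to 0%.
    """

    screen_width_mm: float = 160.0
    screen_height_mm: float = 220.0
    n_lanes: int = 5
    pop_radius_mm: float = 18.5
    bubble_radius_mm: float = 18.5
    bubble_speed_mm_s: float = 20.0
    spawn_gap_s: float = 0.0
    session_duration_s: float = 20.0
    sensor_rate_hz: float = 60.0
    targeting_radius_mm: float = 27.75
    accuracy_decay_mm: float = 18.5
    exploration_cell_mm: float = 10.0
    double_touch_window_s: float = 0.3
    double_touch_radius_mm: float = 10.0
    min_touches_qc: int = 3

    def __post_init__(self) -> None:
        positive = (
            "screen_width_mm", "screen_height_mm", "pop_radius_mm",
            "bubble_radius_mm", "bubble_speed_mm_s", "session_duration_s",
            "sensor_rate_hz", "targeting_radius_mm", "accuracy_decay_mm",
            "exploration_cell_mm", "double_touch_window_s",
            "double_touch_radius_mm",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"GameConfig.{name} must be > 0, got {getattr(self, name)}")
        if self.spawn_gap_s < 0:
            raise ValueError("GameConfig.spawn_gap_s must be >= 0")
        if self.n_lanes < 1:
            raise ValueError("GameConfig.n_lanes must be >= 1")
        if self.min_touches_qc < 1:
            raise ValueError("GameConfig.min_touches_qc must be >= 1")
        if self.pop_radius_mm > self.targeting_radius_mm:
            raise ValueError("pop_radius_mm must not exceed targeting_radius_mm")


class TouchSample(NamedTuple):
    # lightweight record: sessions hold thousands of these
    t: float
    x_mm: float
    y_mm: float
    touch_id: str


@dataclass
class TouchTrace:
    """One finger-down..finger-up contact: ordered samples sharing a touch id."""

    touch_id: str
    samples: list[TouchSample]

    @property
    def onset(self) -> TouchSample:
        return self.samples[0]

    @property
    def offset(self) -> TouchSample:
        return self.samples[-1]


class AccelSample(NamedTuple):
    t: float
    ax: float
    ay: float
    az: float


@dataclass
class BubbleTrack:
    """One bubble's on-screen life: linear ascent in a fixed lane.

    The trajectory is ``y(t) = y0_mm - speed_mm_s * (t - spawn_t)`` over
    ``[spawn_t, end_t]``; y decreases because the origin is top-left.
    ``end_reason`` is "popped" when a touch ended the track, "exited"
    otherwise (left the top of the screen, or session ended).
    """

    bubble_id: str
    lane: int
    character_id: int
    spawn_t: float
    center_x_mm: float
    y0_mm: float
    speed_mm_s: float
    end_t: float
    end_reason: str  # "popped" | "exited"

    def y_at(self, t: float) -> float:
        return self.y0_mm - self.speed_mm_s * (t - self.spawn_t)

    def center_at(self, t: float) -> tuple[float, float]:
        return self.center_x_mm, self.y_at(t)

    def on_screen(self, t: float) -> bool:
        return self.spawn_t <= t <= self.end_t


@dataclass(frozen=True)
class PopEvent:
    t: float
    bubble_id: str
    touch_id: str
    distance_to_center_mm: float


@dataclass
class SessionRecord:
    """One participant's game session — the unit of analysis."""

    session_id: str
    group: str
    age_months: float
    config: GameConfig
    touches: list[TouchTrace] = field(default_factory=list)
    accel: list[AccelSample] = field(default_factory=list)
    bubbles: list[BubbleTrack] = field(default_factory=list)
    pops: list[PopEvent] = field(default_factory=list)
    iq: Optional[float] = None
    clinical_scores: dict[str, float] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_touches(self) -> int:
        return len(self.touches)


@dataclass(frozen=True)
class Violation:
    """One invariant failure: the offending field, the rule, and what was seen."""

    field: str
    rule: str
    observed: Any

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule} (observed {self.observed!r})"


_DIST_TOL = 1e-6  # slack for recomputing pop distances from float trajectories


def validate_session(record: SessionRecord) -> list[Violation]:
    """Check every structural invariant of a session; return all failures.

    Total function: never raises for a structurally complete record.  An empty
    list means the record is valid.
    """
    v: list[Violation] = []
    cfg = record.config
    T = cfg.session_duration_s

    touch_ids = set()
    for i, trace in enumerate(record.touches):
        path = f"touches[{i}]"
        if not trace.samples:
            v.append(Violation(path, "trace must have >= 1 sample", 0))
            continue
        if trace.touch_id in touch_ids:
            v.append(Violation(path, "duplicate touch_id", trace.touch_id))
        touch_ids.add(trace.touch_id)
        prev_t = -math.inf
        for j, s in enumerate(trace.samples):
            sp = f"{path}.samples[{j}]"
            if s.touch_id != trace.touch_id:
                v.append(Violation(sp, "sample touch_id differs from trace", s.touch_id))
            if not (0.0 <= s.t <= T):
                v.append(Violation(sp + ".t", f"time must be in [0, {T}]", s.t))
            if not (0.0 <= s.x_mm <= cfg.screen_width_mm):
                v.append(Violation(sp + ".x_mm", f"x must be in [0, {cfg.screen_width_mm}]", s.x_mm))
            if not (0.0 <= s.y_mm <= cfg.screen_height_mm):
                v.append(Violation(sp + ".y_mm", f"y must be in [0, {cfg.screen_height_mm}]", s.y_mm))
            if not s.t > prev_t:
                v.append(Violation(sp + ".t", "sample times must be strictly increasing", s.t))
            prev_t = s.t

    prev_t = -math.inf
    for i, a in enumerate(record.accel):
        if a.t < prev_t:
            v.append(Violation(f"accel[{i}].t", "accel times must be non-decreasing", a.t))
        prev_t = a.t
        if not (0.0 <= a.t <= T):
            v.append(Violation(f"accel[{i}].t", f"time must be in [0, {T}]", a.t))

    bubble_ids: dict[str, BubbleTrack] = {}
    lane_x: dict[int, float] = {}
    for i, b in enumerate(record.bubbles):
        path = f"bubbles[{i}]"
        if b.bubble_id in bubble_ids:
            v.append(Violation(path, "duplicate bubble_id", b.bubble_id))
        bubble_ids[b.bubble_id] = b
        if not (0 <= b.lane < cfg.n_lanes):
            v.append(Violation(path + ".lane", f"lane must be in [0, {cfg.n_lanes})", b.lane))
        if not b.spawn_t < b.end_t:
            v.append(Violation(path, "spawn_t must precede end_t", (b.spawn_t, b.end_t)))
        if not b.speed_mm_s > 0:
            v.append(Violation(path + ".speed_mm_s", "y must strictly decrease (speed > 0)", b.speed_mm_s))
        if b.end_reason not in ("popped", "exited"):
            v.append(Violation(path + ".end_reason", "must be 'popped' or 'exited'", b.end_reason))
        if not (0.0 <= b.spawn_t <= T and b.end_t <= T):
            v.append(Violation(path, f"track must lie within [0, {T}]", (b.spawn_t, b.end_t)))
        if b.lane in lane_x:
            if abs(lane_x[b.lane] - b.center_x_mm) > _DIST_TOL:
                v.append(Violation(path + ".center_x_mm", "lane x must be constant per lane", b.center_x_mm))
        else:
            lane_x[b.lane] = b.center_x_mm

    traces_by_id = {t.touch_id: t for t in record.touches if t.samples}
    for i, p in enumerate(record.pops):
        path = f"pops[{i}]"
        if not (0.0 <= p.t <= T):
            v.append(Violation(path + ".t", f"time must be in [0, {T}]", p.t))
        if p.distance_to_center_mm > cfg.pop_radius_mm + _DIST_TOL:
            v.append(Violation(
                path + ".distance_to_center_mm",
                f"pop requires onset within {cfg.pop_radius_mm} mm of bubble center",
                p.distance_to_center_mm,
            ))
        b = bubble_ids.get(p.bubble_id)
        if b is None:
            v.append(Violation(path + ".bubble_id", "references unknown bubble", p.bubble_id))
        tr = traces_by_id.get(p.touch_id)
        if tr is None:
            v.append(Violation(path + ".touch_id", "references unknown touch", p.touch_id))
        if b is not None and tr is not None:
            if not b.on_screen(p.t):
                v.append(Violation(path + ".t", "pop outside bubble's on-screen interval", p.t))
            else:
                cx, cy = b.center_at(p.t)
                d = math.hypot(tr.onset.x_mm - cx, tr.onset.y_mm - cy)
                if abs(d - p.distance_to_center_mm) > 1e-6 + 1e-9 * abs(d):
                    v.append(Violation(
                        path + ".distance_to_center_mm",
                        "logged distance inconsistent with touch onset and bubble position",
                        p.distance_to_center_mm,
                    ))
    return v


# ---------------------------------------------------------------------------
# JSON persistence


def _config_to_json(cfg: GameConfig) -> dict:
    return dataclasses.asdict(cfg)


def _record_to_json(record: SessionRecord) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "session_id": record.session_id,
        "group": record.group,
        "age_months": record.age_months,
        "iq": record.iq,
        "clinical_scores": dict(record.clinical_scores),
        "config": _config_to_json(record.config),
        "touches": [
            {
                "touch_id": tr.touch_id,
                "samples": [[s.t, s.x_mm, s.y_mm] for s in tr.samples],
            }
            for tr in record.touches
        ],
        "accel": [[a.t, a.ax, a.ay, a.az] for a in record.accel],
        "bubbles": [
            {
                "bubble_id": b.bubble_id,
                "lane": b.lane,
                "character_id": b.character_id,
                "spawn_t": b.spawn_t,
                "center_x_mm": b.center_x_mm,
                "y0_mm": b.y0_mm,
                "speed_mm_s": b.speed_mm_s,
                "end_t": b.end_t,
                "end_reason": b.end_reason,
            }
            for b in record.bubbles
        ],
        "pops": [
            {
                "t": p.t,
                "bubble_id": p.bubble_id,
                "touch_id": p.touch_id,
                "distance_to_center_mm": p.distance_to_center_mm,
            }
            for p in record.pops
        ],
        "meta": dict(record.meta),
    }


def write_session(record: SessionRecord, destination: str | os.PathLike) -> str:
    """Serialize a validated session to one JSON document.

    Floats are serialized with ``repr`` (Python's json default), which
    round-trips IEEE doubles exactly, so ``read_session(write_session(r))``
    reproduces ``r`` bit for bit and re-writing produces byte-identical files.
    """
    violations = validate_session(record)
    if violations:
        raise SessionValidationError(
            "refusing to write invalid session: " + "; ".join(map(str, violations[:5]))
        )
    doc = _record_to_json(record)
    path = os.fspath(destination)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return path


def _require(doc: dict, key: str, path: str) -> Any:
    if key not in doc:
        raise SchemaError(f"missing required field at {path}.{key}")
    return doc[key]


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(GameConfig)}


def read_session(source: str | os.PathLike) -> SessionRecord:
    """Parse and fully validate a session JSON document.

    Unknown top-level keys are preserved in ``record.meta`` (under their own
    names) so producer extensions survive a round trip through this library.
    """
    path = os.fspath(source)
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("session document must be a JSON object at $")

    cfg_doc = _require(doc, "config", "$")
    if not isinstance(cfg_doc, dict):
        raise SchemaError("$.config must be an object")
    missing = _CONFIG_FIELDS - set(cfg_doc)
    if missing:
        raise SchemaError(f"missing required field at $.config.{sorted(missing)[0]}")
    try:
        config = GameConfig(**{k: cfg_doc[k] for k in _CONFIG_FIELDS})
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"invalid $.config: {exc}") from exc

    touches = []
    for i, td in enumerate(_require(doc, "touches", "$")):
        tid = _require(td, "touch_id", f"$.touches[{i}]")
        samples = [
            TouchSample(t=s[0], x_mm=s[1], y_mm=s[2], touch_id=tid)
            for s in _require(td, "samples", f"$.touches[{i}]")
        ]
        touches.append(TouchTrace(touch_id=tid, samples=samples))

    accel = [AccelSample(*row) for row in _require(doc, "accel", "$")]
    bubbles = []
    for i, bd in enumerate(_require(doc, "bubbles", "$")):
        p = f"$.bubbles[{i}]"
        bubbles.append(BubbleTrack(
            bubble_id=_require(bd, "bubble_id", p),
            lane=_require(bd, "lane", p),
            character_id=_require(bd, "character_id", p),
            spawn_t=_require(bd, "spawn_t", p),
            center_x_mm=_require(bd, "center_x_mm", p),
            y0_mm=_require(bd, "y0_mm", p),
            speed_mm_s=_require(bd, "speed_mm_s", p),
            end_t=_require(bd, "end_t", p),
            end_reason=_require(bd, "end_reason", p),
        ))
    pops = []
    for i, pd in enumerate(_require(doc, "pops", "$")):
        p = f"$.pops[{i}]"
        pops.append(PopEvent(
            t=_require(pd, "t", p),
            bubble_id=_require(pd, "bubble_id", p),
            touch_id=_require(pd, "touch_id", p),
            distance_to_center_mm=_require(pd, "distance_to_center_mm", p),
        ))

    known = {"schema_version", "session_id", "group", "age_months", "iq",
             "clinical_scores", "config", "touches", "accel", "bubbles",
             "pops", "meta"}
    meta = dict(doc.get("meta") or {})
    for key in doc:
        if key not in known:
            meta[key] = doc[key]

    record = SessionRecord(
        session_id=_require(doc, "session_id", "$"),
        group=_require(doc, "group", "$"),
        age_months=_require(doc, "age_months", "$"),
        iq=doc.get("iq"),
        clinical_scores=dict(doc.get("clinical_scores") or {}),
        config=config,
        touches=touches,
        accel=accel,
        bubbles=bubbles,
        pops=pops,
        meta=meta,
    )
    violations = validate_session(record)
    if violations:
        raise SessionValidationError(
            f"invalid session in {path}: " + "; ".join(map(str, violations[:5]))
        )
    return record


def qc_filter(
    sessions: Iterable[SessionRecord], min_touches: int | None = None
) -> tuple[list[SessionRecord], list[tuple[SessionRecord, str]]]:
    """Engagement filter: keep sessions with at least ``min_touches`` touches.

    The threshold is strict-less exclusion ("fewer than three" excluded):
    a session with exactly ``min_touches`` touches is kept.  ``min_touches``
    defaults to each session's own ``config.min_touches_qc`` (3).
    """
    kept: list[SessionRecord] = []
    excluded: list[tuple[SessionRecord, str]] = []
    for rec in sessions:
        threshold = min_touches if min_touches is not None else rec.config.min_touches_qc
        if threshold < 1:
            raise ValueError("min_touches must be >= 1")
        if rec.n_touches >= threshold:
            kept.append(rec)
        else:
            excluded.append((rec, "insufficient_engagement"))
    return kept, excluded
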