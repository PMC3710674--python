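"""Cage geometry, light schedule, and session-plan configuration.

The conventions used throughout the package:

* Corners are labelled with integers 1-4; corner 1 is top-left, numbering
  runs clockwise.  Floor coordinates are centimetres with the origin at
  the top-left corner of the cage.
* Time is seconds from session start (float).  The wall-clock time at
  which the session started is carried alongside so events can be binned
  into light/dark phases.
* Two adjacent corners form the *active pair* (contingently rewarded
  during the alternation task); the other two are *exploratory* corners
  that are never rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import yaml

HABITUATION = "habituation"
ALTERNATION = "alternation"
REVERSAL = "reversal"
PHASES = (HABITUATION, ALTERNATION, REVERSAL)

LIGHT = "light"
DARK = "dark"

LEFT = "left"
RIGHT = "right"
SIDES = (LEFT, RIGHT)

#: Axis-aligned rectangle in cage-floor cm: (x0, y0, x1, y1).
Rect = Tuple[float, float, float, float]


def _other_side(side: str) -> str:
    return RIGHT if side == LEFT else LEFT


@dataclass(frozen=True)
class LightSchedule:
    """12:12 light/dark cycle anchored to a lights-on clock time.

    ``lights_on_clock_h`` is hours after midnight (e.g. 7.0 for 07:00).
    ``light_hours + dark_hours`` must equal 24.
    """

    lights_on_clock_h: float = 7.0
    light_hours: float = 12.0
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ValueError("light_hours + dark_hours must equal 24")
        if not 0.0 <= self.lights_on_clock_h < 24.0:
            raise ValueError("lights_on_clock_h must be in [0, 24)")


@dataclass(frozen=True)
class CageConfig:
    """Static description of one instrumented home cage.

    The default geometry follows the standard four-corner automated cage:
    a 55 x 37.5 cm floor with a water chamber in each corner.  Each active
    corner rewards exactly one nosepoke side and the two sides are
    opposite between the two active corners.
    """

    cage_id: str = "cage01"
    corner_ids: Tuple[int, int, int, int] = (1, 2, 3, 4)
    active_pair: Tuple[int, int] = (1, 2)
    exploratory_pair: Tuple[int, int] = (3, 4)
    rewarded_side_map: Mapping[int, str] = field(
        default_factory=lambda: {1: LEFT, 2: RIGHT}
    )
    cage_width_cm: float = 55.0
    cage_height_cm: float = 37.5
    climb_zones: Tuple[Rect, ...] = (
        (10.0, 0.0, 18.0, 6.0),    # climbing rod, long wall
        (37.0, 0.0, 45.0, 6.0),    # second rod
        (24.0, 15.0, 31.0, 22.5),  # central structure
    )
    wall_margin_cm: float = 3.0
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        corners = tuple(self.corner_ids)
        if len(set(corners)) != 4:
            raise ValueError("corner_ids must be 4 distinct labels")
        if set(self.active_pair) | set(self.exploratory_pair) != set(corners):
            raise ValueError("active_pair and exploratory_pair must partition the corners")
        if set(self.active_pair) & set(self.exploratory_pair):
            raise ValueError("active_pair and exploratory_pair overlap")
        sides = [self.rewarded_side_map.get(c) for c in self.active_pair]
        if sorted(sides) != [LEFT, RIGHT]:
            raise ValueError(
                "the rewarded sides of the two active corners must be opposite"
            )
        for name in ("cage_width_cm", "cage_height_cm", "wall_margin_cm",
                     "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def other_active(self, corner: int) -> int:
        a, b = self.active_pair
        if corner == a:
            return b
        if corner == b:
            return a
        raise ValueError(f"corner {corner} is not an active corner")

    def swapped_side_map(self) -> Mapping[int, str]:
        return {c: _other_side(s) for c, s in self.rewarded_side_map.items()}


@dataclass(frozen=True)
class PlanSegment:
    """One contiguous block of a session timeline.

    ``side_swap`` toggles the rewarded-side map relative to the previous
    segment (the weekly "task reversed at the start of each session"
    manipulation).  ``active_pair`` optionally overrides which corner
    pair is active for this segment (a corner-contingency reversal).
    """

    phase: str
    duration_h: float
    side_swap: bool = False
    active_pair: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered protocol timeline plus the non-licker watchdog settings.

    Animals that produce no licks over a trailing ``demote_window_h``
    window while on the alternation/reversal task are electronically
    switched back to habituation (free water on corner entry); the check
    runs every ``demote_cadence_h`` hours of session time.
    """

    segments: Tuple[PlanSegment, ...]
    demote_window_h: float = 24.0
    demote_cadence_h: float = 24.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("session plan needs at least one segment")
        if self.demote_window_h <= 0 or self.demote_cadence_h <= 0:
            raise ValueError("demotion window/cadence must be > 0")

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_h for s in self.segments) * 3600.0

    def boundaries_s(self) -> Tuple[float, ...]:
        """Start time (s) of each segment."""
        out, t = [], 0.0
        for seg in self.segments:
            out.append(t)
            t += seg.duration_h * 3600.0
        return tuple(out)

    def segment_at(self, t: float) -> PlanSegment:
        if t < 0:
            raise ValueError("t must be >= 0")
        acc = 0.0
        for seg in self.segments:
            acc += seg.duration_h * 3600.0
            if t < acc:
                return seg
        raise ValueError(f"t={t} s is beyond the plan ({acc} s)")


# -- canonical timelines -------------------------------------------------

def rapid_onset_first_week_plan() -> SessionPlan:
    """First weekly test of the rapid-phenotype design: 6 h habituation,
    a 30 h alternation session, then a 6 h nosepoke-side reversal."""
    return SessionPlan((
        PlanSegment(HABITUATION, 6.0),
        PlanSegment(ALTERNATION, 30.0),
        PlanSegment(REVERSAL, 6.0),
    ))


def rapid_onset_later_week_plan() -> SessionPlan:
    """Later weekly tests: two 30 h sessions with the nosepoke task
    reversed at the start of the second session."""
    return SessionPlan((
        PlanSegment(ALTERNATION, 30.0),
        PlanSegment(ALTERNATION, 30.0, side_swap=True),
    ))


def slow_onset_first_plan() -> SessionPlan:
    """First longitudinal test of the slow-phenotype design: 24 h
    habituation then 48 h on the alternation task."""
    return SessionPlan((
        PlanSegment(HABITUATION, 24.0),
        PlanSegment(ALTERNATION, 48.0),
    ))


def slow_onset_later_plan() -> SessionPlan:
    """Later longitudinal tests: straight onto alternation with the
    contingency reversing after 24 h."""
    return SessionPlan((
        PlanSegment(ALTERNATION, 24.0),
        PlanSegment(ALTERNATION, 24.0, side_swap=True),
    ))


def alternation_only_plan(duration_h: float = 30.0) -> SessionPlan:
    return SessionPlan((PlanSegment(ALTERNATION, duration_h),))


def habituation_only_plan(duration_h: float = 6.0) -> SessionPlan:
    return SessionPlan((PlanSegment(HABITUATION, duration_h),))


# -- YAML round-trip -----------------------------------------------------

def config_to_dict(config: CageConfig, schedule: LightSchedule,
                   plan: SessionPlan) -> dict:
    return {
        "cage": {
            "cage_id": config.cage_id,
            "corner_ids": list(config.corner_ids),
            "active_pair": list(config.active_pair),
            "exploratory_pair": list(config.exploratory_pair),
            "rewarded_side_map": {int(k): v for k, v in
                                  config.rewarded_side_map.items()},
            "cage_width_cm": config.cage_width_cm,
            "cage_height_cm": config.cage_height_cm,
            "climb_zones": [list(z) for z in config.climb_zones],
            "wall_margin_cm": config.wall_margin_cm,
            "frame_rate_hz": config.frame_rate_hz,
        },
        "light_schedule": {
            "lights_on_clock_h": schedule.lights_on_clock_h,
            "light_hours": schedule.light_hours,
            "dark_hours": schedule.dark_hours,
        },
        "session_plan": {
            "demote_window_h": plan.demote_window_h,
            "demote_cadence_h": plan.demote_cadence_h,
            "segments": [
                {"phase": s.phase, "duration_h": s.duration_h,
                 "side_swap": s.side_swap,
                 **({"active_pair": list(s.active_pair)}
                    if s.active_pair else {})}
                for s in plan.segments
            ],
        },
    }


def config_from_dict(d: dict) -> tuple[CageConfig, LightSchedule, SessionPlan]:
    c = d["cage"]
    config = CageConfig(
        cage_id=c["cage_id"],
        corner_ids=tuple(c["corner_ids"]),
        active_pair=tuple(c["active_pair"]),
        exploratory_pair=tuple(c["exploratory_pair"]),
        rewarded_side_map={int(k): v for k, v in c["rewarded_side_map"].items()},
        cage_width_cm=c["cage_width_cm"],
        cage_height_cm=c["cage_height_cm"],
        climb_zones=tuple(tuple(z) for z in c["climb_zones"]),
        wall_margin_cm=c["wall_margin_cm"],
        frame_rate_hz=c["frame_rate_hz"],
    )
    s = d["light_schedule"]
    schedule = LightSchedule(s["lights_on_clock_h"], s["light_hours"],
                             s["dark_hours"])
    p = d["session_plan"]
    plan = SessionPlan(
        tuple(PlanSegment(seg["phase"], seg["duration_h"],
                          seg.get("side_swap", False),
                          tuple(seg["active_pair"]) if seg.get("active_pair")
                          else None)
              for seg in p["segments"]),
        demote_window_h=p.get("demote_window_h", 24.0),
        demote_cadence_h=p.get("demote_cadence_h", 24.0),
    )
    return config, schedule, plan


def load_config(path) -> tuple[CageConfig, LightSchedule, SessionPlan]:
    """Read a cage/schedule/plan YAML (or JSON — YAML is a superset)."""
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(path, config: CageConfig, schedule: LightSchedule,
                plan: SessionPlan) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config, schedule, plan), fh,
                       sort_keys=False)


__all__ = [
    "HABITUATION", "ALTERNATION", "REVERSAL", "PHASES", "LIGHT", "DARK",
    "LEFT", "RIGHT", "SIDES", "Rect", "LightSchedule", "CageConfig",
    "PlanSegment", "SessionPlan", "rapid_onset_first_week_plan",
    "rapid_onset_later_week_plan", "slow_onset_first_plan",
    "slow_onset_later_plan", "alternation_only_plan",
    "habituation_only_plan", "load_config", "save_config",
    "config_to_dict", "config_from_dict",
]
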