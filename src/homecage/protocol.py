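"""Reinforcement-contingency engine for the home-cage alternation task.

The task: two adjacent *active* corners are contingently rewarded, the
other two are *exploratory* and never rewarded.  During habituation any
corner entry opens both water doors for the whole visit.  During the
alternation task, reward is available only in the currently correct
active corner; the only event that moves the correct corner to the other
active corner is a visit to the currently correct one.  Within a correct
visit, the first nosepoke on that corner's rewarded side opens the door
for 8 s; poking the wrong side first carries no penalty beyond being
scored as an inefficient initial poke.  Under reversal the rewarded
nosepoke sides of the two active corners are swapped.

Everything here is deterministic: replaying the same event stream under
the same plan yields a bit-identical annotated stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (ALTERNATION, HABITUATION, REVERSAL, CageConfig,
                     PlanSegment, SessionPlan)
from .events import EventStream

DOOR_OPEN_S = 8.0

# visit annotations
CORRECT = "correct"
INCORRECT = "incorrect"
EXPLORATORY = "exploratory"
HABITUATION_VISIT = "habituation"
ANNOTATIONS = (CORRECT, INCORRECT, EXPLORATORY, HABITUATION_VISIT)


class VisitEvent(NamedTuple):
    animal_id: str
    corner: int
    t_entry: float
    t_exit: float


class NosepokeEvent(NamedTuple):
    animal_id: str
    corner: int
    side: str
    t: float


class LickEvent(NamedTuple):
    animal_id: str
    corner: int
    t: float
    lick_count: int


class RewardEvent(NamedTuple):
    animal_id: str
    corner: int
    side: str
    t_open: float
    door_open_s: float = DOOR_OPEN_S


class VisitAnnotation(NamedTuple):
    """Outcome of classifying one visit against the contingency."""
    annotation: str
    rewarded: bool
    reward_t: Optional[float]
    initial_poke_correct: Optional[bool]  # None if no poke / not scoreable
    phase: str
    target_before: Optional[int]


@dataclass
class ProtocolState:
    """Per-animal contingency state.

    ``target_corner`` is None both during habituation and in the initial
    "either active corner is correct" state of the alternation task.
    ``swapped`` tracks whether the rewarded-side map is currently the
    left/right mirror of the cage configuration.
    """

    animal_id: str
    phase: str = HABITUATION
    target_corner: Optional[int] = None
    swapped: bool = False
    active_pair: Optional[Tuple[int, int]] = None  # None -> config's pair
    rewards_granted: int = 0
    last_active_corner_exit: Optional[float] = None
    demoted: bool = False

    def side_map(self, config: CageConfig) -> Dict[int, str]:
        base = config.swapped_side_map() if self.swapped \
            else dict(config.rewarded_side_map)
        return base

    def current_active_pair(self, config: CageConfig) -> Tuple[int, int]:
        return self.active_pair if self.active_pair is not None \
            else config.active_pair


def init_protocol(config: CageConfig, plan: SessionPlan,
                  roster: Sequence[str]) -> Dict[str, ProtocolState]:
    """Initial per-animal states for the first plan segment.

    Under an alternation-first plan no target is pre-set: either active
    corner counts as correct until the first active-corner visit.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("empty roster")
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate animal id in roster")
    seg = plan.segments[0]
    states = {}
    for a in roster:
        st = ProtocolState(animal_id=a)
        _enter_segment(st, seg)
        states[a] = st
    return states


def _enter_segment(state: ProtocolState, seg: PlanSegment) -> None:
    if state.demoted:
        return
    state.phase = seg.phase
    if seg.phase == HABITUATION:
        state.target_corner = None
        return
    if seg.phase == REVERSAL:
        state.swapped = True
    if seg.side_swap:
        state.swapped = not state.swapped
    if seg.active_pair is not None and seg.active_pair != \
            (state.active_pair or seg.active_pair):
        state.target_corner = None
    if seg.active_pair is not None:
        state.active_pair = seg.active_pair


def apply_side_swap(state: ProtocolState) -> ProtocolState:
    """Swap the rewarded nosepoke sides of both active corners in place.

    An involution; the target corner is unchanged.  Meaningless (and an
    error) during habituation, when both doors open on any entry.
    """
    if state.phase == HABITUATION:
        raise ValueError("side swap is undefined during habituation")
    state.swapped = not state.swapped
    return state


def process_visit(
    state: ProtocolState,
    visit: VisitEvent,
    pokes: Sequence[NosepokeEvent],
    config: CageConfig,
) -> Tuple[ProtocolState, Optional[RewardEvent], VisitAnnotation]:
    """Classify one visit, grant any reward, and advance the contingency.

    The target switch is a consequence of the correct visit itself and is
    applied at classification time, so an immediate re-entry to the same
    corner is already incorrect.  Only the first rewarded-side poke in a
    correct visit opens the door; later pokes in the same visit are inert.
    """
    corner = visit.corner
    if corner not in config.corner_ids:
        raise ValueError(f"unknown corner {corner}")
    phase = state.phase
    target_before = state.target_corner

    if phase == HABITUATION:
        # both doors open for the whole visit; no contingency to advance
        reward = RewardEvent(visit.animal_id, corner, "both", visit.t_entry,
                             visit.t_exit - visit.t_entry)
        ann = VisitAnnotation(HABITUATION_VISIT, True, visit.t_entry, None,
                              phase, None)
        return state, reward, ann

    active = state.current_active_pair(config)
    if corner not in active:
        ann = VisitAnnotation(EXPLORATORY, False, None, None, phase,
                              target_before)
        return state, None, ann

    is_correct = state.target_corner is None or corner == state.target_corner
    a, b = active
    if is_correct:
        # the correct visit both arms the door and moves the target
        state.target_corner = b if corner == a else a
        rewarded_side = state.side_map(config)[corner]
        reward = None
        initial_ok: Optional[bool] = None
        for k, poke in enumerate(pokes):
            if k == 0:
                initial_ok = poke.side == rewarded_side
            if poke.side == rewarded_side:
                reward = RewardEvent(visit.animal_id, corner, rewarded_side,
                                     poke.t)
                break
        if reward is not None:
            state.rewards_granted += 1
        state.last_active_corner_exit = visit.t_exit
        ann = VisitAnnotation(CORRECT, reward is not None,
                              None if reward is None else reward.t_open,
                              initial_ok, phase, target_before)
        return state, reward, ann

    state.last_active_corner_exit = visit.t_exit
    ann = VisitAnnotation(INCORRECT, False, None, None, phase, target_before)
    return state, None, ann


def demote_nonlickers(
    states: Dict[str, ProtocolState],
    licks: pd.DataFrame,
    window_h: float,
    now_s: float,
) -> Tuple[Dict[str, ProtocolState], List[str]]:
    """Switch animals with zero licks over the trailing window back to
    habituation (the electronic per-animal watchdog that protects
    hydration); animals already on habituation are left alone."""
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    lo = now_s - window_h * 3600.0
    t = licks["t"].to_numpy() if len(licks) else np.empty(0)
    ids = licks["animal_id"].to_numpy() if len(licks) else np.empty(0, dtype=object)
    recent = set(ids[(t > lo) & (t <= now_s)])
    demoted = []
    for a, st in states.items():
        if st.phase == HABITUATION:
            continue
        if a not in recent:
            st.phase = HABITUATION
            st.target_corner = None
            st.demoted = True
            demoted.append(a)
    return states, demoted


class ProtocolDriver:
    """Chronological driver shared by stream replay and the simulator.

    Feed it visits (with their in-visit pokes) and licks in time order;
    it handles plan-segment boundaries and periodic non-licker demotion
    checks, and records a state trace.
    """

    def __init__(self, config: CageConfig, plan: SessionPlan,
                 roster: Sequence[str]):
        self.config = config
        self.plan = plan
        self.states = init_protocol(config, plan, roster)
        self._boundaries = list(plan.boundaries_s())[1:]  # first is t=0
        self._segments = list(plan.segments)[1:]
        self._next_check = plan.demote_cadence_h * 3600.0
        self._total = plan.total_duration_s
        self._lick_t: List[float] = []
        self._lick_id: List[str] = []
        self.demotions: List[Tuple[float, str]] = []
        self.trace: List[dict] = []
        for a, st in self.states.items():
            self._trace(0.0, a, "segment_start")

    def _trace(self, t: float, animal: str, event: str) -> None:
        st = self.states[animal]
        self.trace.append({"t": t, "animal_id": animal, "event": event,
                           "phase": st.phase, "target": st.target_corner,
                           "swapped": st.swapped})

    def record_lick(self, animal: str, t: float) -> None:
        self._lick_t.append(t)
        self._lick_id.append(animal)

    def advance_to(self, t: float) -> None:
        """Apply all segment boundaries and demotion checks at times <= t
        (boundaries first on ties)."""
        while True:
            tb = self._boundaries[0] if self._boundaries else np.inf
            tc = self._next_check if self._next_check < self._total else np.inf
            nxt = min(tb, tc)
            if nxt > t:
                return
            if tb <= tc:
                seg = self._segments.pop(0)
                self._boundaries.pop(0)
                for a, st in self.states.items():
                    _enter_segment(st, seg)
                    self._trace(tb, a, "segment_start")
            else:
                licks = pd.DataFrame({"animal_id": self._lick_id,
                                      "t": self._lick_t})
                _, demoted = demote_nonlickers(
                    self.states, licks, self.plan.demote_window_h, tc)
                for a in demoted:
                    self.demotions.append((tc, a))
                    self._trace(tc, a, "demoted")
                self._next_check += self.plan.demote_cadence_h * 3600.0

    def process(self, visit: VisitEvent, pokes: Sequence[NosepokeEvent]
                ) -> Tuple[Optional[RewardEvent], VisitAnnotation]:
        self.advance_to(visit.t_entry)
        st = self.states[visit.animal_id]
        _, reward, ann = process_visit(st, visit, pokes, self.config)
        if ann.annotation == CORRECT:
            self._trace(visit.t_entry, visit.animal_id, "correct_visit")
        return reward, ann


@dataclass
class SessionResult:
    """Annotated replay of a session."""

    visits: pd.DataFrame          # visit table + annotation columns
    rewards: pd.DataFrame         # one row per door opening
    state_trace: pd.DataFrame
    demotions: List[Tuple[float, str]]


_ANNOT_COLS = ["annotation", "rewarded", "reward_t", "initial_poke_correct",
               "phase", "target_before"]


def _pokes_for_visits(visits: pd.DataFrame, pokes: pd.DataFrame
                      ) -> List[List[NosepokeEvent]]:
    """Assign each nosepoke to the visit containing it (same animal and
    corner, t within [entry, exit])."""
    out: List[List[NosepokeEvent]] = [[] for _ in range(len(visits))]
    if not len(pokes):
        return out
    by_animal: Dict[str, list] = {}
    for vi, row in enumerate(visits.itertuples(index=False)):
        by_animal.setdefault(row.animal_id, []).append(
            (row.t_entry, row.t_exit, row.corner, vi))
    for row in pokes.itertuples(index=False):
        for (te, tx, c, vi) in by_animal.get(row.animal_id, ()):
            if c == row.corner and te <= row.t <= tx:
                out[vi].append(NosepokeEvent(row.animal_id, row.corner,
                                             row.side, row.t))
                break
    for lst in out:
        lst.sort(key=lambda p: p.t)
    return out


def run_session(stream: EventStream, plan: SessionPlan,
                config: Optional[CageConfig] = None) -> SessionResult:
    """Deterministically replay a full session plan over an event stream.

    Produces the annotated visit table ({correct, incorrect, exploratory,
    habituation}), the reward (door-opening) log, a state trace with every
    phase change, reversal, and non-licker demotion, and the demotion list.
    """
    config = config or stream.cage_config
    visits = stream.visits.sort_values(
        ["t_entry", "animal_id"], kind="mergesort").reset_index(drop=True)
    total = plan.total_duration_s
    if len(visits) and visits["t_entry"].max() > total:
        raise ValueError("stream contains events beyond the session plan")

    driver = ProtocolDriver(config, plan, stream.roster)
    pokes_per_visit = _pokes_for_visits(visits, stream.nosepokes)

    # licks must be fed chronologically alongside visits for the demotion
    # watchdog to see exactly what had happened by each checkpoint
    licks = stream.licks.sort_values("t", kind="mergesort")
    lick_iter = list(licks.itertuples(index=False))
    li = 0

    annotations: List[VisitAnnotation] = []
    rewards: List[RewardEvent] = []
    for vi, row in enumerate(visits.itertuples(index=False)):
        while li < len(lick_iter) and lick_iter[li].t < row.t_entry:
            driver.record_lick(lick_iter[li].animal_id, lick_iter[li].t)
            li += 1
        visit = VisitEvent(row.animal_id, row.corner, row.t_entry, row.t_exit)
        reward, ann = driver.process(visit, pokes_per_visit[vi])
        annotations.append(ann)
        if reward is not None and ann.annotation != HABITUATION_VISIT:
            rewards.append(reward)
    while li < len(lick_iter):
        driver.record_lick(lick_iter[li].animal_id, lick_iter[li].t)
        li += 1
    driver.advance_to(total)

    annotated = visits.copy()
    for col, vals in zip(_ANNOT_COLS, zip(*annotations)) if annotations else []:
        annotated[col] = list(vals)
    if not annotations:
        for col in _ANNOT_COLS:
            annotated[col] = pd.Series(dtype=object)
    rewards_df = pd.DataFrame(rewards, columns=RewardEvent._fields) \
        if rewards else pd.DataFrame(columns=RewardEvent._fields)
    trace_df = pd.DataFrame(driver.trace)
    return SessionResult(annotated, rewards_df, trace_df, driver.demotions)


__all__ = [
    "DOOR_OPEN_S", "CORRECT", "INCORRECT", "EXPLORATORY",
    "HABITUATION_VISIT", "ANNOTATIONS", "VisitEvent", "NosepokeEvent",
    "LickEvent", "RewardEvent", "VisitAnnotation", "ProtocolState",
    "ProtocolDriver", "SessionResult", "init_protocol", "process_visit",
    "apply_side_swap", "demote_nonlickers", "run_session",
]
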