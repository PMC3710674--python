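"""Agent-based simulator of group-housed mice in an instrumented cage.

Generates the two input families every downstream stage consumes —
corner-event streams (visits, nosepokes, licks) and per-frame detection
tables — with the statistical structure the analyses assume:

* visit times follow an inhomogeneous Poisson process whose rate is a
  square wave locked to the 12:12 light/dark schedule (nocturnal animals:
  rate x ``dark_activity_multiplier`` in the dark);
* corner choice is a mixture of task-directed choice (probability
  ``alternation_competence`` of heading to the currently correct corner),
  perseverative return to the previous corner (``perseveration_bias``),
  and uniform exploration;
* the reinforcement contingency is applied *during* generation through
  the same :class:`~homecage.protocol.ProtocolDriver` used for replay, so
  ground-truth annotations, rewards, and non-licker demotions are logged
  as they happen;
* corner chambers hold one mouse at a time: an arriving mouse waits
  briefly for an occupied corner, otherwise redirects;
* between corner visits, trajectories are a two-state (immobile/moving)
  correlated random walk with climbing-structure excursions; mice inside
  a corner are invisible to the camera and emit no detections.

A single integer seed makes every output bit-reproducible; per-animal
substreams are spawned deterministically so editing one animal's
parameters does not perturb the others' event noise.
"""

from __future__ import annotations

import heapq
import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import (ALTERNATION, DARK, HABITUATION, REVERSAL, CageConfig,
                     LightSchedule, SessionPlan, alternation_only_plan)
from .events import (EventStream, empty_frames, empty_licks, empty_nosepokes,
                     empty_visits)
from .protocol import (CORRECT, HABITUATION_VISIT, NosepokeEvent,
                       ProtocolDriver, RewardEvent, VisitEvent)

_PARAM_FIELDS = (
    "visit_rate_per_h", "dark_activity_multiplier", "perseveration_bias",
    "alternation_competence", "lick_rate_per_reward",
    "lick_rate_multiplier_dark", "poke_side_accuracy", "nosepoke_prob",
    "mean_speed_cm_s", "immobile_fraction", "climb_rate_per_h",
    "nonlicker_prob",
)


@dataclass(frozen=True)
class GenotypeParams:
    """Behavioral parameter set for one animal (or one genotype group)."""

    visit_rate_per_h: float = 3.0
    dark_activity_multiplier: float = 2.0
    perseveration_bias: float = 0.05
    alternation_competence: float = 0.70
    lick_rate_per_reward: float = 25.0
    lick_rate_multiplier_dark: float = 1.2
    poke_side_accuracy: float = 0.75
    nosepoke_prob: float = 0.90
    mean_speed_cm_s: float = 6.0
    immobile_fraction: float = 0.35
    climb_rate_per_h: float = 4.0
    nonlicker_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("perseveration_bias", "alternation_competence",
                     "poke_side_accuracy", "nosepoke_prob",
                     "immobile_fraction", "nonlicker_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.alternation_competence + self.perseveration_bias > 1.0:
            raise ValueError("competence + perseveration bias must be <= 1")
        for name in ("visit_rate_per_h", "lick_rate_per_reward",
                     "climb_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dark_activity_multiplier <= 0:
            raise ValueError("dark_activity_multiplier must be > 0")
        if self.mean_speed_cm_s <= 0:
            raise ValueError("mean_speed_cm_s must be > 0")


def _load_presets() -> dict:
    text = importlib.resources.files("homecage").joinpath("presets.yaml") \
        .read_text(encoding="utf-8")
    return yaml.safe_load(text)


PRESET_NAMES = ("WT_like", "R6/2_like", "BACHD_like")


def preset_params(name: str) -> GenotypeParams:
    presets = _load_presets()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; have {sorted(presets)}")
    return GenotypeParams(**presets[name])


def preset_cohort(name: str, n: int = 11, prefix: Optional[str] = None
                  ) -> Dict[str, GenotypeParams]:
    """Roster of ``n`` identically parameterised animals for a preset."""
    params = preset_params(name)
    if prefix is None:
        prefix = name.split("_")[0].replace("/", "").replace("-", "")
    return {f"{prefix}{i:02d}": params for i in range(1, n + 1)}


@dataclass
class SimConfig:
    """Everything that determines one simulated session."""

    roster: Dict[str, GenotypeParams]
    cage_config: CageConfig = field(default_factory=CageConfig)
    light_schedule: LightSchedule = field(default_factory=LightSchedule)
    session_plan: SessionPlan = field(default_factory=alternation_only_plan)
    seed: int = 0
    session_start_clock_h: Optional[float] = None  # default: lights-on
    queue_timeout_s: float = 60.0
    visit_duration_median_s: float = 15.0
    visit_duration_sigma: float = 0.5
    generate_frames: bool = False

    @property
    def start_clock_h(self) -> float:
        if self.session_start_clock_h is not None:
            return self.session_start_clock_h
        return self.light_schedule.lights_on_clock_h


@dataclass
class SimResult:
    """Simulator output: the stream plus its logged ground truth."""

    stream: EventStream
    annotated_visits: pd.DataFrame   # with annotation / reward / phase cols
    rewards: pd.DataFrame
    demotions: List[Tuple[float, str]]
    frame_truth: Optional[pd.DataFrame]  # t, animal_id, immobile, climbing
    genotypes: Dict[str, str]


def _is_dark(t: float, start_clock_h: float, sched: LightSchedule) -> bool:
    clock = (start_clock_h + t / 3600.0) % 24.0
    return (clock - sched.lights_on_clock_h) % 24.0 >= sched.light_hours


def _next_visit_time(rng: np.random.Generator, t0: float,
                     params: GenotypeParams, start_clock_h: float,
                     sched: LightSchedule) -> float:
    """Next arrival of the circadian-modulated Poisson process (thinning)."""
    mult = params.dark_activity_multiplier
    lam_max = params.visit_rate_per_h * max(1.0, mult) / 3600.0
    if lam_max <= 0:
        return np.inf
    t = t0
    while True:
        t += rng.exponential(1.0 / lam_max)
        lam = params.visit_rate_per_h * (
            mult if _is_dark(t, start_clock_h, sched) else 1.0) / 3600.0
        if rng.random() * lam_max < lam:
            return t


def _choose_corner(rng: np.random.Generator, params: GenotypeParams,
                   state, prev_corner: Optional[int],
                   config: CageConfig) -> int:
    corners = config.corner_ids
    u = rng.random()
    if state.phase in (ALTERNATION, REVERSAL):
        comp = params.alternation_competence
        if u < comp:
            tgt = state.target_corner
            if tgt is None:
                pair = state.current_active_pair(config)
                return pair[int(rng.integers(2))]
            return tgt
        if u < comp + params.perseveration_bias and prev_corner is not None:
            return prev_corner
        return corners[int(rng.integers(4))]
    if u < params.perseveration_bias and prev_corner is not None:
        return prev_corner
    return corners[int(rng.integers(4))]


def simulate_cohort(sim: SimConfig) -> SimResult:
    """Run one full simulated session; fully determined by ``sim.seed``."""
    config = sim.cage_config
    sched = sim.light_schedule
    plan = sim.session_plan
    start_clock = sim.start_clock_h
    duration = plan.total_duration_s
    roster = list(sim.roster)
    if not roster:
        raise ValueError("empty roster")

    ss = np.random.SeedSequence(sim.seed)
    children = ss.spawn(2 * len(roster))
    event_rng = {a: np.random.default_rng(children[i])
                 for i, a in enumerate(roster)}
    traj_rng = {a: np.random.default_rng(children[len(roster) + i])
                for i, a in enumerate(roster)}

    driver = ProtocolDriver(config, plan, roster)

    # per-animal nonlicker fate
    lick_stop_at: Dict[str, float] = {}
    for a in roster:
        rng = event_rng[a]
        if rng.random() < sim.roster[a].nonlicker_prob:
            lick_stop_at[a] = float(rng.uniform(0.2, 0.5)) * duration
        else:
            lick_stop_at[a] = np.inf

    occupied_until = {c: -np.inf for c in config.corner_ids}
    prev_corner: Dict[str, Optional[int]] = {a: None for a in roster}
    visits_by_animal: Dict[str, List[Tuple[float, float]]] = {a: [] for a in roster}

    heap: List[Tuple[float, int, str]] = []
    counter = 0
    for a in roster:
        t0 = _next_visit_time(event_rng[a], 0.0, sim.roster[a], start_clock, sched)
        heapq.heappush(heap, (t0, counter, a))
        counter += 1

    vis_rows, poke_rows, lick_rows = [], [], []
    ann_rows: List[dict] = []
    reward_rows: List[RewardEvent] = []

    while heap:
        t, _, a = heapq.heappop(heap)
        if t >= duration:
            continue
        rng = event_rng[a]
        params = sim.roster[a]
        driver.advance_to(t)
        state = driver.states[a]
        corner = _choose_corner(rng, params, state, prev_corner[a], config)
        if occupied_until[corner] > t:
            wait = occupied_until[corner] - t
            if wait <= sim.queue_timeout_s:
                heapq.heappush(heap, (occupied_until[corner] + 1e-3, counter, a))
                counter += 1
                continue
            free = [c for c in config.corner_ids if occupied_until[c] <= t]
            if not free:
                t_retry = min(occupied_until.values()) + 1e-3
                heapq.heappush(heap, (t_retry, counter, a))
                counter += 1
                continue
            corner = free[int(rng.integers(len(free)))]

        dur = float(np.exp(np.log(sim.visit_duration_median_s)
                           + sim.visit_duration_sigma * rng.standard_normal()))
        dur = max(dur, 2.0)
        t_entry = t
        t_exit = min(t_entry + dur, duration)
        if t_exit <= t_entry + 1e-6:
            continue
        occupied_until[corner] = t_exit

        # nosepokes (mouse behavior does not depend on door state)
        pokes: List[NosepokeEvent] = []
        is_active = corner in state.current_active_pair(config)
        on_task = state.phase in (ALTERNATION, REVERSAL)
        poke_p = params.nosepoke_prob if (is_active or not on_task) \
            else 0.3 * params.nosepoke_prob
        if rng.random() < poke_p:
            t1 = t_entry + min(1.0, 0.3 * (t_exit - t_entry))
            if on_task and is_active:
                rewarded_side = state.side_map(config)[corner]
                other = "left" if rewarded_side == "right" else "right"
                if rng.random() < params.poke_side_accuracy:
                    pokes.append(NosepokeEvent(a, corner, rewarded_side, t1))
                else:
                    pokes.append(NosepokeEvent(a, corner, other, t1))
                    t2 = min(t1 + 1.0, t_exit)
                    if t2 > t1 and rng.random() < 0.9:
                        pokes.append(NosepokeEvent(a, corner, rewarded_side, t2))
            else:
                side = "left" if rng.random() < 0.5 else "right"
                pokes.append(NosepokeEvent(a, corner, side, t1))

        visit = VisitEvent(a, corner, t_entry, t_exit)
        reward, ann = driver.process(visit, pokes)

        # licking: on the task only during the 8 s reward window; during
        # habituation freely whenever the animal bothers to drink
        lick_t = None
        dark_here = _is_dark(t_entry, start_clock, sched)
        lick_mean = params.lick_rate_per_reward * (
            params.lick_rate_multiplier_dark if dark_here else 1.0)
        if ann.annotation == HABITUATION_VISIT:
            if rng.random() < 0.9:
                lick_t = t_entry + 0.6 * (t_exit - t_entry)
        elif reward is not None:
            lick_t = min(reward.t_open + 0.5, t_exit)
        if lick_t is not None and lick_t < lick_stop_at[a]:
            n_licks = int(rng.poisson(lick_mean))
            if n_licks >= 1:
                lick_rows.append((a, corner, lick_t, n_licks))
                driver.record_lick(a, lick_t)

        vis_rows.append((a, corner, t_entry, t_exit))
        poke_rows.extend(pokes)
        if reward is not None and ann.annotation == CORRECT:
            reward_rows.append(reward)
        ann_rows.append({
            "animal_id": a, "corner": corner, "t_entry": t_entry,
            "t_exit": t_exit, "annotation": ann.annotation,
            "rewarded": ann.rewarded, "reward_t": ann.reward_t,
            "initial_poke_correct": ann.initial_poke_correct,
            "phase": ann.phase, "target_before": ann.target_before,
        })
        prev_corner[a] = corner
        visits_by_animal[a].append((t_entry, t_exit))

        t_next = _next_visit_time(rng, t_exit, params, start_clock, sched)
        if t_next < duration:
            heapq.heappush(heap, (t_next, counter, a))
            counter += 1
    driver.advance_to(duration)

    visits = pd.DataFrame(vis_rows, columns=["animal_id", "corner",
                                             "t_entry", "t_exit"]) \
        if vis_rows else empty_visits()
    pokes_df = pd.DataFrame(poke_rows, columns=["animal_id", "corner",
                                                "side", "t"]) \
        if poke_rows else empty_nosepokes()
    pokes_df = pokes_df.sort_values("t", kind="mergesort").reset_index(drop=True)
    licks_df = pd.DataFrame(lick_rows, columns=["animal_id", "corner", "t",
                                                "lick_count"]) \
        if lick_rows else empty_licks()
    licks_df = licks_df.sort_values("t", kind="mergesort").reset_index(drop=True)
    annotated = pd.DataFrame(ann_rows) if ann_rows else pd.DataFrame(
        columns=["animal_id", "corner", "t_entry", "t_exit", "annotation",
                 "rewarded", "reward_t", "initial_poke_correct", "phase",
                 "target_before"])
    annotated = annotated.sort_values(["t_entry", "animal_id"],
                                      kind="mergesort").reset_index(drop=True)
    rewards_df = pd.DataFrame(reward_rows, columns=RewardEvent._fields) \
        if reward_rows else pd.DataFrame(columns=RewardEvent._fields)

    frames = None
    frame_truth = None
    if sim.generate_frames:
        frames, frame_truth = _synthesize_frames(
            sim, traj_rng, visits_by_animal, duration)

    stream = EventStream(config, sched, tuple(roster), visits, pokes_df,
                         licks_df, frames, start_clock, duration)
    genotypes = {a: _genotype_label(sim.roster[a]) for a in roster}
    return SimResult(stream, annotated, rewards_df, driver.demotions,
                     frame_truth, genotypes)


def _genotype_label(params: GenotypeParams) -> str:
    presets = _load_presets()
    for name, vals in presets.items():
        if all(abs(getattr(params, f) - vals[f]) < 1e-12
               for f in _PARAM_FIELDS):
            return name
    return "custom"


# ---------------------------------------------------------------------
# trajectory synthesis


def _push_out_of_zones(xy: np.ndarray, zones, width: float, height: float
                       ) -> np.ndarray:
    """Project points that fall inside a climb zone to just outside its
    nearest edge (the open floor the animals actually walk on).  Edges
    flush with a cage wall are never used as the exit direction."""
    for (x0, y0, x1, y1) in zones:
        inside = ((xy[:, 0] > x0) & (xy[:, 0] < x1)
                  & (xy[:, 1] > y0) & (xy[:, 1] < y1))
        if not inside.any():
            continue
        px = xy[inside, 0]
        py = xy[inside, 1]
        d = np.stack([px - x0, x1 - px, py - y0, y1 - py], axis=1)
        blocked = np.array([x0 <= 0.02, x1 >= width - 0.02,
                            y0 <= 0.02, y1 >= height - 0.02])
        d[:, blocked] = np.inf
        side = np.argmin(d, axis=1)
        px = np.where(side == 0, x0 - 0.01, np.where(side == 1, x1 + 0.01, px))
        py = np.where(side == 2, y0 - 0.01, np.where(side == 3, y1 + 0.01, py))
        xy[inside, 0] = px
        xy[inside, 1] = py
    return xy


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect positions into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def _markov_states(rng: np.random.Generator, n: int, immobile_fraction: float,
                   switch_scale: float = 0.05) -> np.ndarray:
    """Two-state chain with the requested stationary immobile fraction.

    Transition probabilities are chosen so the stationary distribution is
    exactly ``immobile_fraction`` while dwell times stay realistically
    long (mean dwell ~ 1/(switch_scale) frames).
    """
    f = immobile_fraction
    if f <= 0:
        return np.zeros(n, dtype=bool)
    if f >= 1:
        return np.ones(n, dtype=bool)
    leave_immobile = (1.0 - f) * switch_scale
    leave_moving = f * switch_scale
    states = np.empty(n, dtype=bool)
    state = rng.random() < f
    i = 0
    while i < n:
        p_leave = leave_immobile if state else leave_moving
        dwell = 1 + int(rng.geometric(p_leave))
        j = min(n, i + dwell)
        states[i:j] = state
        state = not state
        i = j
    return states


def _synthesize_frames(sim: SimConfig, traj_rng, visits_by_animal,
                       duration: float):
    config = sim.cage_config
    fps = config.frame_rate_hz
    n_frames = int(np.floor(duration * fps))
    t_grid = np.arange(n_frames) / fps
    W, H = config.cage_width_cm, config.cage_height_cm
    m = 1.0  # wall standoff for the walk itself

    frames_parts = []
    truth_parts = []
    for a, visits in visits_by_animal.items():
        rng = traj_rng[a]
        params = sim.roster[a]

        in_corner = np.zeros(n_frames, dtype=bool)
        for (te, tx) in visits:
            i0 = int(np.ceil(te * fps))
            i1 = int(np.floor(tx * fps)) + 1
            in_corner[max(0, i0):min(n_frames, i1)] = True

        immobile = _markov_states(rng, n_frames, params.immobile_fraction)
        headings = np.cumsum(rng.normal(0.0, 0.35, n_frames))
        speeds = np.abs(rng.normal(params.mean_speed_cm_s,
                                   0.2 * params.mean_speed_cm_s, n_frames))
        speeds = np.maximum(speeds, 1.5)
        step = np.where(immobile, 0.0, speeds / fps)
        dx = step * np.cos(headings)
        dy = step * np.sin(headings)
        x = _fold(rng.uniform(m, W - m) + np.cumsum(dx), m, W - m)
        y = _fold(rng.uniform(m, H - m) + np.cumsum(dy), m, H - m)
        xy = np.stack([x, y], axis=1)
        xy = _push_out_of_zones(xy, config.climb_zones, W, H)

        # climbing excursions: relocate into a random climb zone with a
        # dwell; the animal is active (jittering) while it climbs
        climbing = np.zeros(n_frames, dtype=bool)
        if params.climb_rate_per_h > 0 and config.climb_zones:
            lam = params.climb_rate_per_h / 3600.0
            t_exc = rng.exponential(1.0 / lam)
            while t_exc < duration:
                dwell = max(3.0, rng.exponential(15.0))
                i0 = int(t_exc * fps)
                i1 = min(n_frames, int((t_exc + dwell) * fps))
                if i1 > i0:
                    z = config.climb_zones[int(rng.integers(len(config.climb_zones)))]
                    cx, cy = (z[0] + z[2]) / 2.0, (z[1] + z[3]) / 2.0
                    k = i1 - i0
                    xy[i0:i1, 0] = cx + rng.normal(0.0, 0.15, k)
                    xy[i0:i1, 1] = cy + rng.normal(0.0, 0.15, k)
                    climbing[i0:i1] = True
                t_exc += dwell + rng.exponential(1.0 / lam)
        immobile = immobile & ~climbing

        visible = ~in_corner
        w_box = np.where(climbing, 3.0, 6.0)
        h_box = np.where(climbing, 6.0, 3.0)
        frames_parts.append(pd.DataFrame({
            "t": t_grid[visible], "x_cm": xy[visible, 0],
            "y_cm": xy[visible, 1], "box_w_cm": w_box[visible],
            "box_h_cm": h_box[visible]}))
        truth_parts.append(pd.DataFrame({
            "t": t_grid[visible], "animal_id": a,
            "immobile": immobile[visible], "climbing": climbing[visible]}))

    frames = pd.concat(frames_parts, ignore_index=True) if frames_parts \
        else empty_frames()
    truth = pd.concat(truth_parts, ignore_index=True) if truth_parts else None
    order = np.argsort(frames["t"].to_numpy(), kind="mergesort")
    frames = frames.iloc[order].reset_index(drop=True)
    if truth is not None:
        truth = truth.iloc[order].reset_index(drop=True)
    return frames, truth


def ground_truth_tracks(result: SimResult) -> List[pd.DataFrame]:
    """Per-animal tracks from the simulator's own identity labels
    (bypassing anonymous tracklet linking), split at camera gaps."""
    if result.stream.frames is None or result.frame_truth is None:
        return []
    frames = result.stream.frames
    truth = result.frame_truth
    fps = result.stream.cage_config.frame_rate_hz
    out = []
    for a in truth["animal_id"].unique():
        mask = (truth["animal_id"] == a).to_numpy()
        tr = frames[mask].sort_values("t", kind="mergesort")
        t = tr["t"].to_numpy()
        if not len(t):
            continue
        breaks = np.nonzero(np.diff(t) > 1.5 / fps)[0] + 1
        for seg in np.split(np.arange(len(t)), breaks):
            if len(seg) >= 2:
                out.append(tr.iloc[seg].reset_index(drop=True))
    return out


def inject_nonlickers(stream: EventStream, ids: Sequence[str],
                      onset_s: float = 0.0) -> EventStream:
    """Remove all licks at/after ``onset_s`` for the listed animals —
    the attrition mode where a mouse stops drinking on the task."""
    unknown = set(ids) - set(stream.roster)
    if unknown:
        raise ValueError(f"unknown animal id(s): {sorted(unknown)}")
    out = stream.copy()
    if not len(out.licks) or not ids:
        return out
    drop = out.licks["animal_id"].isin(set(ids)) & (out.licks["t"] >= onset_s)
    out.licks = out.licks[~drop].reset_index(drop=True)
    return out


__all__ = [
    "GenotypeParams", "SimConfig", "SimResult", "PRESET_NAMES",
    "preset_params", "preset_cohort", "simulate_cohort",
    "inject_nonlickers", "ground_truth_tracks",
]
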