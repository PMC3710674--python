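"""Trajectory-level activity endpoints from per-frame detection tables.

These mirror the endpoints an overhead-camera scoring system produces
for group-housed cages: locomotion (distance per mouse), percent time
immobile, and percent time rearing-or-climbing.  Detections are
anonymous — no persistent identity is claimed — so all endpoints are
pooled per cage.  Animals inside a corner chamber produce no detections.

Speed is estimated from consecutive-frame displacement at the configured
frame rate; a detection is immobile when its instantaneous speed falls
strictly below the cutoff (0.7 cm/s by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import DARK, LIGHT, CageConfig, LightSchedule
from .lightcycle import assign_light_phase


@dataclass(frozen=True)
class ActivityParams:
    """Tunables for the activity endpoints.

    * ``immobility_speed_cutoff_cm_s``: strict upper bound for immobility
      (speed < cutoff counts as immobile).
    * ``rearing_wall_margin_cm`` / ``rearing_aspect_min``: a detection is
      rearing when its centroid is within the margin of a wall and its
      bounding box is at least this much taller than wide.
    * ``min_track_gap_frames``: tracklets are split when detections
      vanish for longer than this many frame periods.
    * ``max_link_dist_cm``: gating distance for frame-to-frame
      association.
    """

    immobility_speed_cutoff_cm_s: float = 0.7
    rearing_wall_margin_cm: float = 3.0
    rearing_aspect_min: float = 1.2
    min_track_gap_frames: int = 5
    max_link_dist_cm: float = 8.0
    speed_smooth_frames: int = 1  # 1 = no smoothing

    def __post_init__(self) -> None:
        if self.immobility_speed_cutoff_cm_s <= 0:
            raise ValueError("immobility cutoff must be > 0")
        if self.rearing_aspect_min <= 0:
            raise ValueError("rearing_aspect_min must be > 0")


def _frames_by_time(frames: pd.DataFrame) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Unique frame times and, per time, the detection array
    [[x, y, w, h], ...]."""
    t = frames["t"].to_numpy()
    order = np.argsort(t, kind="mergesort")
    t = t[order]
    xywh = frames[["x_cm", "y_cm", "box_w_cm", "box_h_cm"]].to_numpy()[order]
    times, starts = np.unique(t, return_index=True)
    groups = np.split(xywh, starts[1:])
    return times, groups


def _match(prev: np.ndarray, cur: np.ndarray, max_dist: float
           ) -> List[Tuple[int, int]]:
    """Optimal assignment between two detection sets, gated by distance."""
    if not len(prev) or not len(cur):
        return []
    d = np.linalg.norm(prev[:, None, :2] - cur[None, :, :2], axis=2)
    ri, ci = linear_sum_assignment(d)
    return [(i, j) for i, j in zip(ri, ci) if d[i, j] <= max_dist]


def link_tracks(frames: pd.DataFrame, config: CageConfig,
                params: ActivityParams = ActivityParams()
                ) -> List[pd.DataFrame]:
    """Nearest-neighbour frame-to-frame association into short tracklets.

    Tracklets end at occlusions (no matchable detection), at gating
    failures, and at frame gaps longer than ``min_track_gap_frames``.
    No global identity is claimed — a tracklet is an anonymous segment.
    """
    times, groups = _frames_by_time(frames)
    dt_max = params.min_track_gap_frames / config.frame_rate_hz
    open_tracks: Dict[int, List[Tuple[float, float, float, float, float]]] = {}
    done: List[List[Tuple[float, float, float, float, float]]] = []
    next_id = 0
    prev_dets: np.ndarray = np.empty((0, 4))
    prev_ids: List[int] = []
    prev_t = None
    for t, dets in zip(times, groups):
        if prev_t is not None and t - prev_t > dt_max + 1e-9:
            for tid in prev_ids:
                done.append(open_tracks.pop(tid))
            prev_ids = []
            prev_dets = np.empty((0, 4))
        pairs = _match(prev_dets, dets, params.max_link_dist_cm)
        matched_prev = {i for i, _ in pairs}
        matched_cur = {j for _, j in pairs}
        new_ids: List[Optional[int]] = [None] * len(dets)
        for i, j in pairs:
            tid = prev_ids[i]
            open_tracks[tid].append((t, *dets[j]))
            new_ids[j] = tid
        for i, tid in enumerate(prev_ids):
            if i not in matched_prev:
                done.append(open_tracks.pop(tid))
        for j in range(len(dets)):
            if j not in matched_cur:
                tid = next_id
                next_id += 1
                open_tracks[tid] = [(t, *dets[j])]
                new_ids[j] = tid
        prev_ids = [tid for tid in new_ids if tid is not None]
        prev_dets = dets
        prev_t = t
    done.extend(open_tracks.values())
    cols = ["t", "x_cm", "y_cm", "box_w_cm", "box_h_cm"]
    return [pd.DataFrame(tr, columns=cols) for tr in done if len(tr)]


def compute_locomotion(frames: pd.DataFrame, config: CageConfig,
                       schedule: LightSchedule, start_clock_h: float,
                       params: ActivityParams = ActivityParams()
                       ) -> Dict[str, float]:
    """Distance travelled per mouse, by light phase.

    For each consecutive frame pair the matched displacement magnitudes
    are summed and divided by the number of mice detected in that frame;
    frames with no detections contribute nothing.
    """
    times, groups = _frames_by_time(frames)
    dt_max = params.min_track_gap_frames / config.frame_rate_hz
    out = {LIGHT: 0.0, DARK: 0.0}
    for k in range(1, len(times)):
        if times[k] - times[k - 1] > dt_max + 1e-9:
            continue
        cur = groups[k]
        if not len(cur):
            continue
        pairs = _match(groups[k - 1], cur, params.max_link_dist_cm)
        if not pairs:
            continue
        disp = sum(float(np.linalg.norm(groups[k - 1][i, :2] - cur[j, :2]))
                   for i, j in pairs)
        phase = assign_light_phase(times[k], start_clock_h, schedule)
        out[phase] += disp / len(cur)
    return out


def track_speeds(track: pd.DataFrame, config: CageConfig) -> np.ndarray:
    """Instantaneous speeds (cm/s) for frames 1..n-1 of a tracklet."""
    xy = track[["x_cm", "y_cm"]].to_numpy()
    t = track["t"].to_numpy()
    if len(xy) < 2:
        return np.empty(0)
    dt = np.diff(t)
    dt[dt <= 0] = 1.0 / config.frame_rate_hz
    return np.linalg.norm(np.diff(xy, axis=0), axis=1) / dt


def compute_immobility(tracklets: List[pd.DataFrame], config: CageConfig,
                       schedule: LightSchedule, start_clock_h: float,
                       params: ActivityParams = ActivityParams()
                       ) -> Dict[str, float]:
    """Percent of detected animal-frames with speed strictly below the
    cutoff, by light phase.  NaN when a phase has no scoreable frames."""
    counts = {LIGHT: 0, DARK: 0}
    immobile = {LIGHT: 0, DARK: 0}
    for tr in tracklets:
        sp = track_speeds(tr, config)
        if not len(sp):
            continue
        if params.speed_smooth_frames > 1:
            k = params.speed_smooth_frames
            kernel = np.ones(k) / k
            sp = np.convolve(sp, kernel, mode="same")
        ph = assign_light_phase(tr["t"].to_numpy()[1:], start_clock_h, schedule)
        # strict cutoff with a guard for float roundoff in dist * rate
        thr = params.immobility_speed_cutoff_cm_s - 1e-9
        for p in (LIGHT, DARK):
            m = ph == p
            counts[p] += int(m.sum())
            immobile[p] += int((sp[m] < thr).sum())
    return {p: (100.0 * immobile[p] / counts[p] if counts[p] else np.nan)
            for p in (LIGHT, DARK)}


def _in_any_zone(x: np.ndarray, y: np.ndarray, zones) -> np.ndarray:
    hit = np.zeros(len(x), dtype=bool)
    for (x0, y0, x1, y1) in zones:
        hit |= (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    return hit


def compute_rearing_climbing(frames: pd.DataFrame, config: CageConfig,
                             schedule: LightSchedule, start_clock_h: float,
                             params: ActivityParams = ActivityParams()
                             ) -> Dict[str, float]:
    """Percent of detected animal-frames scored rearing or climbing.

    Climbing: centroid inside any configured climb zone.  Rearing:
    centroid within the wall margin and bounding box taller than wide by
    at least ``rearing_aspect_min``.  Reported jointly, as one combined
    endpoint.
    """
    if not len(frames):
        return {LIGHT: np.nan, DARK: np.nan}
    x = frames["x_cm"].to_numpy()
    y = frames["y_cm"].to_numpy()
    w = frames["box_w_cm"].to_numpy()
    h = frames["box_h_cm"].to_numpy()
    climbing = _in_any_zone(x, y, config.climb_zones)
    near_wall = ((x <= params.rearing_wall_margin_cm)
                 | (x >= config.cage_width_cm - params.rearing_wall_margin_cm)
                 | (y <= params.rearing_wall_margin_cm)
                 | (y >= config.cage_height_cm - params.rearing_wall_margin_cm))
    with np.errstate(divide="ignore", invalid="ignore"):
        aspect = np.where(w > 0, h / np.maximum(w, 1e-9), 0.0)
    rearing = near_wall & (aspect >= params.rearing_aspect_min)
    flagged = climbing | rearing
    ph = assign_light_phase(frames["t"].to_numpy(), start_clock_h, schedule)
    out = {}
    for p in (LIGHT, DARK):
        m = ph == p
        out[p] = 100.0 * flagged[m].sum() / m.sum() if m.sum() else np.nan
    return out


def build_activity_table(frames: pd.DataFrame, config: CageConfig,
                         schedule: LightSchedule, start_clock_h: float,
                         session_label: str = "session",
                         params: ActivityParams = ActivityParams()
                         ) -> pd.DataFrame:
    """Tidy per-(cage, light phase) table of the three activity endpoints."""
    tracklets = link_tracks(frames, config, params)
    loco = compute_locomotion(frames, config, schedule, start_clock_h, params)
    immob = compute_immobility(tracklets, config, schedule, start_clock_h,
                               params)
    rc = compute_rearing_climbing(frames, config, schedule, start_clock_h,
                                  params)
    rows = []
    for p in (LIGHT, DARK):
        rows.append({
            "cage_id": config.cage_id,
            "session_label": session_label,
            "light_phase": p,
            "locomotion_cm_per_mouse": loco[p],
            "pct_time_immobile": immob[p],
            "pct_time_rearing_climbing": rc[p],
        })
    return pd.DataFrame(rows)


__all__ = [
    "ActivityParams", "link_tracks", "compute_locomotion", "track_speeds",
    "compute_immobility", "compute_rearing_climbing", "build_activity_table",
]
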