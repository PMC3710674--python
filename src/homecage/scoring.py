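"""Behavioral measures from annotated event streams.

Five measures, reported per animal (optionally pooled per cage), per
session, per light phase:

* corner entries per hour
* licks per hour
* percent repeats        — immediate returns to the corner just visited,
                           over all four corners
* percent alternation    — active-to-active corner transitions (within a
                           time window of leaving an active corner) that
                           switch corners
* percent collected rewards — active-corner entries containing at least
                           one nosepoke

Undefined measures (zero denominators) come out as NaN, never 0 or 100,
so group summaries are not biased by empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ALTERNATION, DARK, LIGHT, REVERSAL, CageConfig, LightSchedule
from .lightcycle import assign_light_phase, phase_exposure_hours

TASK_PHASES = (ALTERNATION, REVERSAL)


@dataclass(frozen=True)
class AlternationParams:
    """Scoring window for percent alternation.

    ``window_s`` caps the interval between leaving an active corner and
    entering the next one; longer gaps are excluded so that unrelated
    pauses do not dilute the statistic (113 s by default).  With
    ``include_excluded_in_denominator`` the excluded transitions still
    count as opportunities (the alternative denominator convention).
    """

    window_s: float = 113.0
    include_excluded_in_denominator: bool = False

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")


def _phase_rates(t: np.ndarray, weights: Optional[np.ndarray],
                 schedule: LightSchedule, start_clock_h: float,
                 duration_s: float) -> Dict[str, float]:
    exposure = phase_exposure_hours(duration_s, start_clock_h, schedule)
    phases = assign_light_phase(np.atleast_1d(t), start_clock_h, schedule) \
        if len(t) else np.empty(0, dtype=object)
    out = {}
    for ph in (LIGHT, DARK):
        if exposure[ph] <= 0:
            out[ph] = np.nan
            continue
        mask = phases == ph
        total = float(weights[mask].sum()) if weights is not None \
            else float(mask.sum())
        out[ph] = total / exposure[ph]
    return out


def score_corner_entries(visits: pd.DataFrame, schedule: LightSchedule,
                         start_clock_h: float, duration_s: float
                         ) -> Dict[str, float]:
    """Corner entries per hour by light phase (entry time decides the
    phase; exposure uses the actual per-phase hours of the session)."""
    return _phase_rates(visits["t_entry"].to_numpy(), None, schedule,
                        start_clock_h, duration_s)


def score_licks(licks: pd.DataFrame, schedule: LightSchedule,
                start_clock_h: float, duration_s: float) -> Dict[str, float]:
    """Lick count per hour by light phase."""
    return _phase_rates(licks["t"].to_numpy(),
                        licks["lick_count"].to_numpy(dtype=float),
                        schedule, start_clock_h, duration_s)


def repeat_transitions(corners: np.ndarray) -> Tuple[np.ndarray, int]:
    """(is-repeat flags for transitions 1..n-1, number of transitions)."""
    corners = np.asarray(corners)
    if len(corners) < 2:
        return np.empty(0, dtype=bool), 0
    rep = corners[1:] == corners[:-1]
    return rep, len(rep)


def score_repeats(visits: pd.DataFrame, per_animal: bool = True
                  ) -> Optional[float]:
    """Percent of visit transitions that return to the previous corner.

    Transitions are formed per animal across all four corners; the
    denominator is the transition count.  NaN with fewer than 2 visits.
    """
    num = den = 0
    groups = visits.groupby("animal_id", sort=False) if per_animal \
        else [(None, visits)]
    for _, grp in groups:
        g = grp.sort_values("t_entry")
        rep, n = repeat_transitions(g["corner"].to_numpy())
        num += int(rep.sum())
        den += n
    if den == 0:
        return np.nan
    return 100.0 * num / den


def alternation_transitions(
    corners: np.ndarray, t_entry: np.ndarray, t_exit: np.ndarray,
    window_s: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized transition bookkeeping over active-corner visits only.

    Inputs are the active-corner visits of one animal in time order.
    Returns (switched, included, t_entry_of_later_visit) for each of the
    n-1 transitions.
    """
    corners = np.asarray(corners)
    t_entry = np.asarray(t_entry, dtype=float)
    t_exit = np.asarray(t_exit, dtype=float)
    if len(corners) < 2:
        z = np.empty(0)
        return z.astype(bool), z.astype(bool), z
    gaps = t_entry[1:] - t_exit[:-1]
    included = gaps <= window_s
    switched = corners[1:] != corners[:-1]
    return switched, included, t_entry[1:]


def score_alternation(
    annotated_visits: pd.DataFrame,
    config: CageConfig,
    params: AlternationParams = AlternationParams(),
) -> Optional[float]:
    """Percent alternation over an annotated visit table.

    Only visits to the active pair during the alternation/reversal task
    enter; exploratory visits in between are irrelevant.  Transitions
    with a leave-to-enter gap beyond the window are excluded from both
    numerator and denominator (see :class:`AlternationParams` for the
    alternative convention).  NaN when nothing is scoreable.
    """
    num = den = 0
    for _, grp in annotated_visits.groupby("animal_id", sort=False):
        g = grp.sort_values("t_entry")
        mask = g["phase"].isin(TASK_PHASES).to_numpy() & \
            g["corner"].isin(config.active_pair).to_numpy()
        g = g[mask]
        switched, included, _ = alternation_transitions(
            g["corner"].to_numpy(), g["t_entry"].to_numpy(),
            g["t_exit"].to_numpy(), params.window_s)
        num += int((switched & included).sum())
        if params.include_excluded_in_denominator:
            den += len(included)
        else:
            den += int(included.sum())
    if den == 0:
        return np.nan
    return 100.0 * num / den


def _visit_has_poke(visits: pd.DataFrame, pokes: pd.DataFrame) -> np.ndarray:
    """Boolean per visit row: did any nosepoke land inside it (same
    animal and corner)."""
    has = np.zeros(len(visits), dtype=bool)
    if not len(pokes) or not len(visits):
        return has
    for (animal, corner), pk in pokes.groupby(["animal_id", "corner"],
                                              sort=False):
        sel = (visits["animal_id"] == animal) & (visits["corner"] == corner)
        idx = np.nonzero(sel.to_numpy())[0]
        if not len(idx):
            continue
        te = visits["t_entry"].to_numpy()[idx]
        tx = visits["t_exit"].to_numpy()[idx]
        pt = pk["t"].to_numpy()
        for j, (a, b) in enumerate(zip(te, tx)):
            if np.any((pt >= a) & (pt <= b)):
                has[idx[j]] = True
    return has


def score_collected_rewards(annotated_visits: pd.DataFrame,
                            pokes: pd.DataFrame,
                            config: CageConfig) -> Optional[float]:
    """Percent of active-corner task visits containing >= 1 nosepoke."""
    mask = annotated_visits["phase"].isin(TASK_PHASES).to_numpy() & \
        annotated_visits["corner"].isin(config.active_pair).to_numpy()
    active = annotated_visits[mask]
    if not len(active):
        return np.nan
    has = _visit_has_poke(active, pokes)
    return 100.0 * has.sum() / len(active)


MEASURES = ["corner_entries_per_h", "licks_per_h", "repeat_pct",
            "alternation_pct", "collected_rewards_pct"]


def build_score_table(
    annotated_visits: pd.DataFrame,
    licks: pd.DataFrame,
    pokes: pd.DataFrame,
    config: CageConfig,
    schedule: LightSchedule,
    start_clock_h: float,
    duration_s: float,
    session_label: str = "session",
    params: AlternationParams = AlternationParams(),
    pool_cage: bool = False,
) -> pd.DataFrame:
    """Tidy per-(animal, light phase) table of all five measures.

    Transitions (repeats, alternation) are attributed to the light phase
    of the later visit's entry.  With ``pool_cage=True`` all animals are
    pooled into one row pair keyed by the cage id (the reporting unit
    used for camera-based measures).
    """
    exposure = phase_exposure_hours(duration_s, start_clock_h, schedule)
    if pool_cage:
        units = [(config.cage_id, annotated_visits, licks)]
    else:
        ids = sorted(annotated_visits["animal_id"].unique())
        units = [(a, annotated_visits[annotated_visits["animal_id"] == a],
                  licks[licks["animal_id"] == a]) for a in ids]

    rows = []
    for unit_id, av, lk in units:
        entries = score_corner_entries(av, schedule, start_clock_h, duration_s)
        lick_rate = score_licks(lk, schedule, start_clock_h, duration_s)

        rep_num = {LIGHT: 0, DARK: 0}
        rep_den = {LIGHT: 0, DARK: 0}
        alt_num = {LIGHT: 0, DARK: 0}
        alt_den = {LIGHT: 0, DARK: 0}
        cr_num = {LIGHT: 0, DARK: 0}
        cr_den = {LIGHT: 0, DARK: 0}
        for _, grp in av.groupby("animal_id", sort=False):
            g = grp.sort_values("t_entry")
            rep, _ = repeat_transitions(g["corner"].to_numpy())
            if len(rep):
                ph = assign_light_phase(g["t_entry"].to_numpy()[1:],
                                        start_clock_h, schedule)
                for p in (LIGHT, DARK):
                    m = ph == p
                    rep_num[p] += int(rep[m].sum())
                    rep_den[p] += int(m.sum())
            task = g[g["phase"].isin(TASK_PHASES).to_numpy()
                     & g["corner"].isin(config.active_pair).to_numpy()]
            switched, included, t_later = alternation_transitions(
                task["corner"].to_numpy(), task["t_entry"].to_numpy(),
                task["t_exit"].to_numpy(), params.window_s)
            if len(switched):
                ph = assign_light_phase(t_later, start_clock_h, schedule)
                for p in (LIGHT, DARK):
                    m = ph == p
                    alt_num[p] += int((switched & included & m).sum())
                    if params.include_excluded_in_denominator:
                        alt_den[p] += int(m.sum())
                    else:
                        alt_den[p] += int((included & m).sum())
            if len(task):
                has = _visit_has_poke(task, pokes)
                ph = assign_light_phase(task["t_entry"].to_numpy(),
                                        start_clock_h, schedule)
                for p in (LIGHT, DARK):
                    m = ph == p
                    cr_num[p] += int(has[m].sum())
                    cr_den[p] += int(m.sum())

        for p in (LIGHT, DARK):
            rows.append({
                "animal_id": unit_id,
                "session_label": session_label,
                "light_phase": p,
                "exposure_h": exposure[p],
                "corner_entries_per_h": entries[p],
                "licks_per_h": lick_rate[p],
                "repeat_pct": (100.0 * rep_num[p] / rep_den[p]
                               if rep_den[p] else np.nan),
                "alternation_pct": (100.0 * alt_num[p] / alt_den[p]
                                    if alt_den[p] else np.nan),
                "collected_rewards_pct": (100.0 * cr_num[p] / cr_den[p]
                                          if cr_den[p] else np.nan),
            })
    return pd.DataFrame(rows)


__all__ = [
    "AlternationParams", "MEASURES", "TASK_PHASES",
    "score_corner_entries", "score_licks", "score_repeats",
    "score_alternation", "score_collected_rewards", "build_score_table",
    "repeat_transitions", "alternation_transitions",
]
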