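"""Event-stream container, CSV readers/writers, and validation.

Event tables are held as pandas DataFrames with fixed column schemas:

* ``visits``:    animal_id, corner, t_entry, t_exit
* ``nosepokes``: animal_id, corner, side, t
* ``licks``:     animal_id, corner, t, lick_count
* ``frames``:    t, x_cm, y_cm, box_w_cm, box_h_cm  (one row per detection;
  a frame with no detections simply has no rows — corner occupancy makes
  animals invisible to the overhead camera)

Times are seconds from session start.  On disk each table is a headed,
comma-separated UTF-8 file (visits.csv, nosepokes.csv, licks.csv,
frames.csv) in one directory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import CageConfig, LightSchedule, SIDES

VISIT_COLUMNS = ["animal_id", "corner", "t_entry", "t_exit"]
NOSEPOKE_COLUMNS = ["animal_id", "corner", "side", "t"]
LICK_COLUMNS = ["animal_id", "corner", "t", "lick_count"]
FRAME_COLUMNS = ["t", "x_cm", "y_cm", "box_w_cm", "box_h_cm"]

_DTYPES = {
    "animal_id": str, "corner": np.int64, "side": str,
    "t": float, "t_entry": float, "t_exit": float,
    "lick_count": np.int64,
    "x_cm": float, "y_cm": float, "box_w_cm": float, "box_h_cm": float,
}


class StreamValidationError(ValueError):
    """Raised when an event stream violates its invariants."""

    def __init__(self, violations: List[dict]):
        self.violations = violations
        lines = "; ".join(v["message"] for v in violations[:5])
        more = "" if len(violations) <= 5 else f" (+{len(violations) - 5} more)"
        super().__init__(f"{len(violations)} violation(s): {lines}{more}")


def empty_visits() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in VISIT_COLUMNS})


def empty_nosepokes() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in NOSEPOKE_COLUMNS})


def empty_licks() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in LICK_COLUMNS})


def empty_frames() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in FRAME_COLUMNS})


@dataclass
class EventStream:
    """A validated bundle of per-cage behavioral event tables."""

    cage_config: CageConfig
    light_schedule: LightSchedule
    roster: tuple
    visits: pd.DataFrame
    nosepokes: pd.DataFrame = field(default_factory=empty_nosepokes)
    licks: pd.DataFrame = field(default_factory=empty_licks)
    frames: Optional[pd.DataFrame] = None
    session_start_clock_h: float = 7.0
    duration_s: Optional[float] = None

    def copy(self) -> "EventStream":
        return replace(
            self,
            visits=self.visits.copy(),
            nosepokes=self.nosepokes.copy(),
            licks=self.licks.copy(),
            frames=None if self.frames is None else self.frames.copy(),
        )

    @property
    def session_duration_s(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        parts = [0.0]
        if len(self.visits):
            parts.append(float(self.visits["t_exit"].max()))
        if len(self.licks):
            parts.append(float(self.licks["t"].max()))
        return max(parts)


def _check_sorted(df: pd.DataFrame, col: str, table: str, out: List[dict]) -> None:
    t = df[col].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) < 0):
        i = int(np.argmax(np.diff(t) < 0)) + 1
        out.append({"table": table, "row": i, "rule": "time_ordered",
                    "message": f"{table} not time-ordered at row {i}"})


def validate_stream(stream: EventStream) -> List[dict]:
    """Check every stream invariant; violations are returned as data.

    Each violation record carries ``table``, ``row`` (positional index or
    None), ``rule`` and a human-readable ``message``.
    """
    out: List[dict] = []
    cfg = stream.cage_config
    corners = set(cfg.corner_ids)
    roster = set(stream.roster)
    v = stream.visits

    _check_sorted(v, "t_entry", "visits", out)
    _check_sorted(stream.nosepokes, "t", "nosepokes", out)
    _check_sorted(stream.licks, "t", "licks", out)
    if stream.frames is not None:
        _check_sorted(stream.frames, "t", "frames", out)

    for i, row in enumerate(v.itertuples(index=False)):
        if row.t_exit <= row.t_entry:
            out.append({"table": "visits", "row": i, "rule": "exit_after_entry",
                        "message": f"visit row {i}: t_exit <= t_entry"})
        if row.corner not in corners:
            out.append({"table": "visits", "row": i, "rule": "valid_corner",
                        "message": f"visit row {i}: unknown corner {row.corner}"})
        if row.animal_id not in roster:
            out.append({"table": "visits", "row": i, "rule": "roster",
                        "message": f"visit row {i}: animal {row.animal_id} "
                                   "not in roster"})

    # one animal cannot be in two corners at once
    for animal, grp in v.groupby("animal_id", sort=False):
        g = grp.sort_values("t_entry")
        entry = g["t_entry"].to_numpy()
        exit_ = g["t_exit"].to_numpy()
        bad = np.nonzero(entry[1:] < exit_[:-1] - 1e-9)[0]
        for j in bad:
            out.append({"table": "visits", "row": int(g.index[j + 1]),
                        "rule": "no_self_overlap",
                        "message": f"animal {animal} has overlapping visits"})

    # corner chambers admit one mouse at a time
    for corner, grp in v.groupby("corner", sort=False):
        g = grp.sort_values("t_entry")
        entry = g["t_entry"].to_numpy()
        exit_ = g["t_exit"].to_numpy()
        bad = np.nonzero(entry[1:] < exit_[:-1] - 1e-9)[0]
        for j in bad:
            out.append({"table": "visits", "row": int(g.index[j + 1]),
                        "rule": "corner_exclusive",
                        "message": f"corner {corner} co-occupied around "
                                   f"t={entry[j + 1]:.1f}s"})

    # nosepokes and licks must fall inside a visit by the same animal/corner
    def _inside_visit(table: pd.DataFrame, name: str) -> None:
        for i, row in enumerate(table.itertuples(index=False)):
            sub = v[(v["animal_id"] == row.animal_id) & (v["corner"] == row.corner)]
            ok = ((sub["t_entry"] <= row.t) & (row.t <= sub["t_exit"])).any()
            if not ok:
                out.append({"table": name, "row": i, "rule": "inside_visit",
                            "message": f"{name} row {i} (animal {row.animal_id}, "
                                       f"corner {row.corner}, t={row.t:.1f}s) "
                                       "outside any visit"})

    _inside_visit(stream.nosepokes, "nosepokes")
    _inside_visit(stream.licks, "licks")

    for i, row in enumerate(stream.nosepokes.itertuples(index=False)):
        if row.side not in SIDES:
            out.append({"table": "nosepokes", "row": i, "rule": "valid_side",
                        "message": f"nosepoke row {i}: bad side {row.side!r}"})
    for i, row in enumerate(stream.licks.itertuples(index=False)):
        if row.lick_count < 1:
            out.append({"table": "licks", "row": i, "rule": "positive_count",
                        "message": f"lick row {i}: lick_count < 1"})

    if stream.frames is not None and len(stream.frames):
        f = stream.frames
        inb = ((f["x_cm"] >= 0) & (f["x_cm"] <= cfg.cage_width_cm)
               & (f["y_cm"] >= 0) & (f["y_cm"] <= cfg.cage_height_cm))
        for i in np.nonzero(~inb.to_numpy())[0]:
            out.append({"table": "frames", "row": int(i), "rule": "in_bounds",
                        "message": f"frame row {i}: position outside cage"})
    return out


def _read_table(path: str, columns: Sequence[str], required: bool) -> pd.DataFrame:
    if not os.path.exists(path):
        if required:
            raise FileNotFoundError(path)
        return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in columns})
    try:
        df = pd.read_csv(path, dtype={c: _DTYPES[c] for c in columns})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df[list(columns)]


def read_event_stream(
    directory,
    config: CageConfig,
    schedule: LightSchedule,
    roster: Optional[Sequence[str]] = None,
    session_start_clock_h: float = 7.0,
    duration_s: Optional[float] = None,
    validate: bool = True,
) -> EventStream:
    """Load visits/nosepokes/licks(/frames) CSVs from ``directory``.

    If ``roster`` is omitted it is inferred from the animal ids present.
    With ``validate=True`` (default) a :class:`StreamValidationError` is
    raised listing every offending event.
    """
    directory = str(directory)
    visits = _read_table(os.path.join(directory, "visits.csv"),
                         VISIT_COLUMNS, required=True)
    pokes = _read_table(os.path.join(directory, "nosepokes.csv"),
                        NOSEPOKE_COLUMNS, required=False)
    licks = _read_table(os.path.join(directory, "licks.csv"),
                        LICK_COLUMNS, required=False)
    frames_path = os.path.join(directory, "frames.csv")
    frames = (_read_table(frames_path, FRAME_COLUMNS, required=False)
              if os.path.exists(frames_path) else None)
    if roster is None:
        roster = sorted(set(visits["animal_id"]) | set(pokes["animal_id"])
                        | set(licks["animal_id"]))
    stream = EventStream(config, schedule, tuple(roster), visits, pokes,
                         licks, frames, session_start_clock_h, duration_s)
    if validate:
        violations = validate_stream(stream)
        if violations:
            raise StreamValidationError(violations)
    return stream


def write_event_stream(stream: EventStream, directory) -> None:
    """Write the stream's tables as CSVs (lossless float round-trip)."""
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    stream.visits.to_csv(os.path.join(directory, "visits.csv"), index=False)
    stream.nosepokes.to_csv(os.path.join(directory, "nosepokes.csv"), index=False)
    stream.licks.to_csv(os.path.join(directory, "licks.csv"), index=False)
    if stream.frames is not None:
        stream.frames.to_csv(os.path.join(directory, "frames.csv"), index=False)


__all__ = [
    "EventStream", "StreamValidationError", "validate_stream",
    "read_event_stream", "write_event_stream",
    "VISIT_COLUMNS", "NOSEPOKE_COLUMNS", "LICK_COLUMNS", "FRAME_COLUMNS",
    "empty_visits", "empty_nosepokes", "empty_licks", "empty_frames",
]
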