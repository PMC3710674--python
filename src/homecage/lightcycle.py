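"""Light/dark phase assignment and exposure bookkeeping.

Phases are assigned on a half-open convention: the instant of lights-on
belongs to the light phase, the instant of lights-off to the dark phase.
A session is described by the clock time at which it started
(``session_start_clock_h``, hours after midnight) plus event times in
seconds from session start.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .config import DARK, LIGHT, LightSchedule


def assign_light_phase(
    t: Union[float, np.ndarray],
    session_start_clock_h: float,
    schedule: LightSchedule,
) -> Union[str, np.ndarray]:
    """Phase label for time(s) ``t`` seconds after session start.

    Scalar input returns ``"light"`` or ``"dark"``; array input returns
    an object array of labels.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    clock = (session_start_clock_h + t_arr / 3600.0) % 24.0
    since_on = (clock - schedule.lights_on_clock_h) % 24.0
    is_light = since_on < schedule.light_hours
    if np.isscalar(t) or t_arr.ndim == 0:
        return LIGHT if bool(is_light) else DARK
    return np.where(is_light, LIGHT, DARK)


def phase_exposure_hours(
    duration_s: float,
    session_start_clock_h: float,
    schedule: LightSchedule,
) -> dict:
    """Hours of light and dark contained in [0, duration_s).

    Computed by walking the phase boundaries, so sessions of any length
    (including the 30 h sessions whose phases have unequal exposure) are
    handled exactly.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    exposure = {LIGHT: 0.0, DARK: 0.0}
    t = 0.0
    while t < duration_s - 1e-9:
        phase = assign_light_phase(t, session_start_clock_h, schedule)
        clock = (session_start_clock_h + t / 3600.0) % 24.0
        since_on = (clock - schedule.lights_on_clock_h) % 24.0
        if phase == LIGHT:
            remaining_h = schedule.light_hours - since_on
        else:
            remaining_h = 24.0 - since_on
        # guarantee progress when a boundary lands within float epsilon
        t_next = min(duration_s, t + max(remaining_h * 3600.0, 1e-6))
        exposure[phase] += (t_next - t) / 3600.0
        t = t_next
    return exposure


__all__ = ["assign_light_phase", "phase_exposure_hours"]
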