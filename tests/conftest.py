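import numpy as np
import pandas as pd
import pytest

import homecage as hc


@pytest.fixture(scope="session")
def cage():
    return hc.CageConfig()


@pytest.fixture(scope="session")
def schedule():
    return hc.LightSchedule()


@pytest.fixture(scope="session")
def wt_cohort_result():
    """One 30 h alternation session for 11 wild-type-like animals."""
    sim = hc.SimConfig(roster=hc.preset_cohort("WT_like", 11),
                       session_plan=hc.alternation_only_plan(30.0), seed=11)
    return sim, hc.simulate_cohort(sim)


@pytest.fixture(scope="session")
def short_frames_result():
    """A short session with camera frames enabled (3 animals, 1 h)."""
    sim = hc.SimConfig(roster=hc.preset_cohort("WT_like", 3),
                       session_plan=hc.alternation_only_plan(1.0), seed=7,
                       generate_frames=True)
    return sim, hc.simulate_cohort(sim)


def annotated_task_visits(corners, entries, exits, animal="m",
                          phase="alternation"):
    """Hand-build an annotated visit table for scoring tests."""
    return pd.DataFrame({
        "animal_id": animal, "corner": list(corners),
        "t_entry": list(entries), "t_exit": list(exits),
        "phase": phase,
    })


def frames_from_track(xy, fps=30.0, t0=0.0, box=(6.0, 3.0)):
    """Frames table for a single animal following positions ``xy``."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame({
        "t": t0 + np.arange(n) / fps,
        "x_cm": xy[:, 0], "y_cm": xy[:, 1],
        "box_w_cm": box[0], "box_h_cm": box[1],
    })
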