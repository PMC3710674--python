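"""Exhaustive cross-checks of the engine against the literal reference.

The contingency rules and the alternation-window statistic are small
enough that every short visit sequence can be enumerated.  Two factored
families jointly cover the rule dimensions:

* an annotation/reward sweep over all sequences of (corner, first-poke
  side) pairs up to a given length, with short inter-visit gaps — checks
  visit classification, reward granting, and initial-poke efficiency
  scoring against :mod:`homecage.reference`;
* an alternation-window sweep over all corner sequences up to a given
  length crossed with every short/long gap pattern — checks the
  window-excluded percent-alternation bookkeeping (the same array core
  :func:`homecage.scoring.score_alternation` runs on).

Both return the number of cases checked and any mismatches found (an
empty mismatch list is the pass condition).
"""

from __future__ import annotations

from itertools import product
from typing import List, Tuple

import numpy as np

from . import reference
from .config import ALTERNATION, CageConfig, PlanSegment, SessionPlan
from .protocol import NosepokeEvent, VisitEvent, init_protocol, process_visit
from .scoring import alternation_transitions


def annotation_sweep(max_len: int = 5, config: CageConfig | None = None
                     ) -> Tuple[int, List[dict]]:
    """Engine vs reference over all (corner, first-poke side) sequences
    of length 1..max_len with short gaps."""
    config = config or CageConfig()
    plan = SessionPlan((PlanSegment(ALTERNATION, 1000.0),))
    corners = config.corner_ids
    side_map = dict(config.rewarded_side_map)
    other = {"left": "right", "right": "left"}
    options = [(c, ok) for c in corners for ok in (True, False)]
    n_cases = 0
    mismatches: List[dict] = []
    for L in range(1, max_len + 1):
        for seq in product(options, repeat=L):
            n_cases += 1
            state = init_protocol(config, plan, ["m"])["m"]
            eng_ann, eng_rew, eng_ok = [], [], []
            for i, (corner, first_ok) in enumerate(seq):
                t0 = 20.0 * i
                visit = VisitEvent("m", corner, t0, t0 + 10.0)
                rs = side_map.get(corner, "left")
                if first_ok:
                    pokes = [NosepokeEvent("m", corner, rs, t0 + 1.0)]
                else:  # wrong side first, corrected a second later
                    pokes = [NosepokeEvent("m", corner, other[rs], t0 + 1.0),
                             NosepokeEvent("m", corner, rs, t0 + 2.0)]
                _, reward, ann = process_visit(state, visit, pokes, config)
                eng_ann.append(ann.annotation)
                eng_rew.append(reward is not None)
                eng_ok.append(ann.initial_poke_correct)
            ref_ann, ref_rew, ref_ok = reference.annotate_sequence(
                [c for c, _ in seq], [ok for _, ok in seq],
                config.active_pair)
            if (eng_ann, eng_rew, eng_ok) != (ref_ann, ref_rew, ref_ok):
                mismatches.append({"seq": seq, "engine": (eng_ann, eng_rew,
                                                          eng_ok),
                                   "reference": (ref_ann, ref_rew, ref_ok)})
    return n_cases, mismatches


def _engine_alternation(corners, entries, exits, active_pair, window_s):
    """Percent alternation through the package's array core, with the
    same active-corner masking score_alternation applies."""
    corners = np.asarray(corners)
    mask = np.isin(corners, active_pair)
    switched, included, _ = alternation_transitions(
        corners[mask], np.asarray(entries)[mask], np.asarray(exits)[mask],
        window_s)
    den = int(included.sum())
    if den == 0:
        return None
    return 100.0 * int((switched & included).sum()) / den


def alternation_sweep(max_len: int = 6, window_s: float = 113.0,
                      short_gap: float = 5.0, long_gap: float = 200.0,
                      config: CageConfig | None = None
                      ) -> Tuple[int, List[dict]]:
    """Engine vs reference percent alternation over all corner sequences
    of length 1..max_len crossed with every short/long gap pattern."""
    config = config or CageConfig()
    visit_dur = 10.0
    n_cases = 0
    mismatches: List[dict] = []
    for L in range(1, max_len + 1):
        for corners in product(config.corner_ids, repeat=L):
            for gaps in product((short_gap, long_gap), repeat=L - 1):
                n_cases += 1
                entries = [0.0]
                for g in gaps:
                    entries.append(entries[-1] + visit_dur + g)
                exits = [e + visit_dur for e in entries]
                got = _engine_alternation(corners, entries, exits,
                                          config.active_pair, window_s)
                want = reference.percent_alternation(
                    corners, entries, exits, config.active_pair, window_s)
                same = (got is None and want is None) or (
                    got is not None and want is not None
                    and abs(got - want) < 1e-9)
                if not same:
                    mismatches.append({"corners": corners, "gaps": gaps,
                                       "engine": got, "reference": want})
    return n_cases, mismatches


def contingency_oracle_check(max_len_sides: int = 5, max_len_gaps: int = 6
                             ) -> dict:
    """Run both sweeps; returns case counts and mismatch lists."""
    n_a, mm_a = annotation_sweep(max_len_sides)
    n_b, mm_b = alternation_sweep(max_len_gaps)
    return {"annotation_cases": n_a, "annotation_mismatches": mm_a,
            "alternation_cases": n_b, "alternation_mismatches": mm_b,
            "total_cases": n_a + n_b,
            "total_mismatches": len(mm_a) + len(mm_b)}


__all__ = ["annotation_sweep", "alternation_sweep",
           "contingency_oracle_check"]
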