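"""Deliberately literal reference implementation of the contingency and
alternation-scoring rules.

This module re-states the task rules as plainly as possible — one branch
per sentence of the protocol description — and is kept independent of
the optimized engine in :mod:`homecage.protocol` and the array scoring
code in :mod:`homecage.scoring`.  It exists purely as a cross-check: the
test suite and the acceptance script exhaustively compare the engine
against these functions over all short visit sequences.

Do not use this for real data; it is O(n) per event with no batching and
supports only a single animal on a single alternation task.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple


def annotate_sequence(
    corners: Sequence[int],
    first_poke_rewarded: Sequence[Optional[bool]],
    active_pair: Tuple[int, int],
) -> Tuple[List[str], List[bool], List[Optional[bool]]]:
    """Classify a single-animal visit sequence under the alternation task.

    ``first_poke_rewarded[i]`` says whether the first nosepoke of visit i
    was on that corner's rewarded side (None: the animal never poked).
    A wrong-side first poke is assumed to be followed by a correct-side
    poke (no penalty: the first correct-side poke always delivers).

    Returns per-visit (annotation, rewarded, initial_poke_correct).

    Rules, stated literally:
      * An initial visit to either active corner is a correct visit and
        rewarded.
      * After a visit to the correct corner, the corners switch: reward
        is then available only in the other active corner.
      * Repeat visits to the same active corner are incorrect and carry
        no reward.
      * Visits to an exploratory corner never change the correct corner.
      * The only event leading to a switch in the correct corner identity
        is a visit to the currently correct corner.
    """
    annotations: List[str] = []
    rewarded: List[bool] = []
    initial_ok: List[Optional[bool]] = []
    correct_corner: Optional[int] = None  # None: either active corner
    a, b = active_pair
    for corner, poke_ok in zip(corners, first_poke_rewarded):
        if corner not in (a, b):
            annotations.append("exploratory")
            rewarded.append(False)
            initial_ok.append(None)
            continue
        if correct_corner is None or corner == correct_corner:
            annotations.append("correct")
            # any poke eventually reaches the rewarded side -> reward
            rewarded.append(poke_ok is not None)
            initial_ok.append(poke_ok)
            correct_corner = b if corner == a else a
        else:
            annotations.append("incorrect")
            rewarded.append(False)
            initial_ok.append(None)
    return annotations, rewarded, initial_ok


def percent_alternation(
    corners: Sequence[int],
    entries: Sequence[float],
    exits: Sequence[float],
    active_pair: Tuple[int, int],
    window_s: float = 113.0,
    include_excluded_in_denominator: bool = False,
) -> Optional[float]:
    """Percent alternation for a single-animal visit sequence.

    Walks the visits keeping the last active-corner visit; each later
    active-corner visit forms a transition.  Transitions whose gap (entry
    minus the previous active exit) exceeds the window are dropped from
    numerator and denominator (or kept in the denominator when the
    alternative convention is requested).  Exploratory visits in between
    are irrelevant.  Returns None when no transition is scoreable.
    """
    prev: Optional[Tuple[int, float]] = None  # (corner, t_exit)
    num = 0
    den = 0
    for corner, t_in, t_out in zip(corners, entries, exits):
        if corner not in active_pair:
            continue
        if prev is not None:
            gap = t_in - prev[1]
            if gap <= window_s:
                den += 1
                if corner != prev[0]:
                    num += 1
            elif include_excluded_in_denominator:
                den += 1
        prev = (corner, t_out)
    if den == 0:
        return None
    return 100.0 * num / den


def percent_repeats(corners: Sequence[int]) -> Optional[float]:
    """Percent of consecutive-visit transitions returning to the corner
    just visited (all four corners)."""
    if len(corners) < 2:
        return None
    rep = sum(1 for i in range(1, len(corners)) if corners[i] == corners[i - 1])
    return 100.0 * rep / (len(corners) - 1)


__all__ = ["annotate_sequence", "percent_alternation", "percent_repeats"]
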