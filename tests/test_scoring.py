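"""The five behavioral measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import homecage as hc
from homecage.scoring import AlternationParams

from conftest import annotated_task_visits

H = 3600.0


def visits_df(rows):
    return pd.DataFrame(rows, columns=["animal_id", "corner", "t_entry",
                                       "t_exit"])


class TestRates:
    def test_uniform_visits_give_equal_rates(self, schedule):
        v = visits_df([("a", 1, i * H + 10.0, i * H + 20.0)
                       for i in range(24)])
        rates = hc.score_corner_entries(v, schedule,
                                        schedule.lights_on_clock_h, 24 * H)
        assert rates["light"] == pytest.approx(1.0)
        assert rates["dark"] == pytest.approx(1.0)

    def test_all_dark_visits_zero_light_rate(self, schedule):
        v = visits_df([("a", 1, 13 * H, 13 * H + 10)])
        rates = hc.score_corner_entries(v, schedule,
                                        schedule.lights_on_clock_h, 24 * H)
        assert rates["light"] == 0.0
        assert rates["dark"] == pytest.approx(1 / 12)

    def test_30h_session_uses_actual_exposure(self, schedule):
        """30 h from lights-on has 18 light + 12 dark hours; the
        denominators must reflect that (hand-computed bookkeeping)."""
        # 5 entries in light (t=1h..5h), 6 in dark (t=13h..18h)
        rows = [("a", 1, i * H, i * H + 5) for i in range(1, 6)]
        rows += [("a", 2, i * H, i * H + 5) for i in range(13, 19)]
        rates = hc.score_corner_entries(visits_df(rows), schedule,
                                        schedule.lights_on_clock_h, 30 * H)
        assert rates["light"] == pytest.approx(5 / 18.0)
        assert rates["dark"] == pytest.approx(6 / 12.0)

    def test_licks_summed_by_timestamp(self, schedule):
        licks = pd.DataFrame({
            "animal_id": "a", "corner": 1,
            "t": [11.9 * H, 12.1 * H],  # straddles lights-off
            "lick_count": [30, 600],
        })
        rates = hc.score_licks(licks, schedule, schedule.lights_on_clock_h,
                               24 * H)
        assert rates["light"] == pytest.approx(30 / 12.0)
        assert rates["dark"] == pytest.approx(600 / 12.0)

    def test_no_licks_is_zero_not_nan(self, schedule):
        rates = hc.score_licks(pd.DataFrame({"animal_id": [], "corner": [],
                                             "t": [], "lick_count": []}),
                               schedule, 7.0, 24 * H)
        assert rates["light"] == 0.0 and rates["dark"] == 0.0


class TestRepeats:
    @pytest.mark.parametrize("corners, expected", [
        ([1, 2, 3, 4], 0.0),
        ([1, 1, 1], 100.0),
        ([1, 1, 2, 2, 3], 50.0),
    ])
    def test_repeat_fraction(self, corners, expected):
        v = visits_df([("a", c, 10.0 * i, 10.0 * i + 5) for i, c in
                       enumerate(corners)])
        assert hc.score_repeats(v) == pytest.approx(expected)

    def test_single_visit_undefined(self):
        v = visits_df([("a", 1, 0.0, 5.0)])
        assert np.isnan(hc.score_repeats(v))

    def test_transitions_do_not_cross_animals(self):
        v = visits_df([("a", 1, 0.0, 5.0), ("b", 1, 10.0, 15.0),
                       ("a", 2, 20.0, 25.0), ("b", 1, 30.0, 35.0)])
        # a: 1->2 (no repeat); b: 1->1 (repeat) => 50%
        assert hc.score_repeats(v) == pytest.approx(50.0)


class TestAlternation:
    def test_perfect_alternator_is_100(self, cage):
        a1, a2 = cage.active_pair
        av = annotated_task_visits([a1, a2, a1, a2],
                                   [0, 30, 60, 90], [10, 40, 70, 100])
        assert hc.score_alternation(av, cage) == pytest.approx(100.0)

    def test_single_corner_perseverator_is_0(self, cage):
        a1 = cage.active_pair[0]
        av = annotated_task_visits([a1, a1, a1], [0, 30, 60], [10, 40, 70])
        assert hc.score_alternation(av, cage) == pytest.approx(0.0)

    def test_window_exclusion_and_exploratory_irrelevance(self, cage):
        """A1(0-10), E3(15-18), A2(30-40), A2(50-60), A1(200-210):
        included transitions are A1->A2 (switch) and A2->A2 (no switch);
        the 140 s gap excludes A2->A1 entirely => 50%."""
        a1, a2 = cage.active_pair
        e3 = cage.exploratory_pair[0]
        av = annotated_task_visits([a1, e3, a2, a2, a1],
                                   [0, 15, 30, 50, 200],
                                   [10, 18, 40, 60, 210])
        assert hc.score_alternation(av, cage) == pytest.approx(50.0)

    def test_infinite_window_counts_everything(self, cage):
        a1, a2 = cage.active_pair
        e3 = cage.exploratory_pair[0]
        av = annotated_task_visits([a1, e3, a2, a2, a1],
                                   [0, 15, 30, 50, 200],
                                   [10, 18, 40, 60, 210])
        got = hc.score_alternation(av, cage,
                                   AlternationParams(window_s=np.inf))
        assert got == pytest.approx(200.0 / 3.0)

    def test_alternative_denominator_keeps_excluded(self, cage):
        a1, a2 = cage.active_pair
        av = annotated_task_visits([a1, a2, a1], [0, 30, 300],
                                   [10, 40, 310])
        # strict: 1/1 = 100; inclusive: 1/2 = 50
        assert hc.score_alternation(av, cage) == pytest.approx(100.0)
        got = hc.score_alternation(
            av, cage, AlternationParams(include_excluded_in_denominator=True))
        assert got == pytest.approx(50.0)

    def test_habituation_visits_not_scored(self, cage):
        a1, a2 = cage.active_pair
        av = annotated_task_visits([a1, a2, a1, a2], [0, 30, 60, 90],
                                   [10, 40, 70, 100], phase="habituation")
        assert np.isnan(hc.score_alternation(av, cage))

    def test_zero_transitions_undefined(self, cage):
        av = annotated_task_visits([cage.active_pair[0]], [0], [10])
        assert np.isnan(hc.score_alternation(av, cage))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([1, 2]), min_size=2, max_size=20),
       st.integers(0, 3))
def test_exploratory_insertion_invariance(active_seq, n_insert):
    """Splicing quick exploratory visits between active visits never
    changes percent alternation as long as active-to-active gaps stay
    inside the window."""
    cage = hc.CageConfig()
    t = 0.0
    rows = []
    for c in active_seq:
        rows.append((c, t, t + 5.0))
        t += 20.0
    base = annotated_task_visits([r[0] for r in rows],
                                 [r[1] for r in rows],
                                 [r[2] for r in rows])
    with_expl = rows.copy()
    for k in range(n_insert):
        te = 7.0 + 20.0 * k
        with_expl.append((3, te, te + 2.0))
    with_expl.sort(key=lambda r: r[1])
    spliced = annotated_task_visits([r[0] for r in with_expl],
                                    [r[1] for r in with_expl],
                                    [r[2] for r in with_expl])
    b = hc.score_alternation(base, cage)
    s = hc.score_alternation(spliced, cage)
    assert b == pytest.approx(s)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from([1, 2, 3, 4]),
                          st.floats(1.0, 300.0)),
                min_size=1, max_size=15))
def test_included_plus_excluded_equals_total(seq):
    """Window bookkeeping partitions the active-to-active transitions."""
    from homecage.scoring import alternation_transitions
    cage = hc.CageConfig()
    t = 0.0
    corners, entries, exits = [], [], []
    for c, gap in seq:
        corners.append(c)
        entries.append(t)
        exits.append(t + 5.0)
        t += 5.0 + gap
    mask = np.isin(corners, cage.active_pair)
    sw, inc, _ = alternation_transitions(
        np.asarray(corners)[mask], np.asarray(entries)[mask],
        np.asarray(exits)[mask], 113.0)
    n_active = int(mask.sum())
    assert len(inc) == max(0, n_active - 1)
    assert int(inc.sum()) + int((~inc).sum()) == len(inc)


class TestCollectedRewards:
    def _pokes(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "corner", "side", "t"])

    def test_every_active_visit_poked_is_100(self, cage):
        a1, a2 = cage.active_pair
        av = annotated_task_visits([a1, a2], [0, 30], [10, 40])
        pokes = self._pokes([("m", a1, "left", 2.0), ("m", a2, "right", 32.0)])
        assert hc.score_collected_rewards(av, pokes, cage) == 100.0

    def test_three_of_four_is_75(self, cage):
        a1, a2 = cage.active_pair
        av = annotated_task_visits([a1, a2, a1, a2], [0, 30, 60, 90],
                                   [10, 40, 70, 100])
        pokes = self._pokes([("m", a1, "left", 2.0), ("m", a2, "right", 32.0),
                             ("m", a2, "left", 95.0)])
        assert hc.score_collected_rewards(av, pokes, cage) == 75.0

    def test_exploratory_pokes_do_not_count(self, cage):
        a1 = cage.active_pair[0]
        e3 = cage.exploratory_pair[0]
        av = annotated_task_visits([a1, e3], [0, 30], [10, 40])
        pokes = self._pokes([("m", e3, "left", 32.0)])
        assert hc.score_collected_rewards(av, pokes, cage) == 0.0

    def test_no_active_visits_undefined(self, cage):
        e3 = cage.exploratory_pair[0]
        av = annotated_task_visits([e3], [0], [10])
        assert np.isnan(hc.score_collected_rewards(av, self._pokes([]), cage))


class TestScoreTable:
    def test_two_rows_per_animal(self, wt_cohort_result):
        sim, res = wt_cohort_result
        tab = hc.build_score_table(
            res.annotated_visits, res.stream.licks, res.stream.nosepokes,
            sim.cage_config, sim.light_schedule, sim.start_clock_h,
            sim.session_plan.total_duration_s)
        assert len(tab) == 2 * len(sim.roster)
        assert set(tab["light_phase"]) == {"light", "dark"}
        pct_cols = ["repeat_pct", "alternation_pct", "collected_rewards_pct"]
        ok = tab[pct_cols].to_numpy(dtype=float)
        assert np.all((ok >= 0) & (ok <= 100) | np.isnan(ok))

    def test_phase_rates_match_bruteforce_recount(self, wt_cohort_result,
                                                  schedule):
        """Per-phase rates equal a direct recount with exposure hours."""
        sim, res = wt_cohort_result
        tab = hc.build_score_table(
            res.annotated_visits, res.stream.licks, res.stream.nosepokes,
            sim.cage_config, sim.light_schedule, sim.start_clock_h,
            sim.session_plan.total_duration_s)
        animal = res.stream.roster[0]
        v = res.stream.visits[res.stream.visits["animal_id"] == animal]
        exp = hc.phase_exposure_hours(sim.session_plan.total_duration_s,
                                      sim.start_clock_h, sim.light_schedule)
        ph = hc.assign_light_phase(v["t_entry"].to_numpy(),
                                   sim.start_clock_h, sim.light_schedule)
        for phase in ("light", "dark"):
            want = (ph == phase).sum() / exp[phase]
            got = tab[(tab["animal_id"] == animal)
                      & (tab["light_phase"] == phase)]
            assert got["corner_entries_per_h"].iloc[0] == pytest.approx(want)

    def test_demoted_animal_scores_task_phase_only(self, cage, schedule):
        """An animal demoted to habituation mid-session contributes only
        its task-phase visits to alternation."""
        a1, a2 = cage.active_pair
        av = pd.DataFrame({
            "animal_id": "m", "corner": [a1, a2, a1, a1, a2],
            "t_entry": [0.0, 30.0, 60.0, 90.0, 120.0],
            "t_exit": [10.0, 40.0, 70.0, 100.0, 130.0],
            "phase": ["alternation"] * 3 + ["habituation"] * 2,
        })
        got = hc.score_alternation(av, cage)
        assert got == pytest.approx(100.0)  # hab tail (A1->A1!) ignored

    def test_cage_pooling_gives_one_unit(self, wt_cohort_result):
        sim, res = wt_cohort_result
        tab = hc.build_score_table(
            res.annotated_visits, res.stream.licks, res.stream.nosepokes,
            sim.cage_config, sim.light_schedule, sim.start_clock_h,
            sim.session_plan.total_duration_s, pool_cage=True)
        assert len(tab) == 2
        assert set(tab["animal_id"]) == {sim.cage_config.cage_id}
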