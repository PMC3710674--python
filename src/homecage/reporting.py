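"""Group summaries, permutation-based genotype comparisons, and
simulation-based power analysis.

The inference layer is intentionally distribution-free: group contrasts
on per-animal summary scores are tested by label permutation (two-sided,
add-one corrected), and sample-size planning is done by simulating
cohorts at each candidate ``n`` and counting rejections.  A "therapy
effect" of fraction ``f`` moves the affected parameter of the disease
model ``f`` of the way toward the reference (wild-type-like) value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import CageConfig, LightSchedule, SessionPlan, alternation_only_plan
from .scoring import MEASURES, AlternationParams, build_score_table
from .simulate import GenotypeParams, SimConfig, preset_params, simulate_cohort


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class PowerResult:
    measure: str
    effect_fraction: float
    alpha: float
    target_power: float
    n_grid: Tuple[int, ...]
    power: Tuple[float, ...]
    recommended_n: Optional[int]


def summarize(scores: pd.DataFrame, groups: Dict[str, str],
              measures: Sequence[str] = MEASURES) -> pd.DataFrame:
    """Mean/SD/n per (genotype, light phase, session) cell, long format.

    Undefined (NaN) scores are excluded from n and counted as missing.
    """
    unmapped = set(scores["animal_id"]) - set(groups)
    if unmapped:
        raise ValueError(f"unmapped animal(s): {sorted(unmapped)}")
    df = scores.copy()
    df["group"] = df["animal_id"].map(groups)
    rows = []
    for (grp, phase, sess), cell in df.groupby(
            ["group", "light_phase", "session_label"], sort=True):
        for m in measures:
            vals = cell[m].to_numpy(dtype=float)
            ok = vals[~np.isnan(vals)]
            rows.append({
                "group": grp, "light_phase": phase, "session_label": sess,
                "measure": m,
                "mean": float(ok.mean()) if len(ok) else np.nan,
                "sd": float(ok.std(ddof=1)) if len(ok) > 1 else
                      (0.0 if len(ok) == 1 else np.nan),
                "n": int(len(ok)),
                "n_missing": int(np.isnan(vals).sum()),
            })
    return pd.DataFrame(rows)


def _per_animal_means(scores: pd.DataFrame, measure: str,
                      light_phase: Optional[str]) -> pd.Series:
    df = scores if light_phase is None else \
        scores[scores["light_phase"] == light_phase]
    return df.groupby("animal_id")[measure].mean().dropna()


def permutation_compare(
    scores: pd.DataFrame,
    groups: Dict[str, str],
    measure: str,
    n_perm: int = 2000,
    seed: int = 0,
    light_phase: Optional[str] = None,
) -> GroupComparison:
    """Two-sided permutation test of the group difference in per-animal
    mean scores.  p = (r + 1) / (n_perm + 1) where r counts permuted
    |differences| at least as large as observed."""
    vals = _per_animal_means(scores, measure, light_phase)
    labels = pd.Series({a: groups[a] for a in vals.index})
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    ga, gb = names
    x = vals[labels == ga].to_numpy(dtype=float)
    y = vals[labels == gb].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 animals with defined scores")
    obs = float(x.mean() - y.mean())

    pooled = np.concatenate([x, y])
    n_a = len(x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n_a].mean() - perm[n_a:].mean()
        if abs(d) >= abs(obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return GroupComparison(
        measure=measure, group_a=ga, group_b=gb,
        mean_a=float(x.mean()), mean_b=float(y.mean()),
        sd_a=float(x.std(ddof=1)), sd_b=float(y.std(ddof=1)),
        n_a=len(x), n_b=len(y), observed_diff=obs, p_value=p,
        n_permutations=n_perm, seed=seed)


def compare_all_measures(scores: pd.DataFrame, groups: Dict[str, str],
                         n_perm: int = 2000, seed: int = 0
                         ) -> pd.DataFrame:
    """Permutation comparison for every measure; raw p-values per measure
    (no multiplicity correction is applied — report and judge)."""
    rows = []
    for i, m in enumerate(MEASURES):
        try:
            c = permutation_compare(scores, groups, m, n_perm, seed + i)
        except ValueError:
            continue
        rows.append(vars(c) if not hasattr(c, "_asdict") else c._asdict())
    return pd.DataFrame(rows)


#: which generator parameter a therapy on each measure acts through
MEASURE_PARAM = {
    "repeat_pct": "perseveration_bias",
    "alternation_pct": "alternation_competence",
    "corner_entries_per_h": "visit_rate_per_h",
    "licks_per_h": "lick_rate_per_reward",
    "collected_rewards_pct": "nosepoke_prob",
}


def apply_effect(baseline: GenotypeParams, reference: GenotypeParams,
                 measure: str, effect_fraction: float) -> GenotypeParams:
    """Move the measure's driving parameter ``effect_fraction`` of the way
    from the disease value toward the reference value."""
    if measure not in MEASURE_PARAM:
        raise ValueError(f"no parameter mapping for measure {measure!r}")
    param = MEASURE_PARAM[measure]
    b = getattr(baseline, param)
    r = getattr(reference, param)
    return replace(baseline, **{param: b + effect_fraction * (r - b)})


def _scored_cohort(params: GenotypeParams, n: int, prefix: str,
                   plan: SessionPlan, seed: int,
                   cage: CageConfig, sched: LightSchedule) -> pd.DataFrame:
    roster = {f"{prefix}{i:02d}": params for i in range(1, n + 1)}
    sim = SimConfig(roster=roster, cage_config=cage, light_schedule=sched,
                    session_plan=plan, seed=seed)
    res = simulate_cohort(sim)
    return build_score_table(
        res.annotated_visits, res.stream.licks, res.stream.nosepokes,
        cage, sched, res.stream.session_start_clock_h,
        plan.total_duration_s)


def power_by_simulation(
    baseline: GenotypeParams,
    effect_fraction: float,
    measure: str,
    n_grid: Sequence[int],
    alpha: float = 0.05,
    n_reps: int = 50,
    seed: int = 0,
    reference: Optional[GenotypeParams] = None,
    target_power: float = 0.80,
    plan: Optional[SessionPlan] = None,
    n_perm: int = 500,
) -> PowerResult:
    """Monte-Carlo power curve for detecting a partial rescue.

    For each candidate group size the routine simulates paired cohorts —
    untreated disease model vs the same model with its driving parameter
    moved ``effect_fraction`` of the way toward the reference — scores
    them, runs the permutation test, and reports the rejection fraction.
    """
    if not 0.0 <= effect_fraction <= 1.0:
        raise ValueError("effect_fraction must be in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    reference = reference or preset_params("WT_like")
    plan = plan or alternation_only_plan(12.0)
    cage = CageConfig()
    sched = LightSchedule()
    treated = apply_effect(baseline, reference, measure, effect_fraction)

    ss = np.random.SeedSequence(seed)
    powers = []
    for n in n_grid:
        rejections = 0
        for rep in range(n_reps):
            s1, s2, s3 = [int(s) for s in
                          np.random.SeedSequence((seed, n, rep)).generate_state(3) >> 1]
            sc_base = _scored_cohort(baseline, n, "dis", plan, s1, cage, sched)
            sc_treat = _scored_cohort(treated, n, "rx", plan, s2, cage, sched)
            scores = pd.concat([sc_base, sc_treat], ignore_index=True)
            groups = {a: ("disease" if a.startswith("dis") else "treated")
                      for a in scores["animal_id"]}
            try:
                cmp_ = permutation_compare(scores, groups, measure,
                                           n_perm=n_perm, seed=s3)
            except ValueError:  # undefined scores at tiny n
                continue
            if cmp_.p_value <= alpha:
                rejections += 1
        powers.append(rejections / n_reps)
    rec = None
    for n, p in zip(n_grid, powers):
        if p >= target_power:
            rec = int(n)
            break
    return PowerResult(measure, effect_fraction, alpha, target_power,
                       tuple(int(n) for n in n_grid), tuple(powers), rec)


__all__ = [
    "GroupComparison", "PowerResult", "MEASURE_PARAM", "summarize",
    "permutation_compare", "compare_all_measures", "apply_effect",
    "power_by_simulation",
]
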