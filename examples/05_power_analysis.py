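"""Simulation-based power for detecting a partial therapeutic rescue.

Asks: if a therapy closed half the perseveration gap between the
rapid-onset disease model and wild-type-like behavior, how many mice per
group would detect it at alpha = 0.05?  Power rises with group size;
note that two-sided permutation tests cannot reject at all with 3 per
group, so the curve starts near zero there by construction.
"""

import homecage as hc

res = hc.power_by_simulation(
    baseline=hc.preset_params("R6/2_like"),
    effect_fraction=0.5,
    measure="repeat_pct",
    n_grid=[3, 6, 11, 16],
    alpha=0.05,
    n_reps=25,
    seed=5,
    plan=hc.alternation_only_plan(12.0),
    n_perm=499,
)
for n, p in zip(res.n_grid, res.power):
    print(f"n = {n:2d} per group: power = {p:.2f}")
print(f"recommended n for {res.target_power:.0%} power: {res.recommended_n}")
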