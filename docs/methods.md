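# Methods

`homecage` models the data-generating and data-scoring pipeline of an
automated group-housing operant phenotyping system: four instrumented
corner chambers record RFID-identified visits, nosepokes, and licks while
an overhead camera scores activity of the animals in the open arena.
This note documents the behavioral model, the scoring definitions, the
simulator, and the numerical conventions, in that order.

## The reinforcement contingency

Each cage designates two adjacent corners as the **active pair** and the
other two as **exploratory** (never rewarded). Three protocol phases:

* **Habituation** — magazine training. Any corner entry opens both water
  doors for the duration of the visit. No contingency state advances.
* **Alternation** — reward is available only in the currently *correct*
  active corner. At task onset no target is set: the first visit to
  either active corner is correct. A correct visit (a) is annotated
  `correct`, (b) arms the door — the first nosepoke on that corner's
  rewarded side opens it for 8 s — and (c) moves the target to the other
  active corner. Re-entering the same active corner is `incorrect` (no
  reward, no switch); exploratory visits are `exploratory` and never
  move the target. A wrong-side first poke carries no penalty — the
  first correct-side poke still delivers — but is logged as an
  inefficient *initial poke*.
* **Reversal** — identical contingency with the rewarded nosepoke sides
  of the two active corners mirrored.

Two consequences of applying the target switch at visit-classification
time: the reward and the switch are both effects of the correct visit
itself, and a second consecutive entry to the same corner is already
incorrect. Only the first rewarded-side poke per correct visit opens the
door; later pokes in the same visit are inert.

**Non-licker watchdog.** An animal on the task with zero licks over a
trailing window (default 24 h, checked every 24 h of session time) is
electronically switched back to habituation. Demotion is per-animal and
permanent for the remainder of the session plan; other animals in the
cage are unaffected.

**Session plans** are ordered phase segments with durations. A segment's
`side_swap` flag mirrors the rewarded sides relative to the *previous*
segment (the weekly "task reversed at the start of each session"
manipulation), while a `reversal` segment always forces the mirrored
map. A per-segment `active_pair` override is available for the
corner-pair reinterpretation of a contingency reversal; the default
reading is the nosepoke-side swap.

## Scoring definitions

All measures are reported per animal (or pooled per cage) × light phase;
a visit belongs to the phase of its entry time, a transition to the
phase of its *later* visit. Zero-denominator cells are emitted as NaN,
never 0 or 100, so they drop out of group means rather than biasing
them.

* **Corner entries / licks per hour** — counts divided by the actual
  per-phase exposure hours of the session (a 30 h session starting at
  lights-on contains 18 h light and 12 h dark; the denominators follow).
* **Percent repeats** — consecutive-visit transitions (all four corners,
  per animal) that return to the corner just visited, over the
  transition count. Requires ≥ 2 visits.
* **Percent alternation** — over active-corner visits during the task
  phases only: each active→active transition with a leave-to-re-enter
  gap ≤ 113 s counts; the fraction of counted transitions that switch
  corners, × 100. Exploratory visits in between are irrelevant. Gaps
  beyond the window remove the transition from numerator *and*
  denominator, keeping the statistic a proper proportion; the
  alternative convention (excluded transitions stay in the denominator)
  is available via `AlternationParams(include_excluded_in_denominator=True)`.
  The gap is measured from the previous active-corner *exit* to the next
  active-corner *entry*.
* **Percent collected rewards** — active-corner task visits containing
  ≥ 1 nosepoke, over all active-corner task visits.

Repeats are computed across all phases by default (the measure is
introduced during habituation, where all corners are equivalent, but
perseverative returns are meaningful throughout); restricting to one
phase is a caller-side filter on the annotated table.

## Activity endpoints

The upstream video system is proprietary; this package starts from its
natural interface — per-frame anonymous detections (centroid + bounding
box, animals inside corners invisible) — and computes:

* **Locomotion (cm per mouse)** — per consecutive frame pair, matched
  displacement magnitudes (optimal assignment, gated at 8 cm) summed and
  divided by the number of mice detected in that frame.
* **Percent time immobile** — instantaneous speed = displacement ×
  frame rate along tracklets; a frame is immobile when speed is
  *strictly below* 0.7 cm/s. A 1 ns-scale epsilon guards the comparison
  so that a track moving at exactly the cutoff is classified mobile
  despite float roundoff in `distance × rate`.
* **Percent time rearing/climbing** — a detection climbs when its
  centroid lies in a configured climb-zone rectangle; it rears when its
  centroid is within 3 cm of a wall *and* its box is ≥ 1.2× taller than
  wide. Reported jointly. The rearing rule is a declared operational
  stand-in — the field definition ("rearing against the walls") has no
  published geometry.

Tracklets come from frame-to-frame nearest-neighbour assignment
(`scipy.optimize.linear_sum_assignment`), broken at occlusions, gating
failures, and gaps > 5 frame periods. No persistent identity is claimed,
which is why all camera endpoints pool per cage.

## The simulator

`simulate_cohort` generates a full session for a roster of agents, each
parameterised by a `GenotypeParams`:

* **Visit timing** — inhomogeneous Poisson process (thinning), rate
  `visit_rate_per_h` in light × `dark_activity_multiplier` in dark. The
  circadian modulation is a square wave locked to the 12:12 schedule,
  matching the binary light/dark reporting the measures use. Sessions
  start at lights-on by default. The next visit is scheduled from the
  previous visit's exit, so long visits slightly compress realised rates
  in both phases; the dark:light *ratio* is preserved to within a few
  percent at the default parameters.
* **Corner choice** — a mixture: with probability
  `alternation_competence` head to the currently correct corner (task
  phases only; either active corner if no target is set yet), with
  probability `perseveration_bias` return to the previous corner,
  otherwise choose uniformly among the four. During habituation only the
  perseveration and uniform components apply, which gives the closed
  form P(repeat) = b + (1 − b)/4 used in the parameter-recovery tests.
* **Contingency during generation** — every visit is pushed through the
  same `ProtocolDriver` the replay path uses, so ground-truth
  annotations, rewards, and watchdog demotions are logged at generation
  time and replay agreement is exact by construction. Events are
  processed in strict entry-time order (a waiting animal re-enters the
  scheduling heap rather than being handled early) precisely so the
  replay, which sorts by entry time, sees the same chronology.
* **Corner occupancy** — chambers hold one mouse. An arrival at an
  occupied corner waits for it (retrying when it frees) if the wait is
  ≤ 60 s, otherwise redirects uniformly among free corners.
* **Pokes and licks** — an active-corner visit contains a nosepoke with
  probability `nosepoke_prob`; the first poke lands on the rewarded side
  with probability `poke_side_accuracy`, and a wrong first poke is
  usually followed by a corrective poke. Licks occur only inside reward
  windows during the task (Poisson count, mean `lick_rate_per_reward`,
  × `lick_rate_multiplier_dark` in the dark) and freely during
  habituation. A `nonlicker_prob` fraction of animals stop licking from
  a random mid-session onset, which is what the watchdog then detects.
* **Trajectories** (optional, `generate_frames=True`) — between corner
  visits, a two-state (immobile/moving) Markov chain whose stationary
  immobile probability equals `immobile_fraction` exactly, driving a
  correlated random walk at `mean_speed_cm_s` (clipped well above the
  immobility cutoff), reflected off walls, projected out of climb-zone
  rectangles, with Poisson climbing excursions (`climb_rate_per_h`) into
  a random zone. During an excursion the box is tall (climb posture) and
  the agent jitters actively, so excursion frames are mobile. Inside
  corners the animal emits no detections. Visit durations are log-normal
  (median 15 s, σ = 0.5, floor 2 s).

Frame synthesis is off by default: the event-stream analyses do not need
it, and 30 Hz frames for a multi-day cohort are bulky. Tests and
examples that exercise the camera endpoints enable it on short sessions.

One `SeedSequence` per simulation spawns two substreams per animal
(events, trajectory), so outputs are bit-reproducible and editing one
animal's parameters does not perturb the others.

### What the generator does and does not emulate

It reproduces the statistical skeleton the measures assume — circadian
rate modulation, perseverative/alternating choice, reward-gated licking,
one-mouse-per-corner exclusivity, camera blindness inside corners, and
attrition by lick failure. It does not model learning curves (competence
is static), social dynamics, body-posture kinematics beyond the box
aspect, or identity-swap artifacts of real multi-animal tracking.
Passing tests therefore certify the *scoring and inference machinery*
against a known ground truth, not the biological realism of any preset.

## Presets

`WT_like` is the reference. `R6/2_like` (rapid, severe phenotype) raises
perseveration and lick rate, lowers alternation competence, dampens the
circadian multiplier, raises immobility, lowers climbing, and gives each
animal a 10% chance of becoming a non-licker. `BACHD_like` (slow
phenotype) lowers visit rate and speed, raises immobility and
reward-collection efficiency. Only the *sign* of each contrast is
calibrated — no quantitative effect sizes are available to target — so
group comparisons on presets validate detection direction and error
rates, not effect magnitudes.

## Inference and power

Group contrasts use two-sided label-permutation tests on per-animal mean
scores with the add-one correction p = (r + 1)/(n + 1). A mixed-effects
three-way ANOVA workflow is deliberately not re-implemented: the
package's value is the measures and their ground-truthed pipeline, and a
distribution-free test keeps the inference assumptions minimal. Cage is
the honest pooling unit for camera measures (no per-animal identity);
the score table exposes `pool_cage=True` for that.

`power_by_simulation` estimates power for a partial rescue: the measure's
driving parameter (see `MEASURE_PARAM`) is moved `effect_fraction` of
the way from the disease value toward the reference value — the
gap-fraction reading of "a 50% improvement" — and paired cohorts are
simulated, scored, and tested at each candidate group size. Note a
structural floor: with n = 3 per group a two-sided permutation test's
smallest achievable p is ≈ 0.1, so power at α = 0.05 is 0 at n ≤ 3
regardless of effect size; the curve becomes informative from n ≈ 4–5.
Default problem sizes (12 h sessions, 25 replicates, 499 permutations
per test, grid 3–16) keep a full curve to a couple of minutes on one
core while leaving Monte-Carlo error around ±0.1 on each power estimate.

## Numerical conventions and degenerate inputs

* Light phases are half-open: lights-on belongs to light, lights-off to
  dark. Exposure bookkeeping walks phase boundaries exactly, with an
  epsilon step to guarantee progress when a boundary lands within float
  round-off of the current time.
* Visits are attributed to a phase by entry time; a boundary-spanning
  visit is not split.
* CSV round-trips are lossless (pandas writes full-precision floats).
* Validation reports violations as data (`validate_stream`) and the
  reader raises only on parse errors or when asked to validate.
* Empty streams, single-visit animals, zero-exposure phases, and
  all-exploratory sessions produce NaN measures, not exceptions.

## Known limitations

* The engine replays per-animal contingencies independently; cage-level
  competition appears only through the simulator's occupancy queue.
* Percent alternation uses the active pair from the cage configuration;
  per-segment `active_pair` overrides are honored by the engine but the
  scorer assumes one pair per session.
* The anonymous tracker is nearest-neighbour only; crossing animals can
  swap tracklets, mildly inflating mobility. Ground-truth tracks from
  the simulator quantify this in the tests.
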