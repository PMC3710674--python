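"""Replay a full weekly protocol over an event stream.

Uses the first-week timeline — 6 h habituation, 30 h alternation, 6 h
nosepoke-side reversal — simulates a small cohort with one injected
non-licker, replays the stream through the contingency engine, and shows
the annotation breakdown plus the watchdog demotion.  The replay is a
pure function of the stream: the printed counts equal the simulator's
own ground-truth log exactly.
"""

import homecage as hc

plan = hc.rapid_onset_first_week_plan()
sim = hc.SimConfig(roster=hc.preset_cohort("WT_like", 6), session_plan=plan,
                   seed=4)
res = hc.simulate_cohort(sim)

# silence one animal from the start; the 24 h watchdog check will see an
# empty lick window and switch it back to habituation
victim = res.stream.roster[0]
stream = hc.inject_nonlickers(res.stream, [victim], onset_s=0.0)

result = hc.run_session(stream, plan)
print("visit annotations:")
print(result.visits["annotation"].value_counts().to_string())
print(f"\nrewards (8 s door openings): {len(result.rewards)}")
print(f"demotions (non-licker watchdog): {result.demotions}")

trace = result.state_trace
seg = trace[(trace["event"] == "segment_start")
            & (trace["animal_id"] == victim)]
print(f"\nprotocol segments for {victim}: "
      f"{list(zip(seg['t'] / 3600.0, seg['phase']))}")
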