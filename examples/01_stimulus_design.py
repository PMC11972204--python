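"""Build the motion-quartet stimulus schedules and a percept-report stream.

Prints the apparent-motion frequency implied by the frame timing, the block
structure of a physical run, and a sampled percept stream with the pre-scan
switch-rate screening verdict.
"""

from lamiquartet.design import (
    PerceptProcess,
    StimulusTiming,
    build_ambiguous_schedule,
    build_physical_schedule,
    cycle_frequency,
    percept_stream_for_run,
    screen_switch_rate,
)

timing = StimulusTiming()  # 60 Hz display, 9 frames on, 4 frames gap, 2 pairs/cycle
print(f"pair on for {timing.pair_on_ms:.0f} ms, gap {timing.isi_ms:.0f} ms "
      f"-> apparent-motion cycle at {cycle_frequency(timing, ndigits=1)} Hz")

schedule, events = build_physical_schedule()
motion = events[events.trial_type.isin(['horizontal', 'vertical'])]
print(f"physical run: {schedule.total_s:.0f} s = {schedule.n_volumes} volumes at TR {schedule.tr_s} s; "
      f"{len(motion)} motion blocks of {motion.duration.iloc[0]:.0f} s")
# 48 blocks = 6 repetitions x 4 alternations x (horizontal + vertical)

_, amb_events = build_ambiguous_schedule()
percepts = percept_stream_for_run(amb_events, PerceptProcess(), seed=1)
print(f"ambiguous run: {len(percepts)} percept episodes, dwell "
      f"{percepts.duration.min():.1f}-{percepts.duration.max():.1f} s "
      f"(mean {percepts.duration.mean():.1f} s)")
# dwells are truncated-gamma on [3, 20] s; episodes strictly alternate H/V

ok = screen_switch_rate(percepts, window_s=5.0)
print(f"pre-scan screening (switch at least every 5 s): {'pass' if ok else 'fail'}")
# a participant passes only if no percept episode outlasts the 5 s window;
# with the default dwell law (mean ~6.6 s) this simulated observer fails --
# the screening models the behavioral pre-selection, not the scanner session
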