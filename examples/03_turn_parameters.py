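"""Segment the turn of a trial and extract its spatiotemporal parameters.

The turning period is where the pelvis yaw rate exceeds 30 deg/s; the
analysis window runs from the last toe-off before that period to the first
heel strike after it.  Whole-turn parameters (speed, duration, steps,
cadence) and per-leg, per-cycle parameters (stride/step length, signed
stride width, cycle/stance/double-support times) are measured inside the
window, with legs labelled internal/external relative to the turn circle.
"""

from turngait import (GaitScenario, detect_events, detect_turn,
                      generate_trial, turn_parameters)

scenario = GaitScenario(turn_amplitude=90, turn_direction="left",
                        turn_radius=1.5, step_width_offset=0.10)
recording, truth = generate_trial(scenario)

events = detect_events(recording)
segment = detect_turn(recording, events)
print(f"turn: {segment.direction}, measured amplitude "
      f"{segment.amplitude_measured:.1f} deg, internal leg = {segment.internal_side}")
print(f"window: {segment.window_start_time:.2f} s (toe-off) -> "
      f"{segment.window_end_time:.2f} s (heel strike)")

tp = turn_parameters(recording, events, segment)
print(f"whole turn: speed {tp.speed:.2f} m/s, duration {tp.duration:.2f} s, "
      f"{tp.n_steps} steps, cadence {tp.cadence:.1f} steps/min")
for role in ("internal", "external"):
    leg = tp.legs[role]
    if len(leg["stride_length"]) == 0:
        print(f"{role}: no complete cycle in the window")
        continue
    print(f"{role}: stride {leg['stride_length'].mean():.3f} m, "
          f"step {leg['step_length'].mean():.3f} m, "
          f"width {leg['stride_width'].mean():+.3f} m, "
          f"stance/cycle {leg['stance_cycle_ratio'].mean():.1f} %")
# the external leg walks the outer, longer path: its stride is longer than
# the internal leg's, and a negative width would indicate a crossover step.
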