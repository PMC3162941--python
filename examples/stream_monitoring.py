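"""Per-second stream monitoring: a patient deteriorates, alerts fire.

Generates a synthetic 1 Hz scenario (ten seconds unstable, then ten seconds
of low mean pressure), runs the engine over every tick, and prints the
timeline transitions and the emitted alerts. Exactly two alerts appear: one
when monitoring starts in the unstable state, one at the transition to low
pressure; re-entering an already-alerted state within the debounce window
would be suppressed.
"""

from fuzzyvitals import ScenarioSegment, build_engine, generate_stream, process_stream

engine = build_engine()
records = generate_stream(
    [ScenarioSegment(duration=10, state="instability", noise=1.0),
     ScenarioSegment(duration=10, state="low_MBP", noise=1.0)],
    patient_id="demo-254", seed=42,
)

timeline, alerts = process_stream(records, engine)

print("timeline (label changes only):")
previous = None
for entry in timeline:
    if entry.label != previous:
        print(f"  {entry.timestamp.time()}  MBP={entry.mbp:6.1f}  "
              f"SpO2={entry.spo2:5.1f}  score={entry.score:.2f}  -> {entry.label}")
        previous = entry.label

print(f"\n{len(alerts)} alert(s):")
for a in alerts:
    print(f"  [{a.urgency}] {a.timestamp.time()} {a.label}: {a.message}")

print("\nThe patient held 20 ticks; the label changed once, so the alert log")
print("holds the initial unstable alert plus one low-MBP transition alert.")
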