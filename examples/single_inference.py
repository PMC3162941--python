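"""Single-shot pre-diagnosis: fuzzify one (MBP, SpO2) pair and classify it.

Runs the published divergent cases through the default engine and prints the
rule activations, crisp score and situation. The score is the centroid of
the aggregated output set on the [0, 10] pre-diagnosis scale; the label is
the consequent of the strongest rule.
"""

from fuzzyvitals import build_engine

engine = build_engine()

cases = [(33, 94), (126, 87), (123, 87), (117, 94), (98, 94)]
print(f"{'MBP':>5} {'SpO2':>5} {'score':>7}  label        urgency  active rules")
for mbp, spo2 in cases:
    d = engine.infer(mbp, spo2)
    active = ", ".join(f"R{a.rule_id}={a.strength:.3f}"
                       for a in d.activations if a.strength > 0)
    print(f"{mbp:>5} {spo2:>5} {d.score:>7.3f}  {d.label:<12} {str(d.urgency):<8} {active}")

print("\nEach row is one monitor reading: a low mean pressure with normal")
print("saturation scores in the low-MBP band (2.5-4.5); low saturation with")
print("normal pressure lands in the hypoxemia band (4-6); both normal lands")
print("in the stable band (5.5-8) and raises no alert.")
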