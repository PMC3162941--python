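# Patient starts clinically unstable, then settles into low mean pressure.
# Run: monitor simulate --scenario examples/scenarios/deteriorating.yaml \
#        --seed 1 --out stream.csv
# Processing the stream yields the transition instability -> low_MBP and
# exactly two alerts.
patient_id: demo-254
segments:
- duration: 10
  state: instability
  noise: 1.0
  artifact_rate: 0.0
- duration: 10
  state: low_MBP
  noise: 1.0
  artifact_rate: 0.0
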