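# A stably monitored patient: every tick classifies as stable, and because
# the stable situation carries no urgency, the alert log stays empty.
# Explicit channel means may override a state; artifacts inject dropouts
# or out-of-range spikes at the given per-tick probability.
patient_id: demo-055
segments:
- duration: 24
  state: stable
  noise: 0.5
  artifact_rate: 0.02
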