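# Default ICU pre-diagnosis engine configuration.
#
# Membership breakpoints are the specialist-elicited piecewise-linear
# (relevance) functions for mean blood pressure and oxygen saturation;
# output bands on the [0, 10] pre-diagnosis scale carry the five clinical
# situations. Edit with care: rules may only reference terms defined here.
variables:
- name: MBP
  units: mmHg
  domain: [0.0, 200.0]
  sets:
  - name: low
    points: [[0.0, 1.0], [60.0, 1.0], [80.0, 0.0]]
  - name: normal
    points: [[75.0, 0.0], [105.0, 1.0], [130.0, 0.0]]
  - name: high
    points: [[126.0, 0.0], [138.7, 1.0], [200.0, 1.0]]
- name: SpO2
  units: '%'
  domain: [0.0, 100.0]
  sets:
  - name: low
    points: [[0.0, 1.0], [90.0, 1.0], [94.0, 0.0]]
  - name: normal
    points: [[89.2, 0.0], [96.2, 1.0], [100.0, 0.0]]
output:
  name: situation
  units: score
  domain: [0.0, 10.0]
  sets:
  - name: instability
    points: [[0.0, 1.0], [1.25, 1.0], [2.5, 0.0]]
  - name: low_MBP
    points: [[2.5, 0.0], [3.5, 1.0], [4.5, 0.0]]
  - name: hypoxemia
    points: [[4.0, 0.0], [5.0, 1.0], [6.0, 0.0]]
  - name: stable
    points: [[5.5, 0.0], [6.75, 1.0], [8.0, 0.0]]
  - name: high_MBP
    points: [[8.0, 0.0], [8.75, 1.0], [10.0, 1.0]]
rules:
- id: 1
  if: {MBP: low, SpO2: low}
  then: instability
  message: The patient's vital signs are altered
  urgency: high
- id: 2
  if: {MBP: low, SpO2: normal}
  then: low_MBP
  message: The patient's blood pressure is low
  urgency: low
- id: 3
  if: {MBP: normal, SpO2: low}
  then: hypoxemia
  message: Patient with hypoxemia - abnormal deficiency of oxygen concentration
    in arterial blood
  urgency: high
- id: 4
  if: {MBP: normal, SpO2: normal}
  then: stable
  message: No alert
  urgency: none
- id: 5
  if: {MBP: high, SpO2: low}
  then: instability
  message: The patient's vital signs are altered
  urgency: medium
- id: 6
  if: {MBP: high, SpO2: normal}
  then: high_MBP
  message: The patient's blood pressure is high
  urgency: low
monitoring:
  debounce_seconds: 0
  stale_gap_seconds: 30
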