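# Methods

## Model

The engine is a two-input Mamdani fuzzy controller. A crisp pair
(MBP in mmHg, SpO2 in %) is fuzzified through piecewise-linear membership
functions; a six-rule base with AND-joined antecedents is evaluated with
min as the t-norm; each rule's consequent set on the [0, 10] pre-diagnosis
scale is clipped (min) at the rule's activation strength; the clipped sets
are combined by pointwise max; and the aggregate is defuzzified by its
centroid. Centroid is the standard companion of Mamdani max-min composition
and the only defuzzifier used here. The clinical situation label is the
consequent of the maximal-strength rule, with ties broken toward higher
urgency (safety-first) and then lower rule id. Band lookup of the crisp
score is deliberately *not* used for labelling because the bands overlap
(4.5 > 4 and 6 > 5.5); the score is reported alongside the label for
trending.

The engine is memoryless: every tick is classified independently. All
monitoring state (transitions, debounce, staleness) lives in the streaming
layer.

### Membership functions

The input breakpoints are the specialist-elicited values and are encoded
verbatim in `src/fuzzyvitals/data/default_config.yaml`. Evaluation is
linear between breakpoints, constant beyond the first/last breakpoint (so
plateau endpoints behave as trapezoid shoulders), and exact at breakpoints
— no epsilon nudging. Inputs outside the variable domain (sensor spikes)
are clamped to the domain edge with a warning.

### Output sets

Only the five band intervals and their names are prescribed; the shapes are
this package's choice: symmetric triangles supported exactly on the three
interior bands (low_MBP on [2.5, 4.5] peaking at 3.5; hypoxemia on [4, 6]
peaking at 5; stable on [5.5, 8] peaking at 6.75) and shoulder trapezoids
at the scale edges (instability (0,1),(1.25,1),(2.5,0); high_MBP
(8,0),(8.75,1),(10,1), mirroring the instability plateau fraction). Support
equal to the printed band guarantees *single-rule confinement*: when one
rule fires alone, the centroid of its clipped set lies inside that
situation's band, which is what makes the worked-example scores land where
the bands say they should.

### Degenerate point at SpO2 = 100 %

The elicited normal-saturation set falls to zero exactly at 100 %, and the
low set is zero above 94 %, so at a reading of exactly 100 % every
saturation term — hence every rule — has strength zero. Readings of 100 %
are routine, so `FuzzyEngine.infer` resolves this single point by a
one-sided limit: the value is stepped one float ulp toward the domain
interior until some term is positive. The result classifies 100 % as
(barely) normal saturation, consistent with the clinical normal band of
95–100 %. Raw `fuzzify` output at 100 % still reports the exact elicited
zeros; only full inference takes the limit.

### Exact geometry

Clipping and aggregation are done symbolically on piecewise-linear vertex
lists: clip inserts the crossings with the strength level, and the max
envelope is built from all vertices plus pairwise segment intersections, so
between consecutive candidates the maximum is a single linear piece. The
centroid is then the exact per-segment moment sum
(`dx (x0 (2 y0 + y1) + x1 (y0 + 2 y1)) / 6`), not a grid quadrature. Tests
cross-check it against 10,000-point trapezoidal integration (tolerance
1e-6) and the whole pipeline against an independent dense-grid numeric
Mamdani implementation (labels equal; scores within 0.05 on 1,000 random
inputs).

## Streaming and alerts

Records arrive at 1 Hz per patient as timestamped channel maps. MBP is read
from `ABP_mean` when present, otherwise estimated from systolic/diastolic
as (SBP + 2·DBP)/3 — the textbook mean-arterial-pressure approximation, a
package choice flagged per-tick via `mbp_derived`. An alert is emitted when
the label changes to one whose urgency is not `none`; the first tick counts
as a transition from no label. `debounce_seconds` (default 0) is a
per-label refractory window: a repeat alert for a label alerted within the
window is suppressed. (A minimum-dwell interpretation was rejected because
it silences a patient who oscillates in and out of a dangerous state; the
refractory reading caps alarm rate without ever missing the first event.)
Ticks with no usable inputs are kept in the timeline as stale
carry-forwards of the last label — so the timeline has one entry per record
and the count of non-stale entries equals the count of usable records — and
a gap of `stale_gap_seconds` (default 30 s) raises one medium-priority
sensor-fault notice until signal returns.

## Synthetic data

The generator emulates the *structure* of multiparameter ICU recordings:
per-second records with pressure channels (mean, systolic, diastolic,
internally consistent with a 40 mmHg pulse pressure), SpO2, and inert
adult-normal HR/RR/temperature channels. Each scenario segment holds one
situation, whose characteristic (MBP, SpO2) means sit at the membership
cores — instability (55, 85), low_MBP (60, 97), hypoxemia (105, 85),
stable (105, 97), high_MBP (150, 97) — with Gaussian per-channel noise and
Bernoulli artifacts (dropouts or out-of-range spikes). There is no
autoregressive physiology, circadian structure, or waveform content, and
channels are independent given the segment mean; passing tests therefore
demonstrate the pipeline's correctness on the engine's input geometry, not
robustness to real monitor dynamics or artefact morphology.

Labelled datasets for the surrogate draw a class per row from the requested
mix, sample (MBP, SpO2) as Gaussians around that class's means (default
spreads 5 mmHg and 1.5 %), and store the fuzzy engine's own verdict as the
label, so datasets are label-consistent by construction. All generation is
driven by `numpy.random.default_rng(seed)`; identical inputs give
byte-identical outputs.

## Surrogate classifier

A one-hidden-layer feed-forward network (scikit-learn `MLPClassifier`,
logistic hidden activation, default 15 hidden units) is trained on
engine-labelled samples with inputs min-max scaled by the variable domains
(deterministic scaling, not data-dependent). L-BFGS is used as the
optimizer: the contract is agreement with the fuzzy labels on this small,
piecewise-linearly separable 2-D problem, and on such problems the choice
of a standard first-order/quasi-Newton optimizer does not change the
outcome, while L-BFGS is deterministic given the seed. An 80/20 stratified
split is used and recorded in the report metadata. The evaluation report
carries the 5×5 confusion matrix (rows: fuzzy label; columns: predicted),
per-class precision/recall, and overall agreement; at 5,000 samples the
held-out agreement is ≥ 95 % (typically ≈ 99.8 %), with residual errors on
fuzzy cell boundaries.

## Problem sizes and tolerances

Default suites use: 10,000 random points per set for interpolation checks
(1e-9), 1,000 random input pairs for the independent-reference comparison
(scores within 0.05), a 101×51 input sweep for score bounds, 0.01-step
per-variable scans for coverage, and 5,000 samples for surrogate training.
These sizes make the full suite run in seconds while keeping every check
statistically comfortable.

## Known limitations

- Two-input model only; heart rate, respiratory rate and temperature are
  carried as passive channels but never influence the verdict.
- The ambiguous published borderline cases (36, 92) and (40, 92) activate
  both the instability rule (0.5) and the low-pressure rule (0.4); this
  engine resolves them to instability by maximal strength. They are
  documented, not used as reference labels.
- Alert transport (SMS, e-mail, mobile push) is out of scope; a JSON Lines
  log stands in as the delivery boundary.
- No reader for WFDB-format numeric records is included; streams enter as
  long- or wide-form CSV.
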