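"""Train the feed-forward surrogate on fuzzy-labelled synthetic samples.

Draws 5,000 (MBP, SpO2) pairs around the five situations' characteristic
regions, labels them with the fuzzy engine, fits a 15-hidden-unit sigmoidal
network on an 80/20 stratified split, and prints the held-out agreement and
confusion matrix. Agreement is the fraction of held-out samples where the
network reproduces the rule-based engine's verdict.
"""

from fuzzyvitals import (
    build_engine,
    evaluate,
    generate_labelled_dataset,
    train_surrogate,
    train_test_split_stratified,
)

engine = build_engine()
data = generate_labelled_dataset(5000, seed=7, engine=engine)
train, test = train_test_split_stratified(data, test_fraction=0.2, seed=7)
model = train_surrogate(train, hidden_units=15, seed=7)
report = evaluate(model, test)

print(report)
print("\nRows are the fuzzy engine's labels, columns the network's")
print("predictions; off-diagonal counts are boundary samples where the")
print("network's smooth decision surface crosses a fuzzy cell edge.")
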