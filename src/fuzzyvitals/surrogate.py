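"""Feed-forward surrogate of the fuzzy engine's five-situation classification.

The fuzzy engine partitions the (MBP, SpO2) plane into five piecewise-linear
decision cells. A small one-hidden-layer network with sigmoidal activations
trained on engine-labelled samples learns those cells; its held-out agreement
with the fuzzy labels measures how faithfully the surrogate reproduces the
rule-based pre-diagnosis. Inputs are min-max scaled to [0, 1] using the
variable domains, not the sample, so scaling is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.neural_network import MLPClassifier

__all__ = ["LABELS", "SurrogateModel", "ClassifierReport", "train_surrogate", "evaluate"]

LABELS: tuple[str, ...] = ("instability", "low_MBP", "hypoxemia", "stable", "high_MBP")

# (lo, hi) per input column, matching the engine's variable domains
_DOMAINS = {"MBP": (0.0, 200.0), "SpO2": (0.0, 100.0)}


@dataclass(frozen=True)
class ClassifierReport:
    """Evaluation summary of a surrogate against the fuzzy labels."""

    labels: tuple[str, ...]
    confusion: np.ndarray  # rows: true fuzzy label, columns: predicted
    agreement: float
    precision: dict[str, float]
    recall: dict[str, float]
    hidden_units: int
    seed: int
    n_train: int
    n_test: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.labels),
                            columns=list(self.labels))

    def __str__(self) -> str:
        lines = [
            f"surrogate: {self.hidden_units} hidden units, seed {self.seed}, "
            f"train/test {self.n_train}/{self.n_test}",
            f"held-out agreement with fuzzy labels: {self.agreement:.4f}",
            "confusion matrix (rows = fuzzy label, cols = predicted):",
            self.to_frame().to_string(),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class SurrogateModel:
    mlp: MLPClassifier
    hidden_units: int
    seed: int
    n_train: int

    def predict(self, dataset: pd.DataFrame) -> np.ndarray:
        return self.mlp.predict(_scale(dataset))


def _scale(dataset: pd.DataFrame) -> np.ndarray:
    cols = []
    for name in ("MBP", "SpO2"):
        lo, hi = _DOMAINS[name]
        cols.append((dataset[name].to_numpy(dtype=float) - lo) / (hi - lo))
    return np.column_stack(cols)


def train_surrogate(dataset: pd.DataFrame, hidden_units: int = 15,
                    seed: int = 0, max_iter: int = 3000) -> SurrogateModel:
    """Fit the one-hidden-layer sigmoidal network on fuzzy-labelled samples.

    ``dataset`` needs columns MBP, SpO2 and label (all five situations
    present). Deterministic given the seed.
    """
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    labels = dataset["label"].unique()
    if len(labels) < 2:
        raise ValueError("training data must contain more than one class")
    mlp = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=int(seed),
    )
    mlp.fit(_scale(dataset), dataset["label"].to_numpy())
    return SurrogateModel(mlp=mlp, hidden_units=hidden_units,
                          seed=int(seed), n_train=len(dataset))


def evaluate(model: SurrogateModel, test: pd.DataFrame) -> ClassifierReport:
    """Score a surrogate on a held-out split; rows of the matrix conserve counts."""
    if len(test) == 0:
        raise ValueError("test split is empty")
    y_true = test["label"].to_numpy()
    y_pred = model.predict(test)
    present = [lab for lab in LABELS if lab in set(y_true) | set(y_pred)]
    cm = confusion_matrix(y_true, y_pred, labels=present)
    prec, rec, _, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, zero_division=0.0
    )
    return ClassifierReport(
        labels=tuple(present),
        confusion=cm,
        agreement=float((y_true == y_pred).mean()),
        precision={lab: float(p) for lab, p in zip(present, prec)},
        recall={lab: float(r) for lab, r in zip(present, rec)},
        hidden_units=model.hidden_units,
        seed=model.seed,
        n_train=model.n_train,
        n_test=len(test),
    )
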