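"""Mamdani inference: rule firing, max-min aggregation, centroid defuzzification.

The engine evaluates an AND-of-antecedents rule base with ``min`` as the
t-norm, clips each consequent set at its rule's activation strength, combines
the clipped sets by pointwise ``max``, and defuzzifies the aggregate by its
centroid on the [0, 10] pre-diagnosis scale. All geometry is piecewise
linear, so the aggregate envelope and its centroid are computed exactly
(closed form), not on a grid.

The clinical situation label is taken from the maximal-strength rule (the
printed score bands overlap, so locating the crisp score in a band would be
ambiguous); ties break toward higher urgency, then lower rule id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

from .membership import FuzzySet, LinguisticVariable

__all__ = [
    "Urgency",
    "Rule",
    "RuleActivation",
    "PreDiagnosis",
    "FuzzyEngine",
    "DegenerateOutputError",
    "ConfigError",
]


class ConfigError(ValueError):
    """A rule or variable reference that the engine registry cannot resolve."""


class DegenerateOutputError(ValueError):
    """Aggregated output has zero area; no centroid exists."""


class Urgency(IntEnum):
    """Alert priority ladder; comparison order is clinical severity."""

    none = 0
    low = 1
    medium = 2
    high = 3

    def __str__(self) -> str:  # serialize as the bare name
        return self.name


@dataclass(frozen=True)
class Rule:
    """One fuzzy rule: AND-joined (variable, term) antecedents -> output term."""

    id: int
    antecedents: tuple[tuple[str, str], ...]
    consequent: str
    message: str
    urgency: Urgency

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "antecedents", tuple((str(v), str(t)) for v, t in self.antecedents)
        )
        object.__setattr__(self, "urgency", Urgency[str(self.urgency)]
                           if not isinstance(self.urgency, Urgency) else self.urgency)


@dataclass(frozen=True)
class RuleActivation:
    rule_id: int
    strength: float


@dataclass(frozen=True)
class PreDiagnosis:
    """Per-evaluation engine output: activations, crisp score, situation."""

    mbp: float
    spo2: float
    activations: tuple[RuleActivation, ...]
    score: float
    label: str
    urgency: Urgency
    message: str


# ---------------------------------------------------------------------------
# Piecewise-linear envelope geometry.
#
# A function is a list of (x, y) vertices over a fixed closed interval, linear
# between consecutive vertices, with the first/last x at the interval edges.

def _clip(points: tuple[tuple[float, float], ...], h: float,
          lo: float, hi: float) -> list[tuple[float, float]]:
    """min(f, h) over [lo, hi] with constant extension beyond the breakpoints."""
    # materialise f on [lo, hi] with explicit edge vertices
    verts: list[tuple[float, float]] = []
    first_x, first_y = points[0]
    last_x, last_y = points[-1]
    if lo < first_x:
        verts.append((lo, first_y))
    for x, y in points:
        if lo <= x <= hi:
            verts.append((x, y))
    if hi > last_x:
        verts.append((hi, last_y))
    if verts[0][0] > lo:
        verts.insert(0, (lo, _interp(points, lo)))
    if verts[-1][0] < hi:
        verts.append((hi, _interp(points, hi)))
    # insert crossings with the horizontal line y = h, then clip
    out: list[tuple[float, float]] = []
    for (x0, y0), (x1, y1) in zip(verts, verts[1:]):
        out.append((x0, min(y0, h)))
        if (y0 - h) * (y1 - h) < 0:  # strict sign change -> interior crossing
            xc = x0 + (x1 - x0) * (h - y0) / (y1 - y0)
            out.append((xc, h))
    out.append((verts[-1][0], min(verts[-1][1], h)))
    return _dedupe(out)


def _interp(points: tuple[tuple[float, float], ...], x: float) -> float:
    if x <= points[0][0]:
        return points[0][1]
    if x >= points[-1][0]:
        return points[-1][1]
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        if x0 <= x <= x1:
            return y0 if x == x0 else (y1 if x == x1 else y0 + (y1 - y0) * (x - x0) / (x1 - x0))
    raise AssertionError("unreachable")


def _dedupe(verts: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out = [verts[0]]
    for x, y in verts[1:]:
        if abs(x - out[-1][0]) > 1e-12:
            out.append((x, y))
        else:
            out[-1] = (out[-1][0], max(out[-1][1], y))
    return out


def _envelope(funcs: list[list[tuple[float, float]]]) -> list[tuple[float, float]]:
    """Exact pointwise max of piecewise-linear functions on a shared interval.

    Candidate vertices are every input vertex plus every pairwise segment
    intersection; between consecutive candidates the max is attained by a
    single linear piece, so evaluating the max at the candidates gives the
    exact upper envelope.
    """
    xs: set[float] = set()
    for f in funcs:
        xs.update(x for x, _ in f)
    segs = [
        (s0, s1)
        for f in funcs
        for s0, s1 in zip(f, f[1:])
    ]
    for i, (a0, a1) in enumerate(segs):
        for b0, b1 in segs[i + 1:]:
            x = _segment_crossing(a0, a1, b0, b1)
            if x is not None:
                xs.add(x)
    grid = sorted(xs)
    verts = [(x, max(_interp_list(f, x) for f in funcs)) for x in grid]
    return verts


def _interp_list(f: list[tuple[float, float]], x: float) -> float:
    return _interp(tuple(f), x)


def _segment_crossing(a0, a1, b0, b1) -> float | None:
    """x where two linear segments cross inside their overlapping span."""
    lo = max(a0[0], b0[0])
    hi = min(a1[0], b1[0])
    if lo >= hi:
        return None
    sa = (a1[1] - a0[1]) / (a1[0] - a0[0])
    sb = (b1[1] - b0[1]) / (b1[0] - b0[0])
    if sa == sb:
        return None
    # y_a(x) = a0.y + sa (x - a0.x); solve y_a = y_b
    x = (b0[1] - a0[1] + sa * a0[0] - sb * b0[0]) / (sa - sb)
    return x if lo < x < hi else None


def _centroid(verts: list[tuple[float, float]]) -> tuple[float, float]:
    """(centroid, area) of a piecewise-linear function, exact per segment.

    For a linear piece y(x) on [x0, x1]:
      area   = (y0 + y1) dx / 2
      moment = dx (x0 (2 y0 + y1) + x1 (y0 + 2 y1)) / 6
    """
    area = 0.0
    moment = 0.0
    for (x0, y0), (x1, y1) in zip(verts, verts[1:]):
        dx = x1 - x0
        area += (y0 + y1) * dx / 2.0
        moment += dx * (x0 * (2.0 * y0 + y1) + x1 * (y0 + 2.0 * y1)) / 6.0
    if area <= 0.0:
        raise DegenerateOutputError("aggregated output set has zero area")
    return moment / area, area


# ---------------------------------------------------------------------------


class FuzzyEngine:
    """Two-input Mamdani controller for ICU pre-diagnosis.

    Parameters
    ----------
    variables
        Input linguistic variables, keyed lookups by name (mean blood
        pressure and oxygen saturation in the shipped configuration).
    output
        Output linguistic variable on the [0, 10] pre-diagnosis scale; its
        sets are the situation bands (instability, low_MBP, hypoxemia,
        stable, high_MBP).
    rules
        The rule base; the shipped base has six rules covering every
        combination of pressure term x saturation term.
    """

    def __init__(self, variables: list[LinguisticVariable],
                 output: LinguisticVariable, rules: list[Rule]):
        self.variables = {v.name: v for v in variables}
        self.output = output
        self.rules = tuple(sorted(rules, key=lambda r: r.id))
        self._validate()

    def _validate(self) -> None:
        for rule in self.rules:
            for var, term in rule.antecedents:
                if var not in self.variables:
                    raise ConfigError(f"rule {rule.id}: unknown variable {var!r}")
                if term not in self.variables[var].term_names:
                    raise ConfigError(
                        f"rule {rule.id}: variable {var!r} has no term {term!r}"
                    )
            if rule.consequent not in self.output.term_names:
                raise ConfigError(
                    f"rule {rule.id}: unknown output term {rule.consequent!r}"
                )

    # -- pipeline stages ----------------------------------------------------

    def fuzzify(self, inputs: dict[str, float]) -> dict[str, dict[str, float]]:
        out = {}
        for name, value in inputs.items():
            if name not in self.variables:
                raise ConfigError(f"unknown input variable {name!r}")
            out[name] = self.variables[name].fuzzify(value)
        return out

    def fire_rules(self, fuzzified: dict[str, dict[str, float]]) -> tuple[RuleActivation, ...]:
        """Activation strength of every rule: min over its antecedent degrees."""
        acts = []
        for rule in self.rules:
            degrees = []
            for var, term in rule.antecedents:
                if var not in fuzzified:
                    raise ConfigError(f"rule {rule.id}: no fuzzified input for {var!r}")
                degrees.append(fuzzified[var][term])
            acts.append(RuleActivation(rule.id, min(degrees)))
        return tuple(acts)

    def aggregate(self, activations: tuple[RuleActivation, ...]) -> list[tuple[float, float]]:
        """Pointwise max of consequent sets clipped at their rule strengths."""
        lo, hi = self.output.domain
        by_id = {r.id: r for r in self.rules}
        clipped = []
        for act in activations:
            if act.strength <= 0.0:
                continue
            cons = self.output.get_set(by_id[act.rule_id].consequent)
            clipped.append(_clip(cons.points, act.strength, lo, hi))
        if not clipped:
            raise DegenerateOutputError("no rule fired with positive strength")
        return _envelope(clipped)

    def defuzzify_centroid(self, aggregated: list[tuple[float, float]]) -> float:
        """Area-weighted mean abscissa of the aggregated membership function."""
        score, _ = _centroid(aggregated)
        lo, hi = self.output.domain
        return min(max(score, lo), hi)

    def classify(self, activations: tuple[RuleActivation, ...]) -> Rule:
        """Winning rule: maximal strength, ties to higher urgency then lower id."""
        by_id = {r.id: r for r in self.rules}
        positive = [a for a in activations if a.strength > 0.0]
        if not positive:
            raise DegenerateOutputError("no rule fired with positive strength")
        best = max(
            positive,
            key=lambda a: (a.strength, by_id[a.rule_id].urgency, -a.rule_id),
        )
        return by_id[best.rule_id]

    def _degrees_with_limit(self, name: str, value: float) -> dict[str, float]:
        """Fuzzified degrees, taking the one-sided limit at a coverage gap.

        The shipped saturation sets all vanish at exactly 100% (the normal
        set's printed falling edge ends at (100, 0)), which would leave the
        rule base silent for a perfectly saturated reading. A value where
        every term is zero is therefore evaluated in the limit from inside
        the domain, which classifies 100% as (barely) normal saturation —
        consistent with the clinical normal band of 95-100%.
        """
        var = self.variables[name]
        degrees = var.fuzzify(value)
        if max(degrees.values()) > 0.0:
            return degrees
        lo, hi = var.domain
        x = var.clamp(value)
        toward = (lo + hi) / 2.0
        for _ in range(64):
            x = math.nextafter(x, toward)
            degrees = var.fuzzify(x)
            if max(degrees.values()) > 0.0:
                return degrees
        raise DegenerateOutputError(
            f"variable {name!r}: no term has positive membership near {value!r}"
        )

    def infer(self, mbp: float, spo2: float) -> PreDiagnosis:
        """Full pipeline: fuzzify -> fire -> aggregate -> centroid -> classify."""
        if not (math.isfinite(mbp) and math.isfinite(spo2)):
            raise ValueError("inference requires finite MBP and SpO2")
        fuzzified = {
            "MBP": self._degrees_with_limit("MBP", mbp),
            "SpO2": self._degrees_with_limit("SpO2", spo2),
        }
        activations = self.fire_rules(fuzzified)
        aggregated = self.aggregate(activations)
        score = self.defuzzify_centroid(aggregated)
        winner = self.classify(activations)
        return PreDiagnosis(
            mbp=float(mbp),
            spo2=float(spo2),
            activations=activations,
            score=score,
            label=winner.consequent,
            urgency=winner.urgency,
            message=winner.message,
        )
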