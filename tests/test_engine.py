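"""Mamdani rule firing, aggregation, centroid defuzzification, classification."""

from __future__ import annotations

import numpy as np
import pytest

from fuzzyvitals import (
    DegenerateOutputError,
    ConfigError,
    FuzzyEngine,
    Rule,
    RuleActivation,
    Urgency,
    build_engine,
)

from _oracle import oracle_infer


def _strengths(engine, mbp, spo2):
    acts = engine.fire_rules(engine.fuzzify({"MBP": mbp, "SpO2": spo2}))
    return {a.rule_id: a.strength for a in acts}


class TestFireRules:
    def test_low_pressure_normal_saturation_fires_only_rule_2(self, engine):
        s = _strengths(engine, 33.0, 94.0)
        assert s[2] == pytest.approx(4.8 / 7.0, abs=1e-12)
        assert all(s[i] == 0.0 for i in (1, 3, 4, 5, 6))

    def test_normal_pressure_low_saturation_fires_only_rule_3(self, engine):
        s = _strengths(engine, 126.0, 87.0)
        assert s[3] == pytest.approx(0.16, abs=1e-12)
        assert all(s[i] == 0.0 for i in (1, 2, 4, 5, 6))

    def test_both_inputs_at_peaks_fire_rule_4_fully(self, engine):
        s = _strengths(engine, 105.0, 96.2)
        assert s[4] == 1.0
        assert all(s[i] == 0.0 for i in (1, 2, 3, 5, 6))

    def test_every_rule_reports_one_activation(self, engine):
        acts = engine.fire_rules(engine.fuzzify({"MBP": 100.0, "SpO2": 95.0}))
        assert [a.rule_id for a in acts] == [1, 2, 3, 4, 5, 6]

    def test_missing_variable_is_config_error(self, engine):
        with pytest.raises(ConfigError):
            engine.fire_rules({"MBP": {"low": 1.0, "normal": 0.0, "high": 0.0}})

    def test_rule_base_covers_all_term_combinations(self, engine):
        combos = {tuple(sorted(r.antecedents)) for r in engine.rules}
        expected = {
            tuple(sorted((("MBP", m), ("SpO2", s))))
            for m in ("low", "normal", "high")
            for s in ("low", "normal")
        }
        assert combos == expected


def _grid_eval(verts, xs):
    vx = [v[0] for v in verts]
    vy = [v[1] for v in verts]
    return np.interp(xs, vx, vy)


class TestAggregate:
    def test_single_activation_is_clipped_consequent(self, engine):
        acts = (RuleActivation(4, 0.52),)
        verts = engine.aggregate(acts)
        xs = np.linspace(0.0, 10.0, 5001)
        stable = engine.output.get_set("stable")
        expected = np.minimum(np.interp(xs, stable.xs, stable.mus), 0.52)
        assert np.max(np.abs(_grid_eval(verts, xs) - expected)) < 1e-9

    def test_zero_strength_contributes_nothing(self, engine):
        with_zero = engine.aggregate((RuleActivation(3, 0.16), RuleActivation(1, 0.0)))
        without = engine.aggregate((RuleActivation(3, 0.16),))
        xs = np.linspace(0.0, 10.0, 5001)
        assert np.allclose(_grid_eval(with_zero, xs), _grid_eval(without, xs), atol=1e-12)

    def test_two_activations_match_dense_grid_max(self, engine):
        verts = engine.aggregate((RuleActivation(1, 0.5), RuleActivation(2, 0.4)))
        xs = np.linspace(0.0, 10.0, 20001)
        inst = engine.output.get_set("instability")
        low = engine.output.get_set("low_MBP")
        expected = np.maximum(
            np.minimum(np.interp(xs, inst.xs, inst.mus), 0.5),
            np.minimum(np.interp(xs, low.xs, low.mus), 0.4),
        )
        assert np.max(np.abs(_grid_eval(verts, xs) - expected)) < 1e-9

    def test_all_zero_activations_degenerate(self, engine):
        with pytest.raises(DegenerateOutputError):
            engine.aggregate(tuple(RuleActivation(i, 0.0) for i in range(1, 7)))


class TestCentroid:
    @pytest.mark.parametrize("height", [0.1, 0.5, 1.0])
    def test_clipped_symmetric_triangle_centroid_on_axis(self, engine, height):
        """Clipping a symmetric triangle never moves its centroid off-axis."""
        verts = engine.aggregate((RuleActivation(3, height),))
        assert engine.defuzzify_centroid(verts) == pytest.approx(5.0, abs=1e-12)

    def test_single_rule_score_stays_in_band(self, engine):
        verts = engine.aggregate((RuleActivation(4, 0.52),))
        assert 5.5 <= engine.defuzzify_centroid(verts) <= 8.0

    def test_closed_form_matches_numeric_integration(self, engine):
        """Exact centroid vs 10,000-point trapezoidal integration, 1e-6."""
        rng = np.random.default_rng(7)
        xs = np.linspace(0.0, 10.0, 10_000)
        for _ in range(50):
            strengths = rng.uniform(0.0, 1.0, size=6)
            strengths[rng.random(6) < 0.5] = 0.0
            if strengths.max() == 0.0:
                strengths[rng.integers(6)] = rng.uniform(0.1, 1.0)
            acts = tuple(RuleActivation(i + 1, s) for i, s in enumerate(strengths))
            verts = engine.aggregate(acts)
            ys = _grid_eval(verts, xs)
            numeric = np.trapezoid(ys * xs, xs) / np.trapezoid(ys, xs)
            assert engine.defuzzify_centroid(verts) == pytest.approx(numeric, abs=1e-6)


class TestClassify:
    @pytest.mark.parametrize(
        "mbp,spo2,label",
        [
            (33.0, 94.0, "low_MBP"),
            (126.0, 87.0, "hypoxemia"),
            (123.0, 87.0, "hypoxemia"),
            (117.0, 94.0, "stable"),
            (98.0, 94.0, "stable"),
        ],
    )
    def test_reference_cases_reproduce_labels(self, engine, mbp, spo2, label):
        assert engine.infer(mbp, spo2).label == label

    def test_stable_situation_has_no_urgency(self, engine):
        diag = engine.infer(98.0, 94.0)
        assert diag.urgency == Urgency.none
        assert diag.message == "No alert"

    def test_hypoxemia_is_high_priority(self, engine):
        diag = engine.infer(126.0, 87.0)
        assert diag.urgency == Urgency.high
        assert "hypoxemia" in diag.message

    def test_tie_breaks_toward_higher_urgency(self, engine):
        """Equal activations resolve to the clinically severer rule."""
        acts = (RuleActivation(2, 0.4), RuleActivation(1, 0.4))
        winner = engine.classify(acts)
        assert winner.id == 1  # instability (high) beats low_MBP (low)

    def test_ambiguous_borderline_cases_fire_two_rules(self, engine):
        """(36, 92) and (40, 92) activate both the instability and low-pressure
        rules at 0.5 / 0.4; the engine resolves by maximal strength. These
        inputs are documented as genuinely ambiguous and carry no reference
        label here."""
        for mbp in (36.0, 40.0):
            s = _strengths(engine, mbp, 92.0)
            assert s[1] == pytest.approx(0.5, abs=1e-12)
            assert s[2] == pytest.approx(0.4, abs=1e-12)


class TestInfer:
    def test_deterministic(self, engine):
        a = engine.infer(101.3, 93.7)
        b = engine.infer(101.3, 93.7)
        assert a == b

    def test_single_rule_score_confined_to_band(self, engine):
        assert 2.5 <= engine.infer(33.0, 94.0).score <= 4.5

    def test_non_finite_inputs_rejected(self, engine):
        with pytest.raises(ValueError):
            engine.infer(float("nan"), 95.0)

    def test_score_bounds_and_coverage_on_grid(self, engine):
        """Some rule always fires and the score stays within [0, 10]."""
        for mbp in np.linspace(0.0, 200.0, 81):
            for spo2 in np.linspace(0.0, 100.0, 41):
                diag = engine.infer(float(mbp), float(spo2))
                assert max(a.strength for a in diag.activations) > 0.0
                assert 0.0 <= diag.score <= 10.0

    def test_agrees_with_independent_numeric_reference(self, engine):
        """Labels match and scores agree within 0.05 against a dense-grid
        numeric Mamdani implementation on 1,000 random in-domain inputs."""
        rng = np.random.default_rng(2026)
        for _ in range(1000):
            mbp = float(rng.uniform(0.0, 200.0))
            spo2 = float(rng.uniform(0.0, 100.0))
            diag = engine.infer(mbp, spo2)
            ref_label, ref_score = oracle_infer(mbp, spo2)
            assert diag.label == ref_label, (mbp, spo2)
            assert diag.score == pytest.approx(ref_score, abs=0.05)


def test_dangling_rule_reference_rejected(engine):
    bad = Rule(id=7, antecedents=(("MBP", "very_high"),), consequent="stable",
               message="x", urgency=Urgency.low)
    with pytest.raises(ConfigError):
        FuzzyEngine(list(engine.variables.values()), engine.output,
                    list(engine.rules) + [bad])
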