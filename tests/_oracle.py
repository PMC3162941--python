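"""Independent numeric Mamdani reference used to cross-check the engine.

Everything here is brute-force and grid-based on purpose: fuzzification via
``np.interp``, aggregation as a pointwise max over a dense output grid, and
centroid by trapezoidal numeric integration. It shares no geometry code with
the package's exact piecewise-linear implementation.
"""

from __future__ import annotations

import numpy as np

# printed membership breakpoints
MBP_SETS = {
    "low": ([0.0, 60.0, 80.0], [1.0, 1.0, 0.0]),
    "normal": ([75.0, 105.0, 130.0], [0.0, 1.0, 0.0]),
    "high": ([126.0, 138.7, 200.0], [0.0, 1.0, 1.0]),
}
SPO2_SETS = {
    "low": ([0.0, 90.0, 94.0], [1.0, 1.0, 0.0]),
    "normal": ([89.2, 96.2, 100.0], [0.0, 1.0, 0.0]),
}
OUTPUT_SETS = {
    "instability": ([0.0, 1.25, 2.5], [1.0, 1.0, 0.0]),
    "low_MBP": ([2.5, 3.5, 4.5], [0.0, 1.0, 0.0]),
    "hypoxemia": ([4.0, 5.0, 6.0], [0.0, 1.0, 0.0]),
    "stable": ([5.5, 6.75, 8.0], [0.0, 1.0, 0.0]),
    "high_MBP": ([8.0, 8.75, 10.0], [0.0, 1.0, 1.0]),
}
# (id, mbp term, spo2 term, consequent, urgency rank)
RULES = [
    (1, "low", "low", "instability", 3),
    (2, "low", "normal", "low_MBP", 1),
    (3, "normal", "low", "hypoxemia", 3),
    (4, "normal", "normal", "stable", 0),
    (5, "high", "low", "instability", 2),
    (6, "high", "normal", "high_MBP", 1),
]

_GRID = np.linspace(0.0, 10.0, 100_001)


def oracle_infer(mbp: float, spo2: float) -> tuple[str, float]:
    """(label, centroid score) by dense-grid numeric Mamdani inference."""
    mbp = float(np.clip(mbp, 0.0, 200.0))
    spo2 = float(np.clip(spo2, 0.0, 100.0))
    mbp_deg = {t: float(np.interp(mbp, xs, mus)) for t, (xs, mus) in MBP_SETS.items()}
    spo2_deg = {t: float(np.interp(spo2, xs, mus)) for t, (xs, mus) in SPO2_SETS.items()}

    strengths = {rid: min(mbp_deg[mt], spo2_deg[st]) for rid, mt, st, _, _ in RULES}
    agg = np.zeros_like(_GRID)
    for rid, _, _, cons, _ in RULES:
        if strengths[rid] > 0.0:
            xs, mus = OUTPUT_SETS[cons]
            agg = np.maximum(agg, np.minimum(np.interp(_GRID, xs, mus), strengths[rid]))
    area = np.trapezoid(agg, _GRID)
    score = float(np.trapezoid(agg * _GRID, _GRID) / area)

    # winner: max strength, ties to higher urgency then lower rule id
    best = max(RULES, key=lambda r: (strengths[r[0]], r[4], -r[0]))
    return best[3], score
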