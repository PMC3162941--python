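"""Piecewise-linear fuzzy sets and fuzzification of crisp vital-sign values.

A :class:`FuzzySet` is a named membership function given by an ordered list of
``(x, mu)`` breakpoints; between breakpoints membership is linear, and beyond
the first/last breakpoint it is held constant, so trapezoids written as
``(0, 1), (60, 1), (80, 0)`` behave as intended over the whole domain.
A :class:`LinguisticVariable` bundles the sets that partition one measured
quantity (e.g. mean blood pressure in mmHg) together with its domain bounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FuzzySet", "LinguisticVariable"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FuzzySet:
    """A named piecewise-linear membership function.

    Parameters
    ----------
    name
        Linguistic term, e.g. ``"low"``, ``"normal"``, ``"high"``.
    points
        Breakpoints ``(x, mu)`` with strictly increasing ``x`` and
        ``mu`` in [0, 1]; at least two points.
    """

    name: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(mu)) for x, mu in self.points)
        if len(pts) < 2:
            raise ValueError(f"fuzzy set {self.name!r} needs at least 2 points")
        xs = [p[0] for p in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError(
                f"fuzzy set {self.name!r}: breakpoint x values must be strictly increasing"
            )
        if any(not (0.0 <= mu <= 1.0) for _, mu in pts):
            raise ValueError(f"fuzzy set {self.name!r}: membership degrees must lie in [0, 1]")
        object.__setattr__(self, "points", pts)

    @property
    def xs(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)

    @property
    def mus(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.points)

    def membership(self, x: float) -> float:
        """Membership degree at ``x``.

        Linear interpolation between the bracketing breakpoints; constant
        extension outside the breakpoint range. A value exactly at a
        breakpoint returns that breakpoint's ``mu``.
        """
        if not math.isfinite(x):
            raise ValueError(f"membership evaluation requires a finite value, got {x!r}")
        pts = self.points
        if x <= pts[0][0]:
            return pts[0][1]
        if x >= pts[-1][0]:
            return pts[-1][1]
        for (x0, m0), (x1, m1) in zip(pts, pts[1:]):
            if x0 <= x <= x1:
                if x == x0:
                    return m0
                if x == x1:
                    return m1
                return m0 + (m1 - m0) * (x - x0) / (x1 - x0)
        raise AssertionError("unreachable: breakpoints cover the bracketed range")

    def __call__(self, x: float) -> float:
        return self.membership(x)


@dataclass(frozen=True)
class LinguisticVariable:
    """A measured quantity with its domain and the fuzzy sets defined on it."""

    name: str
    units: str
    domain: tuple[float, float]
    sets: tuple[FuzzySet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lo, hi = float(self.domain[0]), float(self.domain[1])
        if not (lo < hi):
            raise ValueError(f"variable {self.name!r}: domain must satisfy lo < hi")
        object.__setattr__(self, "domain", (lo, hi))
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError(f"variable {self.name!r}: duplicate set names {names}")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)

    def get_set(self, term: str) -> FuzzySet:
        for s in self.sets:
            if s.name == term:
                return s
        raise KeyError(f"variable {self.name!r} has no term {term!r}")

    def clamp(self, x: float) -> float:
        """Clamp ``x`` into the variable domain, warning when it is outside.

        Out-of-range monitor readings (sensor spikes, cuff artefacts) are
        clinically meaningless beyond "very low" / "very high", so they are
        pinned to the domain edge rather than rejected.
        """
        if not math.isfinite(x):
            raise ValueError(f"variable {self.name!r}: input must be finite, got {x!r}")
        lo, hi = self.domain
        if x < lo or x > hi:
            clamped = min(max(x, lo), hi)
            logger.warning(
                "%s=%g %s outside domain [%g, %g]; clamped to %g",
                self.name, x, self.units, lo, hi, clamped,
            )
            return clamped
        return x

    def fuzzify(self, x: float) -> dict[str, float]:
        """Map a crisp value to a ``term -> degree`` dict (one entry per set)."""
        xc = self.clamp(x)
        return {s.name: s.membership(xc) for s in self.sets}

    def coverage_gaps(self, step: float = 0.01) -> np.ndarray:
        """Grid points where no set has positive membership (should be empty)."""
        lo, hi = self.domain
        grid = np.arange(lo, hi + step / 2, step)
        max_mu = np.zeros_like(grid)
        for s in self.sets:
            max_mu = np.maximum(max_mu, np.interp(grid, s.xs, s.mus))
        return grid[max_mu <= 0.0]
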