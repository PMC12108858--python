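"""Positive ω-periodic coefficient functions and their period extrema.

Every rate in the model is a continuous, bounded, positive ω-periodic
function of time.  All criteria (permanence bounds, stability margins) are
built from the period supremum ``φ^m = sup φ(t)`` and infimum
``φ^l = inf φ(t)`` of each coefficient, so those two numbers are the
fundamental quantities this module computes.

Coefficients are stored structurally — a constant term plus a list of
sine/cosine terms — so that for the single-term affine form
``c0 + c1·trig(wt)`` the extrema are exact: ``(c0 + |c1|, c0 − |c1|)``.
A general callable with a declared period is supported as an escape hatch;
its extrema are found by a dense grid scan with local refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["TrigTerm", "PeriodicCoefficient", "common_period", "PeriodError"]

#: grid density for the numeric extrema fallback (points per period)
GRID_POINTS = 100_001

TWO_PI = 2.0 * math.pi


class PeriodError(ValueError):
    """Raised when coefficients declare incompatible periods."""


@dataclass(frozen=True)
class TrigTerm:
    """One sinusoidal term ``amplitude · trig(angular_frequency · t)``."""

    kind: str  # "sin" or "cos"
    amplitude: float
    angular_frequency: float

    def __post_init__(self) -> None:
        if self.kind not in ("sin", "cos"):
            raise ValueError(f"trig kind must be 'sin' or 'cos', got {self.kind!r}")
        if self.angular_frequency <= 0:
            raise ValueError("angular_frequency must be positive")

    @property
    def period(self) -> float:
        return TWO_PI / self.angular_frequency

    def __call__(self, t: float) -> float:
        f = math.sin if self.kind == "sin" else math.cos
        return self.amplitude * f(self.angular_frequency * t)


@dataclass(frozen=True)
class PeriodicCoefficient:
    """A positive ω-periodic scalar coefficient ``φ(t)``.

    Parameters
    ----------
    constant_term:
        The mean level ``c0``.
    trig_terms:
        Zero or more :class:`TrigTerm` added to the constant.
    period:
        Declared period ω.  If omitted it is inferred from the trig terms
        (constants are compatible with any period).
    general_callable:
        Escape hatch: an arbitrary ``t -> scalar`` with declared ``period``;
        when given it replaces the structural form entirely.
    """

    constant_term: float = 0.0
    trig_terms: tuple[TrigTerm, ...] = ()
    period: float | None = None
    general_callable: Callable[[float], float] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "trig_terms", tuple(self.trig_terms))
        if self.general_callable is not None and self.period is None:
            raise ValueError("a general callable must declare its period")

    # -- evaluation ------------------------------------------------------

    def __call__(self, t: float) -> float:
        return self.evaluate(t)

    def evaluate(self, t: float) -> float:
        if self.general_callable is not None:
            return float(self.general_callable(t))
        return self.constant_term + sum(term(t) for term in self.trig_terms)

    def evaluate_array(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.general_callable is not None:
            return np.array([float(self.general_callable(ti)) for ti in np.atleast_1d(t)]).reshape(t.shape)
        out = np.full(t.shape, self.constant_term, dtype=float)
        for term in self.trig_terms:
            f = np.sin if term.kind == "sin" else np.cos
            out += term.amplitude * f(term.angular_frequency * t)
        return out

    # -- period ----------------------------------------------------------

    @property
    def declared_period(self) -> float | None:
        """The period ω this coefficient declares (None for pure constants)."""
        if self.period is not None:
            return self.period
        if not self.trig_terms:
            return None  # a constant is every-period
        periods = [term.period for term in self.trig_terms]
        return _lcm_periods(periods)

    @property
    def is_constant(self) -> bool:
        return self.general_callable is None and not self.trig_terms

    # -- extrema ---------------------------------------------------------

    def extrema(self) -> tuple[float, float]:
        """Return ``(φ^m, φ^l)``, the period supremum and infimum.

        Exact for the zero- and single-trig-term forms; otherwise a dense
        grid scan over one period with local refinement around the grid
        optima.
        """
        if self.general_callable is None:
            if not self.trig_terms:
                return self.constant_term, self.constant_term
            if len(self.trig_terms) == 1:
                a = abs(self.trig_terms[0].amplitude)
                return self.constant_term + a, self.constant_term - a
        return self._extrema_numeric()

    def _extrema_numeric(self) -> tuple[float, float]:
        omega = self.declared_period
        if omega is None:  # constant via callable is impossible; trig sum w/o period neither
            return self.constant_term, self.constant_term
        tgrid = np.linspace(0.0, omega, GRID_POINTS)
        vals = self.evaluate_array(tgrid)
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficient is non-finite on its period")
        sup = _refine(self, tgrid, vals, omega, maximize=True)
        inf = _refine(self, tgrid, vals, omega, maximize=False)
        return sup, inf

    @property
    def sup(self) -> float:
        return self.extrema()[0]

    @property
    def inf(self) -> float:
        return self.extrema()[1]

    @property
    def is_positive(self) -> bool:
        """Whether ``φ^l > 0`` (the model requires this of every coefficient)."""
        return self.inf > 0.0


def _refine(
    coef: PeriodicCoefficient,
    tgrid: np.ndarray,
    vals: np.ndarray,
    omega: float,
    maximize: bool,
) -> float:
    """Polish a grid optimum with a bounded scalar search on its bracket."""
    idx = int(np.argmax(vals) if maximize else np.argmin(vals))
    lo = tgrid[max(idx - 1, 0)]
    hi = tgrid[min(idx + 1, len(tgrid) - 1)]
    sign = -1.0 if maximize else 1.0
    if hi > lo:
        res = minimize_scalar(
            lambda t: sign * coef.evaluate(t), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12 * max(omega, 1.0)},
        )
        best = sign * res.fun
    else:  # degenerate bracket
        best = vals[idx]
    grid_best = vals[idx]
    return max(best, grid_best) if maximize else min(best, grid_best)


def _lcm_periods(periods: Sequence[float], rtol: float = 1e-9) -> float:
    """Smallest common period of commensurate individual periods."""
    base = max(periods)
    for k in range(1, 1001):
        cand = k * base
        if all(_divides(p, cand, rtol) for p in periods):
            return cand
    raise PeriodError(f"could not find a common period for {periods}")


def _divides(p: float, omega: float, rtol: float = 1e-9) -> bool:
    ratio = omega / p
    return abs(ratio - round(ratio)) <= rtol * max(1.0, ratio) and round(ratio) >= 1


def common_period(
    coefs: Iterable[PeriodicCoefficient], default: float = 1.0
) -> float:
    """Shared period ω of a collection of coefficients.

    All declared periods must equal the returned ω or be integer divisors
    of it.  A collection of pure constants accepts any period and yields
    ``default``.
    """
    declared = [
        c.declared_period for c in coefs if c.declared_period is not None
    ]
    if not declared:
        return default
    omega = max(declared)
    for p in declared:
        if not _divides(p, omega):
            raise PeriodError(
                f"incompatible coefficient periods: {p} does not divide {omega}"
            )
    return omega
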