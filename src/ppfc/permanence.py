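"""Closed-form permanence (uniform persistence) bounds and criteria H1–H10.

For the degenerate delay-ODE system the theory yields explicit constants
built from coefficient extrema: ultimate upper bounds ``M1, M2`` for the
prey, ``N1..N4`` for the control variables, lower bounds ``m1, m2`` and
``n1..n4``, and threshold bounds ``M3*, M4*, m3*, m4*`` for the predators.
When the ten sign conditions H1–H10 all hold, every solution from positive
history is eventually trapped in the box ``[m_i, M_i] × [n_i, N_i]``.

The free predator bounds ``M3, M4, m3, m4`` must satisfy the ordering
``0 < m_i ≤ m_i* ≤ M_i* ≤ M_i``; by default they are taken equal to the
starred thresholds (an optional ``slack`` widens them multiplicatively for
strict inequality).

All formulas are evaluated with the sup/inf of each coefficient written
``φ^m`` / ``φ^l`` in the docstrings below.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import exp

from .model import ModelParameters

__all__ = [
    "PermanenceBounds",
    "CriterionValue",
    "prey_upper_bounds",
    "control_upper_bounds",
    "control_lower_bounds",
    "predator_upper_thresholds",
    "prey_lower_bounds",
    "predator_lower_thresholds",
    "compute_bounds",
    "evaluate_H1_H10",
]


@dataclass(frozen=True)
class CriterionValue:
    """One sign criterion: satisfied iff its expression value is > 0."""

    name: str
    value: float | None
    description: str = ""

    @property
    def satisfied(self) -> bool:
        return self.value is not None and self.value > 0.0


@dataclass(frozen=True)
class PermanenceBounds:
    """The permanence constants; fields are ``None`` when undefined
    (i.e. when a prerequisite sign condition fails)."""

    M1: float
    M2: float
    N1: float
    N2: float
    N3: float
    N4: float
    M3_star: float | None = None
    M4_star: float | None = None
    m1: float | None = None
    m2: float | None = None
    n1: float | None = None
    n2: float | None = None
    n3: float | None = None
    n4: float | None = None
    m3_star: float | None = None
    m4_star: float | None = None
    # the chosen free bounds (default: the starred thresholds themselves)
    M3: float | None = None
    M4: float | None = None
    m3: float | None = None
    m4: float | None = None
    slack: float = 0.0

    @property
    def complete(self) -> bool:
        return all(
            getattr(self, f) is not None
            for f in ("m1", "m2", "m3", "m4", "M3", "M4", "n1", "n2", "n3", "n4")
        )

    def v_bounds(self, i: int) -> tuple[float | None, float | None]:
        """(lower, upper) permanence bounds for species ``v_i`` (1-based)."""
        return getattr(self, f"m{i}"), getattr(self, f"M{i}")

    def u_bounds(self, i: int) -> tuple[float | None, float | None]:
        """(lower, upper) permanence bounds for control ``u_i`` (1-based)."""
        return getattr(self, f"n{i}"), getattr(self, f"N{i}")


# ---------------------------------------------------------------------------
# individual bound formulas


def prey_upper_bounds(params: ModelParameters) -> tuple[float, float]:
    """``M1 = (r1^m/a11^l)·exp(r1^m τ11)`` and analogously ``M2``."""
    d = params.delays
    M1 = params.sup("r1") / params.inf("a11") * exp(params.sup("r1") * d.tau11)
    M2 = params.sup("r2") / params.inf("a22") * exp(params.sup("r2") * d.tau22)
    return M1, M2


def control_upper_bounds(
    params: ModelParameters, M1: float, M2: float
) -> tuple[float, float, float, float]:
    """``N1 = (e1^m + q1^m M1)/f1^l``, ``N2`` analogous, ``N3 = e3^m/f3^l``,
    ``N4 = e4^m/f4^l``."""
    N1 = (params.sup("e1") + params.sup("q1") * M1) / params.inf("f1")
    N2 = (params.sup("e2") + params.sup("q2") * M2) / params.inf("f2")
    N3 = params.sup("e3") / params.inf("f3")
    N4 = params.sup("e4") / params.inf("f4")
    return N1, N2, N3, N4


def control_lower_bounds(
    params: ModelParameters, m1: float, m2: float, M3: float, M4: float
) -> tuple[float, float, float, float]:
    """``n1 = (e1^l + q1^l m1)/f1^m`` … ``n4 = (e4^l − q4^m M4)/f4^m``.

    ``n3`` and ``n4`` may be negative when the control drain ``q^m M``
    exceeds the replenishment ``e^l``; this is reported, not raised.
    """
    n1 = (params.inf("e1") + params.inf("q1") * m1) / params.sup("f1")
    n2 = (params.inf("e2") + params.inf("q2") * m2) / params.sup("f2")
    n3 = (params.inf("e3") - params.sup("q3") * M3) / params.sup("f3")
    n4 = (params.inf("e4") - params.sup("q4") * M4) / params.sup("f4")
    return n1, n2, n3, n4


def predator_upper_thresholds(
    params: ModelParameters, M1: float, N3: float, N4: float
) -> tuple[float | None, float | None, float, float, float, float]:
    """Predator upper thresholds and the H1–H4 expression values.

    ``M3* = M1(a31^m − r3^l + a32^m + k3^m N3) / (b13^l (r3^l − a32^m − k3^m N3))``
    and analogously ``M4*``.  Returns ``(M3*, M4*, h1, h2, h3, h4)``;
    the thresholds are ``None`` when the corresponding denominator
    criterion (h1 resp. h2) is non-positive.
    """
    h1 = params.inf("r3") - params.sup("a32") - params.sup("k3") * N3
    h2 = params.inf("r4") - params.sup("a42") - params.sup("k4") * N4
    h3 = params.sup("a31") - params.inf("r3") + params.sup("a32") + params.sup("k3") * N3
    h4 = params.sup("a41") - params.inf("r4") + params.sup("a42") + params.sup("k4") * N4
    M3_star = M1 * h3 / (params.inf("b13") * h1) if h1 > 0 else None
    M4_star = M1 * h4 / (params.inf("b14") * h2) if h2 > 0 else None
    return M3_star, M4_star, h1, h2, h3, h4


def prey_lower_bounds(
    params: ModelParameters, M1: float, M2: float, N1: float, N2: float
) -> tuple[float | None, float | None, float, float]:
    """Prey lower bounds ``m1, m2`` and the H5/H6 expression values.

    ``G5 = (r1^l − a12^m M2 − k1^m N1) b13^l b14^l − a13^m b14^l − a14^m b13^l``;
    ``m1 = G5/(b13^l b14^l a11^m) · exp[(G5/(b13^l b14^l) − a11^m M1) τ11]``;
    ``m2`` analogous with the prey-2 coefficients and ``G6``.
    """
    d = params.delays
    b13l, b14l = params.inf("b13"), params.inf("b14")
    b23l, b24l = params.inf("b23"), params.inf("b24")
    g5 = (
        (params.inf("r1") - params.sup("a12") * M2 - params.sup("k1") * N1)
        * b13l * b14l
        - params.sup("a13") * b14l
        - params.sup("a14") * b13l
    )
    g6 = (
        (params.inf("r2") - params.sup("a21") * M1 - params.sup("k2") * N2)
        * b23l * b24l
        - params.sup("a23") * b24l
        - params.sup("a24") * b23l
    )
    m1 = m2 = None
    if g5 > 0:
        a11m = params.sup("a11")
        m1 = g5 / (b13l * b14l * a11m) * exp(
            (g5 / (b13l * b14l) - a11m * M1) * d.tau11
        )
    if g6 > 0:
        a22m = params.sup("a22")
        m2 = g6 / (b23l * b24l * a22m) * exp(
            (g6 / (b23l * b24l) - a22m * M2) * d.tau22
        )
    return m1, m2, g5, g6


def predator_lower_thresholds(
    params: ModelParameters,
    M1: float,
    m1: float,
    M3: float,
    M4: float,
    n3: float,
    n4: float,
) -> tuple[float | None, float | None, float, float, float, float]:
    """Predator lower thresholds and the H7–H10 expression values.

    With ``X3 = r3^m + a34^m M4 − k3^l n3`` and
    ``X4 = r4^m + a43^m M3 − k4^l n4``:
    ``m3* = (a31^l m1 − M1 X3)/(b13^m X3)``,
    ``m4* = (a41^l m1 − M1 X4)/(b14^m X4)``.
    Returns ``(m3*, m4*, h7, h8, h9, h10)``.
    """
    X3 = params.sup("r3") + params.sup("a34") * M4 - params.inf("k3") * n3
    X4 = params.sup("r4") + params.sup("a43") * M3 - params.inf("k4") * n4
    h9 = params.inf("a31") * m1 - M1 * X3
    h10 = params.inf("a41") * m1 - M1 * X4
    m3_star = h9 / (params.sup("b13") * X3) if X3 > 0 else None
    m4_star = h10 / (params.sup("b14") * X4) if X4 > 0 else None
    return m3_star, m4_star, X3, X4, h9, h10


# ---------------------------------------------------------------------------
# orchestration


def compute_bounds(params: ModelParameters, slack: float = 0.0) -> PermanenceBounds:
    """Evaluate every permanence constant that is defined for ``params``.

    ``slack`` widens the free predator bounds to ``M* · (1 + slack)`` and
    ``m* · (1 − slack)`` so the ordering chain holds with strict
    inequality; the default 0 uses the starred thresholds themselves.
    """
    M1, M2 = prey_upper_bounds(params)
    N1, N2, N3, N4 = control_upper_bounds(params, M1, M2)
    bounds = PermanenceBounds(M1=M1, M2=M2, N1=N1, N2=N2, N3=N3, N4=N4, slack=slack)

    M3_star, M4_star, *_ = predator_upper_thresholds(params, M1, N3, N4)
    if M3_star is None or M4_star is None:
        return bounds
    M3 = M3_star * (1.0 + slack)
    M4 = M4_star * (1.0 + slack)
    bounds = replace(bounds, M3_star=M3_star, M4_star=M4_star, M3=M3, M4=M4)

    m1, m2, _, _ = prey_lower_bounds(params, M1, M2, N1, N2)
    if m1 is None or m2 is None:
        return bounds
    n1, n2, n3, n4 = control_lower_bounds(params, m1, m2, M3, M4)
    bounds = replace(bounds, m1=m1, m2=m2, n1=n1, n2=n2, n3=n3, n4=n4)

    m3_star, m4_star, *_ = predator_lower_thresholds(params, M1, m1, M3, M4, n3, n4)
    if m3_star is None or m4_star is None:
        return bounds
    m3 = m3_star * (1.0 - slack)
    m4 = m4_star * (1.0 - slack)
    return replace(bounds, m3_star=m3_star, m4_star=m4_star, m3=m3, m4=m4)


_H_DESCRIPTIONS = {
    "H1": "r3^l - a32^m - k3^m N3",
    "H2": "r4^l - a42^m - k4^m N4",
    "H3": "a31^m - r3^l + a32^m + k3^m N3",
    "H4": "a41^m - r4^l + a42^m + k4^m N4",
    "H5": "(r1^l - a12^m M2 - k1^m N1) b13^l b14^l - a13^m b14^l - a14^m b13^l",
    "H6": "(r2^l - a21^m M1 - k2^m N2) b23^l b24^l - a23^m b24^l - a24^m b23^l",
    "H7": "r3^m + a34^m M4 - k3^l n3",
    "H8": "r4^m + a43^m M3 - k4^l n4",
    "H9": "a31^l m1 - M1 (r3^m + a34^m M4 - k3^l n3)",
    "H10": "a41^l m1 - M1 (r4^m + a43^m M3 - k4^l n4)",
}


def evaluate_H1_H10(
    params: ModelParameters, slack: float = 0.0
) -> tuple[list[CriterionValue], PermanenceBounds]:
    """Evaluate the ten permanence criteria in order.

    Returns the criterion list and the :class:`PermanenceBounds` computed
    along the way.  Criteria whose prerequisites fail carry ``value=None``
    and are unsatisfied; nothing is raised.
    """
    M1, M2 = prey_upper_bounds(params)
    N1, N2, N3, N4 = control_upper_bounds(params, M1, M2)
    bounds = compute_bounds(params, slack=slack)
    _, _, h1, h2, h3, h4 = predator_upper_thresholds(params, M1, N3, N4)
    _, _, g5, g6 = prey_lower_bounds(params, M1, M2, N1, N2)
    values: dict[str, float | None] = {
        "H1": h1, "H2": h2, "H3": h3, "H4": h4, "H5": g5, "H6": g6,
        "H7": None, "H8": None, "H9": None, "H10": None,
    }
    if (
        bounds.m1 is not None
        and bounds.M3 is not None
        and bounds.n3 is not None
    ):
        _, _, h7, h8, h9, h10 = predator_lower_thresholds(
            params, M1, bounds.m1, bounds.M3, bounds.M4, bounds.n3, bounds.n4
        )
        values.update({"H7": h7, "H8": h8, "H9": h9, "H10": h10})
    crits = [
        CriterionValue(name, values[name], _H_DESCRIPTIONS[name])
        for name in _H_DESCRIPTIONS
    ]
    return crits, bounds
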