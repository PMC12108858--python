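"""Lyapunov stability margins A1–A4, B1–B4 and criteria H11–H18.

When the permanence conditions H1–H10 hold, a strictly positive,
spatially homogeneous ω-periodic solution exists.  The eight additional
margin coefficients below come from a Lyapunov functional argument: each
``A_i`` is the self-damping of species i minus every destabilizing
coupling and delay contribution, and each ``B_i`` is the decay rate of
control variable i minus its delay-weighted feedback load.  If all of
A1–A4 and B1–B4 are strictly positive, the periodic solution is globally
asymptotically stable and the solution of the reaction–diffusion system
converges to it uniformly in space.

Every fraction of the form ``X/(Y)²`` below uses the permanence constants
``m_i, M_i, n_i, N_i`` with the free predator bounds fixed (by default to
the starred thresholds); ``N_i`` are always the recomputed formula values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ModelParameters
from .permanence import CriterionValue, PermanenceBounds, compute_bounds

__all__ = ["StabilityReport", "evaluate_A", "evaluate_B", "evaluate_H11_H18"]


@dataclass(frozen=True)
class StabilityReport:
    """Values of A1–A4, B1–B4 with their sign flags and inputs."""

    A: tuple[float, float, float, float]
    B: tuple[float, float, float, float]
    criteria: tuple[CriterionValue, ...]  # H11..H18 in order
    bounds: PermanenceBounds
    prerequisites_ok: bool  # whether H1-H10 all held
    permanence_criteria: tuple[CriterionValue, ...] = field(default=())

    @property
    def verdict(self) -> bool:
        """True iff H1–H18 are all satisfied."""
        return self.prerequisites_ok and all(c.satisfied for c in self.criteria)


def evaluate_A(
    params: ModelParameters, bounds: PermanenceBounds
) -> tuple[float, float, float, float]:
    """The four species-equation margins A1–A4.

    Requires a complete :class:`PermanenceBounds` (all of m_i, M_i, n_i,
    N_i defined).
    """
    if not bounds.complete:
        raise ValueError("stability margins need complete permanence bounds")
    s, i, d = params.sup, params.inf, params.delays
    M1, M2, M3, M4 = bounds.M1, bounds.M2, bounds.M3, bounds.M4
    m1, m2, m3, m4 = bounds.m1, bounds.m2, bounds.m3, bounds.m4
    N1, N2, N3, N4 = bounds.N1, bounds.N2, bounds.N3, bounds.N4

    D13 = i("b13") * m3 + m1   # denominators of the ratio-response fractions
    D14 = i("b14") * m4 + m1
    D23 = i("b23") * m3 + m2
    D24 = i("b24") * m4 + m2

    # per-capita load of prey equation 1 resp. 2 (the bracketed rate sums)
    L1 = (
        s("r1") + s("a11") * M1 + s("a12") * M2
        + s("a13") * M3 / D13 + s("a14") * M4 / D14 + s("k1") * N1
    )
    L2 = (
        s("r2") + s("a22") * M2 + s("a21") * M1
        + s("a23") * M3 / D23 + s("a24") * M4 / D24 + s("k2") * N2
    )

    A1 = (
        i("a11") - s("a21") - s("q1")
        - (s("a11") * d.tau11 + s("a21") * d.tau21) * L1
        - (M1 * s("a11") * d.tau11 + M1 * s("a21") * d.tau21 + 1 + s("b13"))
        * s("a13") * M3 / D13**2
        - (M1 * s("a11") * d.tau11 + M1 * s("a21") * d.tau21 + 1 + s("b14"))
        * s("a14") * M4 / D14**2
        - M1 * s("a11") ** 2 * d.tau11
        - M2 * s("a21") * s("a12") * d.tau12
        - M2 * s("a21") * s("a22") * d.tau22
        - M1 * s("a21") * s("a11") * d.tau21
        - s("a34") * d.tau34 * s("a41") * s("b14") * M4**2 / D14**2
        - s("a43") * d.tau43 * s("a31") * s("b13") * M3**2 / D13**2
    )
    A2 = (
        i("a22") - s("a12") - s("q2")
        - (s("a12") * d.tau12 + s("a22") * d.tau22) * L2
        - (M2 * s("a12") * d.tau12 + M2 * s("a22") * d.tau22 + 1 + s("b23"))
        * s("a23") * M3 / D23**2
        - (M2 * s("a12") * d.tau12 + M2 * s("a22") * d.tau22 + 1 + s("b24"))
        * s("a24") * M4 / D24**2
        - M1 * s("a12") * s("a11") * d.tau11
        - M2 * s("a12") * s("a22") * d.tau12
        - M2 * s("a22") ** 2 * d.tau22
        - M1 * s("a12") * s("a21") * d.tau21
        - s("a34") * d.tau34 * s("a42") * s("b24") * M4**2 / D24**2
        - s("a43") * d.tau43 * s("a32") * s("b23") * M3**2 / D23**2
    )
    A3 = (
        i("a31") * i("b13") * m2 / (s("b13") * M3 + M1) ** 2
        + i("a32") * i("b23") * m2 / (s("b23") * M3 + M2) ** 2
        - s("a34") * d.tau34 * s("a43") * M4
        - s("a43")
        - s("q3")
        - (
            s("a13") * M1
            + s("a13") * M1**2 * (s("a11") * d.tau11 + s("a21") * d.tau21)
            + s("a43") * d.tau43 * s("a31") * s("b13") * M1 * M3
        ) / D13**2
        - (
            s("a23") * M2**2 * s("a12") * d.tau12
            + s("a43") * d.tau43 * s("a32") * s("b23") * M2 * M3
            + s("a23") * M2
            + s("a23") * M2**2 * s("a22") * d.tau22
        ) / D23**2
        - s("a43") * d.tau43 * (
            s("r3") + s("a31") * M1 / D13 + s("a32") * M2 / D23
            + s("a34") * M4 + s("k3") * N3
        )
    )
    A4 = (
        i("a41") * i("b14") * m2 / (s("b14") * M4 + M1) ** 2
        + i("a42") * i("b24") * m2 / (s("b24") * M4 + M2) ** 2
        - s("a34")
        - s("a43") * d.tau43 * s("a34") * M3
        - s("q4")
        - (
            s("a14") * M1
            + s("a14") * M1**2 * s("a11") * d.tau11
            + s("a14") * M1**2 * s("a21") * d.tau21
            + s("a34") * d.tau34 * s("a41") * s("b14") * M1 * M4
        ) / D14**2
        - (
            s("a24") * M2**2 * (s("a12") * d.tau12 + s("a22") * d.tau22)
            + s("a34") * d.tau34 * s("a42") * s("b24") * M2 * M4
            + s("a24") * M2
        ) / D24**2
        - s("a34") * d.tau34 * (
            s("r4") + s("a41") * M1 / D14 + s("a42") * M2 / D24
            + s("a43") * M3 + s("k4") * N4
        )
    )
    return A1, A2, A3, A4


def evaluate_B(
    params: ModelParameters, bounds: PermanenceBounds
) -> tuple[float, float, float, float]:
    """The four control-equation margins B1–B4."""
    if bounds.M3 is None or bounds.M4 is None:
        raise ValueError("B3/B4 need the predator upper bounds M3, M4")
    s, i, d = params.sup, params.inf, params.delays
    M1, M2, M3, M4 = bounds.M1, bounds.M2, bounds.M3, bounds.M4
    B1 = (
        i("f1")
        - s("k1") * (1 + M1 * s("a11") * d.tau11)
        - M1 * s("k1") * s("a21") * d.tau21
    )
    B2 = (
        i("f2")
        - M2 * s("k2") * s("a12") * d.tau12
        - s("k2") * (1 + M2 * s("a22") * d.tau22)
    )
    B3 = i("f3") - s("k3") - s("a43") * d.tau43 * s("k3") * M3
    B4 = i("f4") - s("k4") - s("a34") * d.tau34 * s("k4") * M4
    return B1, B2, B3, B4


def evaluate_H11_H18(
    params: ModelParameters, slack: float = 0.0
) -> StabilityReport:
    """Full stability report: H1–H10 prerequisites, A/B margins, verdict."""
    from .permanence import evaluate_H1_H10

    perm_crits, bounds = evaluate_H1_H10(params, slack=slack)
    prerequisites_ok = all(c.satisfied for c in perm_crits)
    if not bounds.complete:
        nan = float("nan")
        crits = tuple(
            CriterionValue(f"H{i}", None, "undefined: permanence bounds incomplete")
            for i in range(11, 19)
        )
        return StabilityReport(
            A=(nan,) * 4, B=(nan,) * 4, criteria=crits, bounds=bounds,
            prerequisites_ok=prerequisites_ok,
            permanence_criteria=tuple(perm_crits),
        )
    A = evaluate_A(params, bounds)
    B = evaluate_B(params, bounds)
    names = [f"H{i}" for i in range(11, 19)]
    descriptions = [f"A{i} > 0" for i in range(1, 5)] + [
        f"B{i} > 0" for i in range(1, 5)
    ]
    crits = tuple(
        CriterionValue(n, v, desc)
        for n, v, desc in zip(names, list(A) + list(B), descriptions)
    )
    return StabilityReport(
        A=A, B=B, criteria=crits, bounds=bounds,
        prerequisites_ok=prerequisites_ok,
        permanence_criteria=tuple(perm_crits),
    )
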