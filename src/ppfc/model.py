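"""Full parameter set of the four-species delayed predator–prey system.

The model couples two prey (densities ``v1``, ``v2``), two predators
(``v3``, ``v4``) and four feedback-control variables (``u1``..``u4``).
Prey grow logistically with delayed intraspecific crowding (delays τ11,
τ22) and interspecific competition (τ12, τ21); predators consume prey
through ratio-dependent functional responses ``a·v_prey/(b·v_pred +
v_prey)`` with maturation delays (τ31, τ32, τ41, τ42) and interfere with
each other with delays τ34, τ43.  Each control variable obeys a linear ODE
``u̇_i = e_i − f_i u_i ± q_i v_i`` and feeds back into the growth rate of
species i through a term ``∓ k_i u_i``.

All rates are positive ω-periodic functions represented by
:class:`~ppfc.coefficients.PeriodicCoefficient`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from functools import cached_property

from .coefficients import PeriodicCoefficient, PeriodError, common_period

__all__ = [
    "DelaySet",
    "ModelParameters",
    "ValidationReport",
    "COEFFICIENT_NAMES",
    "DELAY_NAMES",
]

#: coefficient slots, in a canonical order used by serialization and solvers
COEFFICIENT_NAMES = (
    "r1", "r2", "r3", "r4",
    "a11", "a12", "a13", "a14",
    "a21", "a22", "a23", "a24",
    "a31", "a32", "a34",
    "a41", "a42", "a43",
    "b13", "b14", "b23", "b24",
    "d1", "d2", "d3", "d4",
    "k1", "k2", "k3", "k4",
    "e1", "e2", "e3", "e4",
    "f1", "f2", "f3", "f4",
    "q1", "q2", "q3", "q4",
)

DELAY_NAMES = (
    "tau11", "tau12", "tau21", "tau22",
    "tau31", "tau32", "tau41", "tau42",
    "tau34", "tau43",
)


@dataclass(frozen=True)
class DelaySet:
    """The ten constant delays of the system.

    τ11..τ22 are crowding delays, τ31..τ42 maturation (gestation) delays,
    τ34 and τ43 predator-interference delays.  The maximum delay defines
    the length of the history interval [−τ, 0]; it deliberately includes
    τ34 and τ43 since both appear as delayed arguments in the equations.
    """

    tau11: float = 0.0
    tau12: float = 0.0
    tau21: float = 0.0
    tau22: float = 0.0
    tau31: float = 0.0
    tau32: float = 0.0
    tau41: float = 0.0
    tau42: float = 0.0
    tau34: float = 0.0
    tau43: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DELAY_NAMES}

    @property
    def tau_max(self) -> float:
        return max(self.as_dict().values())

    @property
    def min_positive(self) -> float:
        """Smallest strictly positive delay (inf if all delays are zero)."""
        positive = [t for t in self.as_dict().values() if t > 0]
        return min(positive) if positive else float("inf")


def max_delay(delays: DelaySet) -> float:
    """Maximum over all ten delay slots."""
    return delays.tau_max


@dataclass
class ValidationReport:
    """Report-style validation outcome: a list of named problems."""

    problems: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.problems

    def __bool__(self) -> bool:
        return self.valid

    def __str__(self) -> str:
        if self.valid:
            return "valid"
        return "invalid: " + "; ".join(self.problems)


@dataclass(frozen=True)
class ModelParameters:
    """The complete coefficient/delay set of the system."""

    coefficients: dict[str, PeriodicCoefficient]
    delays: DelaySet
    omega: float

    def __post_init__(self) -> None:
        missing = [n for n in COEFFICIENT_NAMES if n not in self.coefficients]
        if missing:
            raise ValueError(f"missing coefficient blocks: {', '.join(missing)}")

    def __getattr__(self, name: str) -> PeriodicCoefficient:
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self.coefficients[name]
        except KeyError:
            raise AttributeError(name) from None

    # -- extrema shorthand ----------------------------------------------

    @cached_property
    def _extrema(self) -> dict[str, tuple[float, float]]:
        return {n: self.coefficients[n].extrema() for n in COEFFICIENT_NAMES}

    def sup(self, name: str) -> float:
        """Period supremum ``φ^m`` of the named coefficient."""
        return self._extrema[name][0]

    def inf(self, name: str) -> float:
        """Period infimum ``φ^l`` of the named coefficient."""
        return self._extrema[name][1]

    @property
    def tau_max(self) -> float:
        return self.delays.tau_max

    def validate(self) -> ValidationReport:
        """Check positivity of every coefficient, delay signs and periods."""
        report = ValidationReport()
        for name in COEFFICIENT_NAMES:
            if self.inf(name) <= 0.0:
                report.problems.append(
                    f"coefficient {name} is not positive (inf = {self.inf(name):g})"
                )
        for name, tau in self.delays.as_dict().items():
            if tau < 0:
                report.problems.append(f"delay {name} is negative ({tau:g})")
        try:
            omega = common_period(self.coefficients.values(), default=self.omega)
        except PeriodError as exc:
            report.problems.append(str(exc))
        else:
            if abs(omega - self.omega) > 1e-9 * max(1.0, self.omega):
                report.problems.append(
                    f"declared period {self.omega:g} does not match the "
                    f"coefficients' common period {omega:g}"
                )
        return report


def validate(params: ModelParameters) -> ValidationReport:
    """Module-level alias for :meth:`ModelParameters.validate`."""
    return params.validate()
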