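"""Reference parameter set and synthetic random models.

``example1_model`` encodes the worked example: every coefficient is a
trig-affine function with angular frequency π (period ω = 2), unit
diffusivities, and ten small delays between 0.001 and 0.01.  The printed
interference-saturation coefficient ``b23`` carries amplitude 0.01 in one
equation but 0.1 in another; only the 0.1 reading reproduces the
published derived constants, so 0.1 is the default here (a
``verbatim_eq63`` flag restores 0.01 for sensitivity study) and the
substitution is logged on load.

``random_model`` draws positive trig-affine coefficient sets whose
magnitudes mirror the reference example family by family, so permanence
and stability conditions typically hold; amplitudes are a fraction < 1 of
each constant term, which guarantees positivity by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .coefficients import PeriodicCoefficient, TrigTerm
from .dde import HistoryFunctions
from .model import COEFFICIENT_NAMES, DelaySet, ModelParameters
from .pde import InitialData

__all__ = [
    "example1_model",
    "example1_initial_data",
    "FixtureSpec",
    "random_model",
    "random_constant_history",
]

logger = logging.getLogger(__name__)

_PI = math.pi


def _trig(c0: float, kind: str | None = None, amp: float = 0.0) -> PeriodicCoefficient:
    terms = () if kind is None else (TrigTerm(kind, amp, _PI),)
    return PeriodicCoefficient(constant_term=c0, trig_terms=terms, period=2.0)


# (constant, kind, amplitude) per coefficient of the reference model
_EXAMPLE1_SPEC: dict[str, tuple[float, str | None, float]] = {
    "r1": (22.0, "cos", 1.0),
    "r2": (23.0, "cos", 1.0),
    "r3": (10.5, "cos", 0.1),
    "r4": (11.0, "cos", 0.1),
    "a11": (10.0, "sin", 1.0),
    "a12": (0.06, "sin", 0.01),
    "a13": (0.04, "sin", 0.01),
    "a14": (0.05, "sin", 0.01),
    "a21": (0.05, "sin", 0.01),
    "a22": (11.0, "sin", 1.0),
    "a23": (0.05, "sin", 0.01),
    "a24": (0.04, "sin", 0.01),
    "a31": (20.0, "sin", 1.0),
    "a32": (1.5, "sin", 0.1),
    "a34": (0.05, "sin", 0.01),
    "a41": (21.0, "sin", 1.0),
    "a42": (1.5, "sin", 0.1),
    "a43": (0.04, "sin", 0.01),
    "b13": (2.1, "sin", 0.1),
    "b14": (2.0, "sin", 0.1),
    "b23": (2.1, "sin", 0.1),  # printed 0.01 in one equation; see module docstring
    "b24": (2.0, "sin", 0.1),
    "d1": (1.0, None, 0.0),
    "d2": (1.0, None, 0.0),
    "d3": (1.0, None, 0.0),
    "d4": (1.0, None, 0.0),
    "k1": (0.05, "sin", 0.01),
    "k2": (0.06, "sin", 0.01),
    "k3": (0.05, "sin", 0.01),
    "k4": (0.04, "sin", 0.01),
    "e1": (21.0, "sin", 1.0),
    "e2": (21.5, "sin", 1.0),
    "e3": (19.5, "sin", 1.0),
    "e4": (20.0, "sin", 1.0),
    "f1": (10.0, "sin", 0.5),
    "f2": (9.5, "sin", 0.5),
    "f3": (9.5, "sin", 0.5),
    "f4": (10.0, "sin", 0.5),
    "q1": (0.05, "sin", 0.01),
    "q2": (0.04, "sin", 0.01),
    "q3": (0.05, "sin", 0.01),
    "q4": (0.04, "sin", 0.01),
}

_EXAMPLE1_DELAYS = DelaySet(
    tau11=0.001, tau12=0.004, tau21=0.003, tau22=0.002,
    tau31=0.007, tau32=0.008, tau41=0.009, tau42=0.01,
    tau34=0.005, tau43=0.006,
)


def example1_model(verbatim_eq63: bool = False) -> ModelParameters:
    """The reference four-species periodic model (ω = 2, delays ≤ 0.01).

    ``verbatim_eq63`` uses the literally printed b23 amplitude 0.01
    instead of the self-consistent 0.1.
    """
    spec = dict(_EXAMPLE1_SPEC)
    if verbatim_eq63:
        spec["b23"] = (2.1, "sin", 0.01)
    else:
        logger.info(
            "reference model: using b23 amplitude 0.1 (the printed 0.01 is "
            "inconsistent with the published derived constants)"
        )
    coefs = {name: _trig(*spec[name]) for name in COEFFICIENT_NAMES}
    return ModelParameters(coefficients=coefs, delays=_EXAMPLE1_DELAYS, omega=2.0)


def example1_initial_data() -> InitialData:
    """The reference initial/history profiles on Ω = [0, 2π].

    The printed species histories are stated on [−0.005, 0] although the
    maximum delay is 0.01; they extend naturally (same formulas) to
    [−0.01, 0], which is done here and logged.  The printed control
    profiles take non-positive values at some nodes; they are kept
    verbatim (the simulator tolerates this — the control sources pull
    them positive immediately).
    """
    logger.info(
        "reference initial data: species histories extended from [-0.005, 0] "
        "to [-0.01, 0] by the same formulas; control profiles are not "
        "strictly positive (kept verbatim)"
    )
    v = (
        lambda x, t: (2.0 + 2.0 * t) * (1.0 + np.cos(x + _PI)),
        lambda x, t: (2.5 + 2.5 * t) * (1.0 + np.cos(x + _PI)),
        lambda x, t: (1.0 + 2.0 * t) * (1.0 + np.sin(x - _PI / 2.0)),
        lambda x, t: (0.9 + 1.5 * t) * (1.0 + np.sin(x - _PI / 2.0)),
    )
    u = (
        lambda x: 1.5 * np.sin(x - _PI / 2.0),
        lambda x: 1.0 * np.sin(x - _PI / 2.0),
        lambda x: 0.7 * np.sin(x - _PI / 2.0),
        lambda x: 0.3 * np.sin(x - _PI / 2.0),
    )
    return InitialData(v=v, u=u)


# ---------------------------------------------------------------------------
# synthetic random models


@dataclass(frozen=True)
class FixtureSpec:
    """Controls for the synthetic model generator.

    ``amplitude_fraction`` scales each coefficient's oscillation relative
    to its constant term and must stay below 1 so positivity holds by
    construction.  ``jitter`` is the relative spread of the constant terms
    around the reference-model values.  Delays are drawn uniformly from
    ``delay_range``.
    """

    seed: int = 0
    amplitude_fraction: float = 0.05
    jitter: float = 0.05
    delay_range: tuple[float, float] = (0.001, 0.01)
    omega: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_fraction < 1.0:
            raise ValueError("amplitude_fraction must be in [0, 1)")
        if self.delay_range[0] < 0 or self.delay_range[1] < self.delay_range[0]:
            raise ValueError("invalid delay range")


def random_model(spec: FixtureSpec) -> ModelParameters:
    """Deterministic (per seed) positive trig-affine parameter set.

    Constant terms are the reference-model levels perturbed by a relative
    log-uniform jitter; each coefficient gets one sin or cos term with
    amplitude ``amplitude_fraction`` times its constant term at the common
    angular frequency ``2π/ω``.
    """
    rng = np.random.default_rng(spec.seed)
    w = 2.0 * _PI / spec.omega
    coefs: dict[str, PeriodicCoefficient] = {}
    for name in COEFFICIENT_NAMES:
        base = _EXAMPLE1_SPEC[name][0]
        c0 = base * float(np.exp(rng.uniform(-spec.jitter, spec.jitter)))
        if spec.amplitude_fraction == 0.0:
            coefs[name] = PeriodicCoefficient(constant_term=c0, period=spec.omega)
        else:
            kind = "sin" if rng.random() < 0.5 else "cos"
            amp = spec.amplitude_fraction * c0 * float(rng.uniform(0.2, 1.0))
            coefs[name] = PeriodicCoefficient(
                constant_term=c0, trig_terms=(TrigTerm(kind, amp, w),),
                period=spec.omega,
            )
    lo, hi = spec.delay_range
    delays = DelaySet(**{
        nm: float(rng.uniform(lo, hi)) for nm in DelaySet().as_dict()
    })
    return ModelParameters(coefficients=coefs, delays=delays, omega=spec.omega)


def random_constant_history(rng: np.random.Generator) -> HistoryFunctions:
    """Constant positive history, log-uniform in [0.1, 3] per channel.

    This spans the permanence box without pathological transients, which
    is what the attractivity experiments need.
    """
    vals = np.exp(rng.uniform(np.log(0.1), np.log(3.0), size=8))
    return HistoryFunctions.constant(vals)
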