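"""Method-of-steps integration of the degenerate delay-ODE system.

Dropping diffusion from the reaction–diffusion system leaves an 8-channel
delay differential equation for ``(v1..v4, u1..u4)``.  Spatially
homogeneous solutions of the full system coincide with solutions of this
degenerate system, so this integrator doubles as the accuracy reference
for the PDE solver on homogeneous data.

The integrator uses a fixed step so that delayed lookups align with
stored nodes; off-node delayed values come from cubic Hermite
interpolation on the stored trajectory (state and derivative are kept at
every node).  The default scheme is classical 4th-order Runge–Kutta; an
explicit-Euler variant is provided so the PDE solver (which is Euler in
time) can be compared against an identically discretized reference.

Because the step is required to satisfy ``Δt ≤ (min positive delay)/2``,
every delayed argument of every Runge–Kutta stage lies in the already
computed past — the method of steps needs no implicit iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import ModelParameters

__all__ = [
    "HistoryFunctions",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "integrate_dde",
    "STATE_NAMES",
    "DELAYED_VARIABLE",
]

STATE_NAMES = ("v1", "v2", "v3", "v4", "u1", "u2", "u3", "u4")

#: which state variable each delay slot applies to
DELAYED_VARIABLE = {
    "tau11": "v1", "tau12": "v2", "tau21": "v1", "tau22": "v2",
    "tau31": "v1", "tau32": "v2", "tau34": "v4",
    "tau41": "v1", "tau42": "v2", "tau43": "v3",
}

#: fixed order of the ten delayed lookups fed to the right-hand side
LAG_ORDER = (
    "tau11", "tau12", "tau21", "tau22",
    "tau31", "tau32", "tau34", "tau41", "tau42", "tau43",
)

#: coefficients the reaction terms read (diffusivities excluded)
REACTION_COEFS = (
    "r1", "a11", "a12", "a13", "b13", "a14", "b14", "k1",
    "r2", "a22", "a21", "a23", "b23", "a24", "b24", "k2",
    "r3", "a31", "a32", "a34", "k3",
    "r4", "a41", "a42", "a43", "k4",
    "e1", "f1", "q1", "e2", "f2", "q2",
    "e3", "f3", "q3", "e4", "f4", "q4",
)
_CIDX = {name: j for j, name in enumerate(REACTION_COEFS)}


class IntegrationError(RuntimeError):
    """Raised on positivity loss or non-finite states during integration."""


@dataclass(frozen=True)
class HistoryFunctions:
    """Positive history ``ξ_i`` (species) and ``η_i`` (controls) on [−τ, 0]."""

    xi: tuple[Callable[[float], float], ...]
    eta: tuple[Callable[[float], float], ...]

    @classmethod
    def constant(cls, values: Sequence[float]) -> "HistoryFunctions":
        """Constant history from an 8-vector ``(v1..v4, u1..u4)``."""
        vals = [float(v) for v in values]
        if len(vals) != 8:
            raise ValueError("need 8 values (v1..v4, u1..u4)")
        mk = lambda c: (lambda t, c=c: c)
        return cls(xi=tuple(mk(c) for c in vals[:4]),
                   eta=tuple(mk(c) for c in vals[4:]))

    def state0(self) -> np.ndarray:
        return np.array([f(0.0) for f in self.xi + self.eta], dtype=float)

    def check_positive(self, tau: float, n_samples: int = 64) -> list[str]:
        """Names of channels whose history is not strictly positive on a
        sample grid of [−τ, 0]."""
        ts = np.linspace(-tau, 0.0, n_samples) if tau > 0 else np.array([0.0])
        bad = []
        for name, f in zip(STATE_NAMES, self.xi + self.eta):
            if any(f(t) <= 0.0 for t in ts):
                bad.append(name)
        return bad


@dataclass
class Trajectory:
    """Time series of the 8 state channels on a uniform grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 8), columns in STATE_NAMES order
    dt: float
    derivatives: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


# ---------------------------------------------------------------------------
# right-hand side


def _rhs_core(c: Sequence[float], y: Sequence[float], lag: Sequence[float]):
    """The eight reaction right-hand sides.

    ``c`` holds the coefficient values in REACTION_COEFS order, ``y`` the
    current state, ``lag`` the ten delayed values in LAG_ORDER.  A ratio
    term whose denominator vanishes (both populations zero) contributes 0.
    """
    v1, v2, v3, v4, u1, u2, u3, u4 = y
    v1_11, v2_12, v1_21, v2_22, v1_31, v2_32, v4_34, v1_41, v2_42, v3_43 = lag

    den = c[4] * v3 + v1            # b13 v3 + v1
    p13 = c[3] * v3 / den if den != 0.0 else 0.0
    den = c[6] * v4 + v1            # b14 v4 + v1
    p14 = c[5] * v4 / den if den != 0.0 else 0.0
    dv1 = v1 * (c[0] - c[1] * v1_11 - c[2] * v2_12 - p13 - p14 - c[7] * u1)

    den = c[12] * v3 + v2           # b23 v3 + v2
    p23 = c[11] * v3 / den if den != 0.0 else 0.0
    den = c[14] * v4 + v2           # b24 v4 + v2
    p24 = c[13] * v4 / den if den != 0.0 else 0.0
    dv2 = v2 * (c[8] - c[9] * v2_22 - c[10] * v1_21 - p23 - p24 - c[15] * u2)

    den = c[4] * v3 + v1_31         # b13 v3 + v1(t-tau31)
    g31 = c[17] * v1_31 / den if den != 0.0 else 0.0
    den = c[12] * v3 + v2_32        # b23 v3 + v2(t-tau32)
    g32 = c[18] * v2_32 / den if den != 0.0 else 0.0
    dv3 = v3 * (-c[16] + g31 + g32 - c[19] * v4_34 + c[20] * u3)

    den = c[6] * v4 + v1_41         # b14 v4 + v1(t-tau41)
    g41 = c[22] * v1_41 / den if den != 0.0 else 0.0
    den = c[14] * v4 + v2_42        # b24 v4 + v2(t-tau42)
    g42 = c[23] * v2_42 / den if den != 0.0 else 0.0
    dv4 = v4 * (-c[21] + g41 + g42 - c[24] * v3_43 + c[25] * u4)

    du1 = c[26] - c[27] * u1 + c[28] * v1
    du2 = c[29] - c[30] * u2 + c[31] * v2
    du3 = c[32] - c[33] * u3 - c[34] * v3
    du4 = c[35] - c[36] * u4 - c[37] * v4
    return (dv1, dv2, dv3, dv4, du1, du2, du3, du4)


def rhs(
    params: ModelParameters,
    t: float,
    state: Sequence[float],
    delayed_states: dict[str, float],
) -> np.ndarray:
    """Evaluate the eight reaction right-hand sides at time ``t``.

    ``delayed_states`` maps each delay name (``"tau11"``..``"tau43"``) to
    the value of its delayed variable at ``t − τ``.
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state at t={t}")
    c = [params.coefficients[name].evaluate(t) for name in REACTION_COEFS]
    lag = [float(delayed_states[name]) for name in LAG_ORDER]
    return np.array(_rhs_core(c, y, lag), dtype=float)


# ---------------------------------------------------------------------------
# fast coefficient table


class _CoefficientTable:
    """Vectorized evaluation of all reaction coefficients at one time.

    Trig-affine coefficients are packed into flat (index, amplitude,
    frequency, phase) arrays so one numpy expression evaluates all of
    them; cos terms become phase-shifted sines.  Models containing general
    callables fall back to a per-coefficient python loop.
    """

    def __init__(self, params: ModelParameters, names: Sequence[str] = REACTION_COEFS):
        self.names = tuple(names)
        coefs = [params.coefficients[n] for n in self.names]
        self._fallback = [c.general_callable is not None for c in coefs]
        self._coefs = coefs
        self.const = np.array(
            [0.0 if fb else c.constant_term for c, fb in zip(coefs, self._fallback)]
        )
        idx, amp, freq, phase = [], [], [], []
        for j, (c, fb) in enumerate(zip(coefs, self._fallback)):
            if fb:
                continue
            for term in c.trig_terms:
                idx.append(j)
                amp.append(term.amplitude)
                freq.append(term.angular_frequency)
                phase.append(0.0 if term.kind == "sin" else np.pi / 2.0)
        self.idx = np.array(idx, dtype=np.intp)
        self.amp = np.array(amp)
        self.freq = np.array(freq)
        self.phase = np.array(phase)
        self.any_fallback = any(self._fallback)

    def at(self, t: float) -> list[float]:
        vals = self.const.copy()
        if self.idx.size:
            np.add.at(vals, self.idx, self.amp * np.sin(self.freq * t + self.phase))
        out = vals.tolist()
        if self.any_fallback:
            for j, fb in enumerate(self._fallback):
                if fb:
                    out[j] = float(self._coefs[j].general_callable(t))
        return out


# ---------------------------------------------------------------------------
# integrator


def integrate_dde(
    params: ModelParameters,
    history: HistoryFunctions,
    t_max: float,
    dt: float,
    method: str = "rk4",
    positivity_floor: float = 1e-12,
    metadata: dict | None = None,
) -> Trajectory:
    """Integrate the delay-ODE system from a positive history.

    Parameters
    ----------
    t_max:
        End of the integration interval (the grid ends at the first node
        ``≥ t_max``); ``t_max = 0`` returns just the initial state.
    dt:
        Fixed step; must satisfy ``dt ≤ (min positive delay)/2``.
    method:
        ``"rk4"`` (default) or ``"euler"``.  The Euler variant exists to
        match the PDE solver's time discretization step for step.
    positivity_floor:
        Abort (rather than clip) if any channel drops below this value;
        clipping would silently violate the model.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    min_delay = params.delays.min_positive
    if dt > min_delay / 2.0 + 1e-15:
        raise ValueError(
            f"dt={dt:g} exceeds half the smallest positive delay "
            f"({min_delay:g}); delayed stage lookups would leave the "
            "computed past"
        )
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown method {method!r}")

    n_steps = max(int(np.ceil(t_max / dt - 1e-9)), 0)
    times = np.arange(n_steps + 1) * dt
    Y = np.empty((n_steps + 1, 8))
    F = np.empty((n_steps + 1, 8))

    hist_funcs = history.xi + history.eta
    bad = history.check_positive(params.tau_max)
    if bad:
        raise IntegrationError(
            f"history is not strictly positive on [-tau, 0] for: {', '.join(bad)}"
        )

    table = _CoefficientTable(params)
    taus = params.delays.as_dict()
    lag_info = [
        (taus[name], STATE_NAMES.index(DELAYED_VARIABLE[name]))
        for name in LAG_ORDER
    ]

    def lookup(s: float, var: int, max_node: int) -> float:
        """Delayed value of channel ``var``; needs nodes ``k, k+1 ≤ max_node``.

        ``dt ≤ τ/2`` guarantees every stage's delayed argument satisfies
        ``s ≤ t_{max_node} − dt``, so the bracketing nodes are computed.
        """
        if s <= 0.0:
            return float(hist_funcs[var](s))
        k = int(s / dt)
        if k > max_node - 1:
            k = max_node - 1
        th = s / dt - k
        y0, y1 = Y[k, var], Y[k + 1, var]
        f0, f1 = F[k, var], F[k + 1, var]
        th2 = th * th
        th3 = th2 * th
        return (
            (2 * th3 - 3 * th2 + 1) * y0
            + (th3 - 2 * th2 + th) * dt * f0
            + (-2 * th3 + 3 * th2) * y1
            + (th3 - th2) * dt * f1
        )

    def stage_lags(ts: float, ystage, max_node: int):
        out = []
        for tau, var in lag_info:
            if tau == 0.0:
                out.append(ystage[var])
            else:
                out.append(lookup(ts - tau, var, max_node))
        return out

    y = [float(f(0.0)) for f in hist_funcs]
    Y[0] = y
    F[0] = _rhs_core(table.at(0.0), y, stage_lags(0.0, y, 0))

    c_end = table.at(0.0)
    for n in range(n_steps):
        t = times[n]
        c0 = c_end
        y = Y[n]
        k1 = F[n]
        if method == "rk4":
            ch = table.at(t + dt / 2.0)
            c_end = table.at(t + dt)
            y2 = [y[j] + 0.5 * dt * k1[j] for j in range(8)]
            k2 = _rhs_core(ch, y2, stage_lags(t + dt / 2.0, y2, n))
            y3 = [y[j] + 0.5 * dt * k2[j] for j in range(8)]
            k3 = _rhs_core(ch, y3, stage_lags(t + dt / 2.0, y3, n))
            y4 = [y[j] + dt * k3[j] for j in range(8)]
            k4 = _rhs_core(c_end, y4, stage_lags(t + dt, y4, n))
            ynew = [
                y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
                for j in range(8)
            ]
        else:  # explicit Euler
            c_end = table.at(t + dt)
            ynew = [y[j] + dt * k1[j] for j in range(8)]
        if not all(np.isfinite(ynew)):
            raise IntegrationError(f"non-finite state at t={t + dt:.6g}")
        low = min(ynew)
        if low < positivity_floor:
            ch_name = STATE_NAMES[ynew.index(low)]
            raise IntegrationError(
                f"positivity lost in channel {ch_name} at t={t + dt:.6g} "
                f"(value {low:.3e}); try a smaller dt"
            )
        Y[n + 1] = ynew
        F[n + 1] = _rhs_core(c_end, ynew, stage_lags(t + dt, ynew, n))

    meta = {"method": method, "dt": dt}
    if metadata:
        meta.update(metadata)
    return Trajectory(times=times, states=Y, dt=dt, derivatives=F, metadata=meta)
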