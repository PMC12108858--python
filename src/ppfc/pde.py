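"""Method-of-lines integration of the reaction–diffusion system on [x_min, x_max].

The four species diffuse on a 1-D closed habitat with zero-flux (Neumann)
boundaries; the four control variables obey pointwise ODEs at every node.
Space is discretized on an endpoint grid with the standard three-point
Laplacian; the boundary stencil mirrors the adjacent interior node (ghost
value), which keeps the stencil symmetric and conserves the spatial mean
of a diffusing field.  Time stepping is explicit Euler, guarded by the
diffusion CFL bound ``Δt ≤ Δx²/(2 max d_i^m)`` and by the delay bound
``Δt ≤ (min positive delay)/2``.

Delayed values are read from a ring buffer of the last ``⌈τ/Δt⌉ + 1``
frames with linear interpolation in time; for lagged times before zero
the initial-history callables are evaluated directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dde import IntegrationError, _CoefficientTable, STATE_NAMES
from .model import ModelParameters

__all__ = [
    "SpatialGrid",
    "InitialData",
    "SpacetimeSolution",
    "laplacian_neumann",
    "cfl_max_dt",
    "integrate_pde",
]


@dataclass(frozen=True)
class SpatialGrid:
    """Endpoint-node grid on the closed interval [x_min, x_max]."""

    x_min: float
    x_max: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 spatial nodes")
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.n_nodes - 1)

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_nodes)


@dataclass(frozen=True)
class InitialData:
    """Initial/history profiles for the spatial problem.

    ``v`` holds four callables ``(x, t) -> value`` defined for
    ``t ∈ [−τ, 0]`` (the species carry history in time); ``u`` holds four
    callables ``x -> value`` giving the control profiles at ``t = 0``.
    Both accept numpy arrays of positions.
    """

    v: tuple[Callable[[np.ndarray, float], np.ndarray], ...]
    u: tuple[Callable[[np.ndarray], np.ndarray], ...]

    def positivity_report(
        self, grid: SpatialGrid, tau: float, n_time_samples: int = 16
    ) -> list[str]:
        """Channels whose initial profile is not strictly positive.

        Violations are reported, not fatal: isolated zeros (or negative
        control profiles) are tolerated by the simulator, which relies on
        the control replenishment ``e_i^l > 0`` to pull ``u_i`` positive.
        """
        x = grid.nodes
        ts = np.linspace(-tau, 0.0, n_time_samples) if tau > 0 else [0.0]
        bad = []
        for j, f in enumerate(self.v):
            if any(np.min(np.asarray(f(x, t), dtype=float)) <= 0 for t in ts):
                bad.append(f"v{j + 1}")
        for j, f in enumerate(self.u):
            if np.min(np.asarray(f(x), dtype=float)) <= 0:
                bad.append(f"u{j + 1}")
        return bad


@dataclass
class SpacetimeSolution:
    """Sampled space–time fields: shape (n_times, 8, n_nodes)."""

    grid: SpatialGrid
    times: np.ndarray
    fields: np.ndarray
    dt: float
    metadata: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.fields[:, STATE_NAMES.index(name), :]

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


def laplacian_neumann(field_row: np.ndarray, dx: float) -> np.ndarray:
    """Three-point second difference with mirror-ghost Neumann closure.

    Interior: ``(f[j−1] − 2 f[j] + f[j+1])/Δx²``; endpoints use a ghost
    node equal to the adjacent interior value, giving ``2(f[1] − f[0])/Δx²``
    and ``2(f[n−2] − f[n−1])/Δx²``.
    """
    f = np.asarray(field_row, dtype=float)
    out = np.empty_like(f)
    out[1:-1] = (f[:-2] - 2.0 * f[1:-1] + f[2:]) / dx**2
    out[0] = 2.0 * (f[1] - f[0]) / dx**2
    out[-1] = 2.0 * (f[-2] - f[-1]) / dx**2
    return out


def cfl_max_dt(params: ModelParameters, dx: float) -> float:
    """Explicit-diffusion stability bound ``Δx²/(2 max_i d_i^m)``."""
    dmax = max(params.sup(f"d{i}") for i in range(1, 5))
    return dx**2 / (2.0 * dmax)


def _reaction_fields(c, V, U, lag):
    """Vectorized reaction terms over all nodes.

    ``V``/``U`` are (4, nx) arrays, ``lag`` the ten lagged node rows in
    the DDE module's LAG_ORDER.  Mirrors ``dde._rhs_core`` exactly.
    """
    v1, v2, v3, v4 = V
    u1, u2, u3, u4 = U
    v1_11, v2_12, v1_21, v2_22, v1_31, v2_32, v4_34, v1_41, v2_42, v3_43 = lag

    def ratio(num, den):
        return np.divide(num, den, out=np.zeros_like(den), where=den != 0.0)

    dv1 = v1 * (
        c[0] - c[1] * v1_11 - c[2] * v2_12
        - ratio(c[3] * v3, c[4] * v3 + v1)
        - ratio(c[5] * v4, c[6] * v4 + v1)
        - c[7] * u1
    )
    dv2 = v2 * (
        c[8] - c[9] * v2_22 - c[10] * v1_21
        - ratio(c[11] * v3, c[12] * v3 + v2)
        - ratio(c[13] * v4, c[14] * v4 + v2)
        - c[15] * u2
    )
    dv3 = v3 * (
        -c[16]
        + ratio(c[17] * v1_31, c[4] * v3 + v1_31)
        + ratio(c[18] * v2_32, c[12] * v3 + v2_32)
        - c[19] * v4_34
        + c[20] * u3
    )
    dv4 = v4 * (
        -c[21]
        + ratio(c[22] * v1_41, c[6] * v4 + v1_41)
        + ratio(c[23] * v2_42, c[14] * v4 + v2_42)
        - c[24] * v3_43
        + c[25] * u4
    )
    du1 = c[26] - c[27] * u1 + c[28] * v1
    du2 = c[29] - c[30] * u2 + c[31] * v2
    du3 = c[32] - c[33] * u3 - c[34] * v3
    du4 = c[35] - c[36] * u4 - c[37] * v4
    return np.stack([dv1, dv2, dv3, dv4]), np.stack([du1, du2, du3, du4])


# which (delay name, v-channel) each lag slot reads, in LAG_ORDER
_LAG_SLOTS = (
    ("tau11", 0), ("tau12", 1), ("tau21", 0), ("tau22", 1),
    ("tau31", 0), ("tau32", 1), ("tau34", 3), ("tau41", 0),
    ("tau42", 1), ("tau43", 2),
)


def integrate_pde(
    params: ModelParameters,
    init: InitialData,
    grid: SpatialGrid,
    t_max: float,
    dt: float,
    include_reaction: bool = True,
    include_diffusion: bool = True,
    save_every: int | None = None,
    strict_positive: bool = False,
) -> SpacetimeSolution:
    """Explicit finite-difference integration of the full system.

    The species advance by reaction plus ``d_i(t)·Δ`` with Neumann
    boundaries; the controls advance by their pointwise ODEs.  ``dt`` must
    respect both the diffusion CFL bound and half the smallest positive
    delay.  ``save_every`` controls the output sampling stride (default:
    roughly every 0.01 time units).

    ``strict_positive`` rejects initial data that is not strictly
    positive; by default violations are only reported in the solution
    metadata, since isolated zeros or negative control initials are
    transient (the control source terms are strictly positive).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if include_diffusion:
        cfl = cfl_max_dt(params, grid.dx)
        if dt > cfl * (1 + 1e-12):
            raise ValueError(
                f"dt={dt:g} violates the diffusion CFL bound {cfl:g}"
            )
    min_delay = params.delays.min_positive
    if include_reaction and dt > min_delay / 2.0 + 1e-15:
        raise ValueError(
            f"dt={dt:g} exceeds half the smallest positive delay ({min_delay:g})"
        )

    tau = params.tau_max
    violations = init.positivity_report(grid, tau)
    if strict_positive and violations:
        raise IntegrationError(
            "initial data not strictly positive for: " + ", ".join(violations)
        )

    x = grid.nodes
    nx = grid.n_nodes
    n_steps = max(int(np.ceil(t_max / dt - 1e-9)), 0)
    if save_every is None:
        save_every = max(int(round(0.01 / dt)), 1)

    table = _CoefficientTable(params)
    d_names = ("d1", "d2", "d3", "d4")
    d_coefs = [params.coefficients[n] for n in d_names]

    taus = params.delays.as_dict()
    depth = int(np.ceil(tau / dt)) + 1 if tau > 0 else 1
    # ring[j] holds the v-fields (4, nx) at time t_n - j*dt
    ring = np.empty((depth + 1, 4, nx))

    V = np.stack([np.asarray(f(x, 0.0), dtype=float) for f in init.v])
    U = np.stack([np.asarray(f(x), dtype=float) for f in init.u])
    ring[0] = V

    def lagged(slot_tau: float, channel: int, t: float, n: int):
        """v-field of ``channel`` at time ``t − slot_tau`` (row of nodes)."""
        if slot_tau == 0.0:
            return V[channel]
        s = t - slot_tau
        if s <= 0.0:
            return np.asarray(init.v[channel](x, s), dtype=float)
        # frames available: j = 0..min(n, depth) at times t - j*dt
        r = slot_tau / dt
        j0 = int(r)
        w = r - j0
        if w == 0.0:
            return ring[j0][channel]
        j1 = min(j0 + 1, depth)
        return (1.0 - w) * ring[j0][channel] + w * ring[j1][channel]

    saved_times = [0.0]
    saved_fields = [np.concatenate([V, U], axis=0).copy()]

    for n in range(n_steps):
        t = n * dt
        c = table.at(t)
        lag_rows = [lagged(taus[name], ch, t, n) for name, ch in _LAG_SLOTS]
        if include_reaction:
            dV, dU = _reaction_fields(c, V, U, lag_rows)
        else:
            dV = np.zeros_like(V)
            dU = np.zeros_like(U)
        if include_diffusion:
            for i in range(4):
                dV[i] += d_coefs[i].evaluate(t) * laplacian_neumann(V[i], grid.dx)
        V = V + dt * dV
        U = U + dt * dU
        if not (np.all(np.isfinite(V)) and np.all(np.isfinite(U))):
            raise IntegrationError(f"non-finite field at t={t + dt:.6g}")
        vmin = V.min()
        if vmin < -1e-10:
            ch = int(np.argmin(V.min(axis=1)))
            node = int(np.argmin(V[ch]))
            raise IntegrationError(
                f"positivity lost in v{ch + 1} at node x={x[node]:.4g}, "
                f"t={t + dt:.6g} (value {vmin:.3e}); try a smaller dt"
            )
        # shift the history ring: frame j now refers to t_{n+1} - j*dt
        ring[1:] = ring[:-1]
        ring[0] = V
        if (n + 1) % save_every == 0 or n + 1 == n_steps:
            saved_times.append((n + 1) * dt)
            saved_fields.append(np.concatenate([V, U], axis=0).copy())

    meta = {
        "dt": dt,
        "save_every": save_every,
        "positivity_violations_in_initial_data": violations,
    }
    return SpacetimeSolution(
        grid=grid,
        times=np.array(saved_times),
        fields=np.array(saved_fields),
        dt=dt,
        metadata=meta,
    )
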