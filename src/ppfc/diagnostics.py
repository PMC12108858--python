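"""Numeric counterparts of the qualitative theory: defect measures.

The theory asserts four asymptotic properties of solutions — ω-periodicity,
spatial homogeneity, permanence (confinement to the closed-form box) and
global attractivity of the periodic orbit.  Each is an asymptotic,
uniform-convergence statement, so the finite-horizon surrogates here use
sup-norms over a tail window and allow a small slack on the permanence box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dde import STATE_NAMES, Trajectory
from .pde import SpacetimeSolution
from .permanence import PermanenceBounds

__all__ = [
    "DiagnosticsResult",
    "periodicity_defect",
    "homogeneity_defect",
    "empirical_permanence",
    "attractivity_distance",
]


@dataclass
class DiagnosticsResult:
    """Collected defect measures for one solution (fields optional)."""

    periodicity_defect: float | None = None
    homogeneity_defect: float | None = None
    empirical_bounds: dict | None = None
    attractivity_distance: float | None = None
    window: tuple[float, float] | None = None


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (times >= lo - 1e-12) & (times <= hi + 1e-12)


def periodicity_defect(
    traj: Trajectory, omega: float, window: tuple[float, float]
) -> float:
    """Sup over the window and channels of ``|z(t + ω) − z(t)|``.

    The shifted values are linearly interpolated on the stored grid; the
    window must satisfy ``window_end + ω ≤ t_max``.
    """
    lo, hi = window
    if hi + omega > traj.t_max + 1e-9:
        raise ValueError(
            f"window end {hi:g} + omega {omega:g} exceeds t_max {traj.t_max:g}"
        )
    mask = _window_mask(traj.times, window)
    if not mask.any():
        raise ValueError("window contains no sample times")
    t_win = traj.times[mask]
    defect = 0.0
    for j in range(traj.states.shape[1]):
        z = traj.states[mask, j]
        z_shift = np.interp(t_win + omega, traj.times, traj.states[:, j])
        defect = max(defect, float(np.max(np.abs(z_shift - z))))
    return defect


def periodicity_defect_fields(
    sol: SpacetimeSolution, omega: float, window: tuple[float, float]
) -> float:
    """Space–time version: sup over nodes as well."""
    lo, hi = window
    if hi + omega > sol.t_max + 1e-9:
        raise ValueError("window + omega exceeds the solved horizon")
    mask = _window_mask(sol.times, window)
    t_win = sol.times[mask]
    defect = 0.0
    nt, nch, nx = sol.fields.shape
    for ch in range(nch):
        for ix in range(nx):
            z = sol.fields[mask, ch, ix]
            z_shift = np.interp(t_win + omega, sol.times, sol.fields[:, ch, ix])
            defect = max(defect, float(np.max(np.abs(z_shift - z))))
    return defect


def homogeneity_defect(
    sol: SpacetimeSolution,
    window: tuple[float, float],
    channels: tuple[str, ...] | None = None,
) -> float:
    """Sup over the window and channels of the spatial range max_x − min_x.

    ``channels`` restricts the check (e.g. ``("v1",)``); default all 8.
    """
    mask = _window_mask(sol.times, window)
    if not mask.any():
        raise ValueError("window contains no sample times")
    fields = sol.fields[mask]  # (nt, 8, nx)
    if channels is not None:
        idx = [STATE_NAMES.index(c) for c in channels]
        fields = fields[:, idx, :]
    ranges = fields.max(axis=2) - fields.min(axis=2)
    return float(ranges.max())


def empirical_permanence(
    traj: Trajectory,
    bounds: PermanenceBounds,
    tail_start: float,
    slack: float = 0.05,
) -> dict[str, dict]:
    """Check the trajectory tail against the closed-form permanence box.

    For each channel the tail range must lie inside
    ``[lower·(1−slack), upper·(1+slack)]`` where (lower, upper) are the
    permanence constants (``m_i/M_i`` for species, ``n_i/N_i`` for
    controls).  Returns a per-channel report; channels whose bounds are
    undefined are marked unchecked.
    """
    if tail_start >= traj.t_max:
        raise ValueError("tail_start must lie before the end of the trajectory")
    mask = traj.times >= tail_start
    report: dict[str, dict] = {}
    for j, name in enumerate(STATE_NAMES):
        i = int(name[1])
        lower, upper = (
            bounds.v_bounds(i) if name.startswith("v") else bounds.u_bounds(i)
        )
        tail = traj.states[mask, j]
        entry = {
            "tail_min": float(tail.min()),
            "tail_max": float(tail.max()),
            "lower": lower,
            "upper": upper,
        }
        if lower is None or upper is None:
            entry["passed"] = None  # bounds undefined, nothing to check
        else:
            lo = lower * (1.0 - slack)
            hi = upper * (1.0 + slack)
            entry["passed"] = bool(entry["tail_min"] >= lo and entry["tail_max"] <= hi)
        report[name] = entry
    return report


def attractivity_distance(
    trajA: Trajectory, trajB: Trajectory, window: tuple[float, float]
) -> float:
    """Sup-norm distance between two trajectories over a common window."""
    if trajA.times.shape != trajB.times.shape or not np.allclose(
        trajA.times, trajB.times
    ):
        raise ValueError("trajectories must share the same time grid")
    mask = _window_mask(trajA.times, window)
    if not mask.any():
        raise ValueError("window contains no sample times")
    return float(np.max(np.abs(trajA.states[mask] - trajB.states[mask])))
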