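"""Threshold-linear rate dynamics: simulation, steady states, network error.

Driven-neuron firing rates evolve as

    tau_i dy_i/dt = -y_i + relu( sum_m w_im y_m + sum_m w_im x_(m-D) ),

with the inputs held constant.  Steady states of these dynamics are exactly
the fixed points the solution-space analysis constrains.  The network error
of a weight matrix is the distance between the specified responses and the
fixed points actually reached when the dynamics are started at the
specified responses; patterns whose dynamics do not settle count as
infinite error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config_io import NetworkSpec, PatternSet, WeightMatrix
from .solution_space import relu

__all__ = ["DynamicsParams", "simulate", "network_error"]


@dataclass
class DynamicsParams:
    """Integration parameters for the rate dynamics.

    Time constants default to 1 for every neuron (steady states do not
    depend on them); Euler steps use dt = min(tau)/20 unless overridden.
    """

    tau: np.ndarray | float = 1.0
    dt: float | None = None
    t_max: float = 200.0
    convergence_tol: float = 1e-9
    divergence_ceiling: float | None = None

    def resolve(self, n_driven: int, y_scale: float) -> tuple[np.ndarray, float, float]:
        tau = np.broadcast_to(np.asarray(self.tau, dtype=float), (n_driven,)).copy()
        if np.any(tau <= 0):
            raise ValueError("time constants must be positive")
        dt = self.dt if self.dt is not None else float(tau.min()) / 20.0
        if dt >= tau.min() / 2:
            raise ValueError("dt must be below min(tau)/2")
        ceiling = (
            self.divergence_ceiling
            if self.divergence_ceiling is not None
            else 1e3 * max(1.0, y_scale)
        )
        return tau, dt, ceiling


def simulate(
    spec: NetworkSpec,
    weights: WeightMatrix,
    x_pattern: np.ndarray,
    y0: np.ndarray,
    params: DynamicsParams | None = None,
    record: bool = True,
    require_convergence: bool = True,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Integrate the rate dynamics for one input pattern.

    Returns ``(trajectory, steady_state)``; the trajectory has one row per
    recorded step (None when ``record`` is False), and the steady state is
    None if the dynamics diverge past the ceiling or fail to settle within
    the horizon.  With ``require_convergence=False`` the bounded late-time
    state is returned even when the settling criterion is not met — useful
    for marginally stable configurations whose activity drifts slowly along
    a line of fixed points.  Euler integration is finished off by direct
    fixed-point iteration once the derivative is small; the dynamics are
    piecewise linear so neither step is stiff.
    """
    params = params or DynamicsParams()
    x_pattern = np.asarray(x_pattern, dtype=float).ravel()
    y = np.asarray(y0, dtype=float).ravel().copy()
    if np.any(~np.isfinite(x_pattern)) or np.any(~np.isfinite(y)):
        raise ValueError("NaN or Inf in simulation inputs")
    D = spec.n_driven
    w = weights.w
    if not weights.respects(spec, tol=0.0):
        raise ValueError("weights do not respect the adjacency mask")
    w_rec, w_in = w[:, :D], w[:, D:]
    tau, dt, ceiling = params.resolve(D, float(np.linalg.norm(y0)))
    drive_in = w_in @ x_pattern

    n_steps = int(np.ceil(params.t_max / dt))
    traj = [y.copy()] if record else None
    converged = False
    for _ in range(n_steps):
        rhs = -y + relu(w_rec @ y + drive_in)
        y = y + dt * rhs / tau
        if record:
            traj.append(y.copy())
        if np.any(np.abs(y) > ceiling):
            return (np.array(traj) if record else None), None
        if np.max(np.abs(rhs)) < params.convergence_tol:
            converged = True
            break
    if converged:
        # polish with direct fixed-point iteration
        for _ in range(200):
            y_new = relu(w_rec @ y + drive_in)
            if np.max(np.abs(y_new - y)) < params.convergence_tol / 10:
                y = y_new
                break
            y = y_new
        return (np.array(traj) if record else None), y
    if not require_convergence:
        return (np.array(traj) if record else None), y
    return (np.array(traj) if record else None), None


def network_error(
    spec: NetworkSpec,
    weights: WeightMatrix,
    patterns: PatternSet,
    params: DynamicsParams | None = None,
    late_time: bool = False,
) -> float:
    """Distance between specified and realized fixed points, all patterns.

    For each pattern the dynamics start at the specified responses and run
    to a fixed point; a pattern that oscillates or diverges makes the error
    infinite.  With ``late_time=True`` the bounded state at the end of the
    horizon stands in for the fixed point when the settling criterion is
    not reached (divergence still counts as infinite error).
    """
    params = params or DynamicsParams()
    total = 0.0
    for mu in range(patterns.n_patterns):
        _, steady = simulate(
            spec,
            weights,
            patterns.x[mu],
            patterns.y[mu],
            params,
            record=False,
            require_convergence=not late_time,
        )
        if steady is None:
            return float("inf")
        total += float(np.sum((patterns.y[mu] - steady) ** 2))
    return float(np.sqrt(total))
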