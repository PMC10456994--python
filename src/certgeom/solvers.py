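"""Numerical verification machinery: screening, gradient fits, empirical y_cr.

These routines estimate critical response magnitudes *empirically* — by
drawing exact solutions at scaled response levels and recording where mixed
synapse signs disappear, or by fitting weight ensembles at controlled error
with gradient descent — so they serve as independent checks on the
closed-form certainty conditions rather than reusing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config_io import NetworkSpec, PatternSet, WeightMatrix, presynaptic_matrix
from .dynamics import DynamicsParams, network_error
from .geometry import DimensionLabels, FeedforwardProblem
from .solution_space import relu, sample_solutions

__all__ = [
    "ScreenResult",
    "FitResult",
    "EmpiricalYcr",
    "random_screen",
    "gradient_fit",
    "empirical_y_critical",
    "certain_fraction",
]


@dataclass
class ScreenResult:
    """Sign census across response levels from exact-solution sampling."""

    levels: np.ndarray                  # response magnitudes screened
    fractions: np.ndarray               # (levels, N, 3): pos / neg / zero
    empirical_y_cr: np.ndarray          # per synapse: largest mixed-sign level
    skipped: list[tuple[float, str]] = field(default_factory=list)


def _scaled_problem(problem: FeedforwardProblem, s: float) -> FeedforwardProblem:
    y = problem.y_target
    y_hat = y / np.linalg.norm(y)
    return FeedforwardProblem(
        z=problem.z,
        y_target=s * y_hat,
        Z=problem.Z,
        Z_inv=problem.Z_inv,
        presyn_labels=problem.presyn_labels,
        target_index=problem.target_index,
    )


def random_screen(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    W: float,
    y_grid: np.ndarray | list[float],
    n_per_level: int = 10000,
    seed: int = 0,
    sign_tol: float = 1e-9,
    n_max: int | None = None,
) -> ScreenResult:
    """Sign census of sampled exact solutions at scaled response magnitudes.

    For each level the response vector is rescaled along its own direction,
    exact solutions are sampled uniformly, and each synapse's weight signs
    are tallied.  The empirical critical magnitude of a synapse is the
    largest level at which solutions with both signs were found.  When
    ``n_max`` exceeds ``n_per_level``, the level just above each synapse's
    current estimate is re-screened with up to ``n_max`` draws, since the
    minority-sign volume shrinks to zero as the level approaches the true
    critical value and small censuses under-detect it.
    """
    if problem.n_synapses > 8:
        raise ValueError("rejection screening guarded to at most 8 synapses")
    rng = np.random.default_rng(seed)
    levels = np.asarray(list(y_grid), dtype=float)
    N = problem.n_synapses
    counts = np.zeros((len(levels), N, 3))
    totals = np.zeros(len(levels))
    skipped: list[tuple[float, str]] = []
    tol = sign_tol * max(W, 1.0)

    def census(k: int, n: int) -> None:
        scaled = _scaled_problem(problem, levels[k])
        samples = sample_solutions(scaled, labels, W, n, rng)
        ws = np.array([smp.weights for smp in samples])
        counts[k, :, 0] += np.sum(ws > tol, axis=0)
        counts[k, :, 1] += np.sum(ws < -tol, axis=0)
        counts[k, :, 2] += np.sum(np.abs(ws) <= tol, axis=0)
        totals[k] += len(samples)

    feasible = []
    for k, s in enumerate(levels):
        if s > W * (1 + 1e-12):
            skipped.append((float(s), "no solutions: level exceeds weight bound"))
            continue
        feasible.append(k)
        census(k, n_per_level)

    def mixed(k: int, m: int) -> bool:
        return counts[k, m, 0] > 0 and counts[k, m, 1] > 0

    def best_level(m: int) -> int | None:
        ks = [k for k in feasible if mixed(k, m)]
        return max(ks) if ks else None

    if n_max is not None and n_max > n_per_level:
        for m in range(N):
            while True:
                k_star = best_level(m)
                above = [k for k in feasible if k > (k_star if k_star is not None else -1)]
                if not above:
                    break
                k_next = min(above)
                found = False
                while totals[k_next] < n_max and not mixed(k_next, m):
                    census(k_next, n_per_level)
                if mixed(k_next, m):
                    found = True
                if not found:
                    break

    fractions = np.full((len(levels), N, 3), np.nan)
    for k in feasible:
        fractions[k] = counts[k] / totals[k]
    emp = np.zeros(N)
    for m in range(N):
        k_star = best_level(m)
        emp[m] = levels[k_star] if k_star is not None else 0.0
    return ScreenResult(
        levels=levels, fractions=fractions, empirical_y_cr=emp, skipped=skipped
    )


@dataclass
class FitResult:
    """One gradient-descent model with its proxy and exact errors."""

    weights: WeightMatrix
    proxy_error: float
    exact_error: float
    n_iter: int


def _row_cost_grad(
    w: np.ndarray, z: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    drive = z @ w
    resid = y - relu(drive)
    active = (drive > 0).astype(float)  # subgradient 0 at the kink
    return float(np.sum(resid**2)), -2.0 * (z.T @ (resid * active))


def _fit_row(
    z: np.ndarray,
    y: np.ndarray,
    w0: np.ndarray,
    W: float,
    target_cost: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int]:
    """Projected gradient descent with backtracking for one neuron's row."""
    w = w0.copy()
    cost, grad = _row_cost_grad(w, z, y)
    step = 0.5
    it = 0
    while cost > target_cost and it < max_iter:
        improved = False
        while step > 1e-14:
            trial = w - step * grad
            trial *= min(1.0, W / max(np.linalg.norm(trial), 1e-300))
            new_cost, new_grad = _row_cost_grad(trial, z, y)
            if new_cost < cost:
                w, cost, grad = trial, new_cost, new_grad
                step *= 1.5
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        it += 1
    return w, cost, it


def gradient_fit(
    spec: NetworkSpec,
    patterns: PatternSet,
    target_error: float,
    n_models: int,
    seed: int = 0,
    init_scale: float | None = None,
    W: float = 1.0,
    max_iter: int = 5000,
    evaluate_exact: bool = True,
    n_restarts: int = 5,
) -> list[FitResult]:
    """Fit an ensemble of weight matrices by feedforward-proxy gradient descent.

    The proxy cost treats the network as feedforward — each driven neuron's
    row is fit against its presynaptic steady-state patterns — and rows are
    projected onto the W-ball after every step.  Models start from small
    random weights (scale 0.01 W by default) and stop once the proxy error
    reaches the target; for recurrent specs the exact error is re-evaluated
    by simulating the dynamics.
    """
    rng = np.random.default_rng(seed)
    init_scale = 0.01 * W if init_scale is None else init_scale
    D = spec.n_driven
    z_list, label_list = [], []
    for i in range(D):
        z_i, labels_i = presynaptic_matrix(spec, patterns, i)
        z_list.append(z_i)
        label_list.append(labels_i)
    y_cols = [patterns.y[:, i] for i in range(D)]
    feedforward = all(np.all(lab >= D) for lab in label_list)

    # per-neuron targets: the proxy cost is separable across driven neurons
    row_target = target_error**2 / max(D, 1)
    results: list[FitResult] = []
    for _ in range(n_models):
        w_full = np.zeros((D, spec.n_neurons))
        cost = 0.0
        it = 0
        for i in range(D):
            z_i = z_list[i]
            # restarts guard against the dead-unit local minima that
            # semiconstrained dimensions induce in the proxy landscape
            best = None
            for _ in range(n_restarts):
                w0 = init_scale * rng.standard_normal(z_i.shape[1]) / np.sqrt(z_i.shape[1])
                w_i, c_i, it_i = _fit_row(z_i, y_cols[i], w0, W, row_target, max_iter)
                if best is None or c_i < best[1]:
                    best = (w_i, c_i, it_i)
                if best[1] <= row_target:
                    break
            w_i, c_i, it_i = best
            w_full[i, label_list[i]] = w_i
            cost += c_i
            it = max(it, it_i)
        wm = WeightMatrix(w=w_full)
        proxy_err = float(np.sqrt(cost))
        if evaluate_exact:
            exact = (
                proxy_err
                if feedforward
                else network_error(
                    spec, wm, patterns, DynamicsParams(), late_time=True
                )
            )
        else:
            exact = float("nan")
        results.append(
            FitResult(weights=wm, proxy_error=proxy_err, exact_error=exact, n_iter=it)
        )
    return results


def certain_fraction(
    N: int,
    P: int,
    C: int,
    n_configs: int,
    seed: int = 0,
    W: float = 1.0,
    y_norm: float | None = None,
) -> float:
    """Monte-Carlo fraction of zero-error certain synapses.

    Draws random orthonormal configurations (response norm defaulting to the
    median norm of the unit C-ball), evaluates the zero-error certainty
    condition for every synapse, and returns the mean certain fraction —
    the slope of the certain-synapse count against network size in the
    high-dimensional scaling families.
    """
    from .certainty import y_critical_all
    from .geometry import classify_dimensions
    from .synth import random_configuration

    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_configs):
        problem = random_configuration(N, P, C, rng, y_norm=y_norm)
        labels = classify_dimensions(problem.y_target, N)
        ycr = y_critical_all(problem, labels, W)
        y_mag = float(np.linalg.norm(problem.y_target))
        fractions.append(float(np.mean(y_mag > ycr)))
    return float(np.mean(fractions))


@dataclass
class EmpiricalYcr:
    """Largest mixed-sign response level in an ensemble, with bound checks."""

    estimate: float
    mixed_levels: list[float]
    violates_upper_bound: bool
    violates_no_transition: bool
    violates_linear: bool


def empirical_y_critical(
    ensemble: list[tuple[float, np.ndarray]],
    m: int,
    y_cr_max: float,
    y_cr_no_transition: float,
    y_cr_linear: float,
    sign_tol: float = 1e-9,
) -> EmpiricalYcr:
    """Estimate the noisy critical magnitude from a model ensemble.

    ``ensemble`` pairs each model's response magnitude with the target
    neuron's weight vector.  The estimate is the largest magnitude at which
    models with both synapse signs were found; exceeding the transition-aware
    upper bound is a genuine violation, while exceeding the no-transition or
    linear-theory values is expected when transitions matter and is only
    recorded.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    by_level: dict[float, set[int]] = {}
    for level, w in ensemble:
        s = 0
        if w[m] > sign_tol:
            s = 1
        elif w[m] < -sign_tol:
            s = -1
        by_level.setdefault(float(level), set()).add(s)
    mixed = sorted(lvl for lvl, signs in by_level.items() if 1 in signs and -1 in signs)
    estimate = mixed[-1] if mixed else 0.0
    return EmpiricalYcr(
        estimate=estimate,
        mixed_levels=mixed,
        violates_upper_bound=estimate > y_cr_max,
        violates_no_transition=estimate > y_cr_no_transition,
        violates_linear=estimate > y_cr_linear,
    )
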