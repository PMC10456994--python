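"""Per-synapse certainty conditions at zero and nonzero error.

A synapse is *certain* when every weight vector that reproduces the target
neuron's responses (within the weight bound ``W``, and within an error
budget ``epsilon`` when noise is allowed) carries a nonzero weight of one
consistent sign.  For orthonormal presynaptic patterns the zero-error
condition is a closed form: the response magnitude must exceed

    y_cr = W * sqrt((e_s*^2 + e_u^2) / (e_y^2 + e_s*^2 + e_u^2)),

and the certain sign is the sign of the activity correlation ``e_y``.  The
same condition solved for the weight bound gives W-critical, the bound below
which the synapse is certain at the observed response magnitude.

With noise, every nonnegative denoised response vector within ``epsilon`` of
the data must satisfy its own zero-error condition.  Zeroing a response
component opens a semiconstrained dimension — the topological transitions of
the error surface — so certainty can be lost abruptly as the budget crosses
combinations of response magnitudes.  This module provides closed-form
lower/upper bounds on the noisy critical magnitude (transition-aware) and an
exact decision procedure that minimizes the certainty margin over the
admissible denoised responses by enumerating which components vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    DimensionLabels,
    FeedforwardProblem,
    SynapseGeometry,
    classify_dimensions,
    decompose_recurrent,
    normalize_rows,
    synapse_projections,
    feedforward_problem,
    target_problem,
)
from .config_io import NetworkSpec, PatternSet

__all__ = [
    "NoiseModel",
    "CertaintyResult",
    "y_critical",
    "y_critical_all",
    "min_certainty_margin",
    "y_critical_angle_form",
    "y_critical_linear",
    "w_critical",
    "y_critical_noisy_bounds",
    "certain_with_noise_exact",
    "noisy_y_critical_scan",
    "y_critical_nonorthogonal_bound",
    "certain_synapses",
]

_TINY = 1e-30
_MARGIN_TOL = 1e-9


@dataclass
class NoiseModel:
    """Error budget and weight bound for certainty analyses."""

    epsilon: float = 0.0
    W: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("error budget must be nonnegative")
        if self.W <= 0:
            raise ValueError("weight bound must be positive")


@dataclass
class CertaintyResult:
    """Certainty verdict and critical values for one synapse."""

    neuron: int
    presyn: int
    m: int
    e_y: float
    e_sstar: float
    e_u: float
    theta: float
    phi: float
    alpha: float
    gamma: float
    y_cr: float
    y_cr_linear: float
    W_cr: float
    y_cr_min: float
    y_cr_max: float
    certain: bool
    predicted_sign: int  # +1, -1, or 0 for undetermined
    method: str
    note: str = ""
    extras: dict = field(default_factory=dict)


def y_critical(geom: SynapseGeometry, W: float) -> float:
    """Zero-error critical response magnitude (orthonormal patterns)."""
    K = geom.e_sstar**2 + geom.e_u**2
    denom = geom.e_y**2 + K
    if denom <= _TINY:
        # synapse direction fully inside the constrained data: always certain
        return 0.0
    return float(W * np.sqrt(K / denom))


def y_critical_all(
    problem: FeedforwardProblem, labels: DimensionLabels, W: float
) -> np.ndarray:
    """Vectorized zero-error critical magnitudes for every synapse at once.

    Same quantity as :func:`y_critical` over :func:`synapse_projections`,
    computed with matrix operations for large orthonormal configurations.
    """
    y = problem.y_target
    y_norm = float(np.linalg.norm(y))
    if y_norm <= 0:
        raise ValueError("no constrained dimensions; every synapse uncertain for y = 0")
    Z = problem.Z
    P = problem.n_patterns
    c_idx, s_idx = labels.constrained, labels.semiconstrained
    e_y = (y[c_idx] @ Z[c_idx, :]) / y_norm
    eu2 = np.clip(np.sum(Z[P:, :] ** 2, axis=0), 0.0, None)
    semi = Z[s_idx, :]
    sgn = np.where(e_y >= 0, 1.0, -1.0)
    es2 = np.sum(np.where(semi * sgn[None, :] > 0, semi**2, 0.0), axis=0)
    K = es2 + eu2
    denom = e_y**2 + K
    out = np.zeros(problem.n_synapses)
    ok = denom > _TINY
    out[ok] = W * np.sqrt(K[ok] / denom[ok])
    return out


def y_critical_angle_form(geom: SynapseGeometry, W: float) -> float:
    """Algebraically equivalent angle form of the zero-error condition.

    Kept as a cross-check of the projection form; the projection form is the
    primary path because it avoids trigonometric edge cases.
    """
    ct2 = np.cos(geom.theta) ** 2
    st2 = np.sin(geom.theta) ** 2
    cp2 = np.cos(geom.phi) ** 2
    sp2 = np.sin(geom.phi) ** 2
    cg2 = np.cos(geom.gamma) ** 2
    ca2 = np.cos(geom.alpha) ** 2
    num = cg2 * st2 * cp2 + st2 * sp2
    den = ca2 * ct2 + num
    if den <= _TINY:
        return 0.0
    return float(W * np.sqrt(num / den))


def y_critical_linear(geom: SynapseGeometry, W: float) -> float:
    """Critical magnitude if the network were linear (no semiconstrained help)."""
    denom = geom.e_y**2 + geom.e_u**2
    if denom <= _TINY:
        return 0.0
    return float(W * np.sqrt(geom.e_u**2 / denom))


def w_critical(geom: SynapseGeometry, y_norm: float) -> float:
    """Weight bound below which the synapse is certain at magnitude ``y_norm``.

    Inverse of :func:`y_critical` in ``W``; unbounded when the synapse
    direction has no projection outside the constrained data.
    """
    K = geom.e_sstar**2 + geom.e_u**2
    if K <= _TINY:
        return float("inf")
    return float(y_norm * np.sqrt((geom.e_y**2 + K) / K))


def _bound_terms(ey2: float, es2: float, eu2: float, ep2: float, W: float, eps: float) -> tuple[float, float]:
    """Closed-form (lower, upper) noisy critical values, no transitions."""
    K = es2 + eu2
    denom = ey2 + K
    if denom <= _TINY:
        A, B = 0.0, 0.0
    else:
        A = K / denom
        B = ey2 * max(ep2 - ey2, 0.0) / denom**2
    t = eps / W
    lo = W * min(1.0, np.sqrt(A) + t)
    hi = W * min(1.0, np.sqrt(A) + t**2 * (1.0 + B) + t * np.sqrt(1.0 + B))
    return float(lo), float(hi)


def _admissible_subsets(values: np.ndarray, budget: float, cap: int = 1 << 20):
    """Index subsets of ``values`` with root-sum-square at most ``budget``.

    Enumerated in increasing cost with pruning; raises if the cap is hit.
    """
    order = np.argsort(values)
    vals = values[order]
    n = len(vals)
    out = [((), 0.0)]
    budget2 = budget**2 * (1 + 1e-12)
    stack = [((), 0.0, 0)]
    while stack:
        subset, cost2, start = stack.pop()
        for j in range(start, n):
            c2 = cost2 + vals[j] ** 2
            if c2 > budget2:
                break  # values sorted: later ones only cost more
            new = subset + (j,)
            out.append((new, c2))
            if len(out) > cap:
                raise RuntimeError("transition subset cap exceeded")
            stack.append((new, c2, j + 1))
    return [
        (tuple(int(order[j]) for j in subset), np.sqrt(c2))
        for subset, c2 in out
    ]


def _transition_bound_at(
    geom: SynapseGeometry,
    y_hat_c: np.ndarray,
    s: float,
    noise: NoiseModel,
    which: str,
) -> float:
    """Transition-aware closed-form bound at response magnitude ``s``.

    Maximum over admissible subsets T of constrained indices (cost of
    zeroing within the budget) of the no-transition bound recomputed with
    T's dimensions moved to the semiconstrained side and the residual budget.
    Returned as a threshold on the full response norm, capped at ``W``.
    """
    col = geom.basis_components
    c_idx = geom.constrained_idx
    s_idx = geom.semiconstrained_idx
    eu2 = geom.e_u**2
    ep2 = geom.e_p**2
    W, eps = noise.W, noise.epsilon
    semi_cols = col[s_idx]

    best = 0.0
    for subset, cost in _admissible_subsets(s * y_hat_c, eps):
        eps_res = float(np.sqrt(max(eps**2 - cost**2, 0.0)))
        keep = np.setdiff1d(np.arange(len(c_idx)), np.array(subset, dtype=int))
        y_keep = s * y_hat_c[keep]
        rnorm = float(np.linalg.norm(y_keep))
        if rnorm <= _TINY:
            best = max(best, W)
            continue
        cols_keep = col[c_idx[keep]]
        ey = float(np.dot(y_keep, cols_keep)) / rnorm
        sgn = 1.0 if ey >= 0 else -1.0
        moved = col[c_idx[np.array(subset, dtype=int)]] if subset else np.array([])
        es2 = float(np.sum(semi_cols[semi_cols * sgn > 0] ** 2))
        if moved.size:
            es2 += float(np.sum(moved[moved * sgn > 0] ** 2))
        lo, hi = _bound_terms(ey**2, es2, eu2, ep2, W, eps_res)
        term = lo if which == "lower" else hi
        best = max(best, min(W, float(np.sqrt(term**2 + cost**2))))
    return min(best, W)


def y_critical_noisy_bounds(
    geom: SynapseGeometry,
    y_target: np.ndarray,
    noise: NoiseModel,
) -> tuple[float, float]:
    """Lower and upper bounds on the noisy critical response magnitude.

    The bounds are computed self-consistently along the ray of response
    vectors with the direction of ``y_target``: at a candidate magnitude
    ``s`` the admissible topological transitions are those whose zeroing
    cost fits the budget *at that magnitude*, and the returned value is the
    magnitude above which the (lower/upper) closed-form condition certifies
    the synapse.  At ``epsilon = 0`` both bounds equal :func:`y_critical`.
    """
    if noise.epsilon < 0:
        raise ValueError("error budget must be nonnegative")
    y = np.asarray(y_target, dtype=float).ravel()
    y_c = y[geom.constrained_idx]
    y_norm = float(np.linalg.norm(y_c))
    if y_norm <= 0:
        return noise.W, noise.W
    y_hat_c = y_c / y_norm
    if noise.epsilon == 0.0:
        ycr = y_critical(geom, noise.W)
        return ycr, ycr

    def threshold(which: str) -> float:
        g = lambda s: s - _transition_bound_at(geom, y_hat_c, s, noise, which)
        hi = noise.W
        if g(hi) < 0:
            return noise.W
        lo = 1e-12
        if g(lo) >= 0:
            return 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        return hi

    lo = threshold("lower")
    hi = threshold("upper")
    return min(lo, hi), hi


def _min_margin_subproblem(
    cf: np.ndarray,
    y_free: np.ndarray,
    K: float,
    budget: float,
    sigma: float,
    W: float,
) -> float:
    """Minimize  |v| - W*sqrt(K/((v.cf)^2/|v|^2 + K))  over the admissible set.

    v ranges over {v >= 0, |v - y_free| <= budget, sigma*(v.cf) >= 0}; the
    second factor is the zero-error critical value of the denoised response
    ``v`` on the branch where the activity correlation has sign ``sigma``.
    """
    F = len(y_free)
    if F == 0:
        return -W if K > 0 else 0.0
    cn0 = float(np.linalg.norm(cf))
    # branch infeasible when sigma*(v.cf) cannot reach zero inside the ball
    if sigma * float(np.dot(y_free, cf)) + budget * cn0 < 0:
        return np.inf
    if K <= _TINY:
        # critical value is 0 on this branch: margin is just the norm
        return float(max(np.linalg.norm(y_free) - budget, 0.0))

    def margin(v: np.ndarray) -> float:
        r = max(float(np.linalg.norm(v)), 1e-12)
        t = float(np.dot(v, cf))
        q = (t / r) ** 2
        return r - W * np.sqrt(K / (q + K))

    def margin_jac(v: np.ndarray) -> np.ndarray:
        r = max(float(np.linalg.norm(v)), 1e-12)
        t = float(np.dot(v, cf))
        q = (t / r) ** 2
        dq = 2.0 * t * cf / r**2 - 2.0 * t**2 * v / r**4
        return v / r + 0.5 * W * np.sqrt(K) * (q + K) ** -1.5 * dq

    cons = [
        {
            "type": "ineq",
            "fun": lambda v: budget**2 - float(np.sum((v - y_free) ** 2)),
            "jac": lambda v: -2.0 * (v - y_free),
        },
        {
            "type": "ineq",
            "fun": lambda v: sigma * float(np.dot(v, cf)),
            "jac": lambda v: sigma * cf,
        },
    ]
    bounds = [(0.0, None)] * F

    def clip_to_ball(v: np.ndarray) -> np.ndarray:
        v = np.clip(v, 0.0, None)
        d = v - y_free
        n = np.linalg.norm(d)
        if n > budget:
            v = y_free + d * (budget / n) * 0.999
            v = np.clip(v, 0.0, None)
        return v

    cn = np.linalg.norm(cf)
    starts = [y_free.copy()]
    if cn > 0:
        starts.append(clip_to_ball(y_free - budget * sigma * cf / cn))
        starts.append(clip_to_ball(y_free + budget * sigma * cf / cn))
        starts.append(clip_to_ball(y_free - 0.5 * budget * sigma * cf / cn))
    starts.append(clip_to_ball(y_free * max(1.0 - budget / max(np.linalg.norm(y_free), 1e-12), 0.0)))

    def feasible(v: np.ndarray) -> bool:
        return (
            np.all(v >= -1e-12)
            and np.sum((v - y_free) ** 2) <= budget**2 * (1 + 1e-8) + 1e-14
            and sigma * np.dot(v, cf) >= -1e-9 * max(cn, 1.0)
        )

    best = np.inf
    for v0 in starts:
        if sigma * np.dot(v0, cf) < -1e-12 * max(cn, 1.0):
            v0 = clip_to_ball(v0 - (np.dot(v0, cf) / max(cn**2, _TINY)) * cf)
        res = minimize(
            margin,
            v0,
            jac=margin_jac,
            bounds=bounds,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-12},
        )
        v = np.clip(res.x, 0.0, None)
        if feasible(v):
            best = min(best, margin(v))
        if best < -1e-7:
            break
    if not np.isfinite(best):
        # optimizer never produced a feasible point: repair the center onto
        # the sign constraint and evaluate there, or concede the branch
        t0 = float(np.dot(y_free, cf))
        v = clip_to_ball(y_free - (min(sigma * t0, 0.0) * sigma / max(cn**2, _TINY)) * cf)
        if feasible(v):
            best = margin(v)
    return float(best)


def min_certainty_margin(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    m: int,
    noise: NoiseModel,
    subset_cap: int = 1 << 20,
) -> tuple[float, bool]:
    """Minimum of  |y~| - y_cr(y~)  over admissible denoised responses.

    Enumerates every subset of pattern indices whose responses are pinned to
    zero (each pinned component opens a semiconstrained dimension, so the
    topological transitions arise automatically) and solves the smooth
    subproblem over the remaining components.  Returns ``(margin, capped)``
    where ``capped`` reports whether the subset cap was hit.
    """
    y = problem.y_target
    P = problem.n_patterns
    col = problem.Z[:, m]
    eps, W = noise.epsilon, noise.W
    y_norm = float(np.linalg.norm(y))
    if eps >= y_norm:
        return -W, False  # the zero response vector is admissible
    eu2 = float(np.sum(col[P:] ** 2))

    capped = False
    try:
        subsets = _admissible_subsets(np.abs(y), eps, cap=subset_cap)
    except RuntimeError:
        capped = True
        subsets = [((), 0.0)]

    best = np.inf
    for subset, cost in subsets:
        budget = float(np.sqrt(max(eps**2 - cost**2, 0.0)))
        pinned = set(subset)
        free = np.array([i for i in range(P) if i not in pinned], dtype=int)
        pin_arr = np.array(sorted(pinned), dtype=int)
        for sigma in (1.0, -1.0):
            K = eu2
            if pin_arr.size:
                pc = col[pin_arr]
                K += float(np.sum(pc[pc * sigma > 0] ** 2))
            best = min(
                best,
                _min_margin_subproblem(
                    col[free], y[free], K, budget, sigma, W
                ),
            )
            if best < -1e-7:
                return float(best), capped
    return float(best), capped


def certain_with_noise_exact(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    m: int,
    noise: NoiseModel,
) -> CertaintyResult:
    """Exact noisy certainty decision for synapse ``m`` (orthonormal patterns).

    Certain iff every nonnegative denoised response vector within the error
    budget satisfies its zero-error certainty condition, decided by
    minimizing the certainty margin over the budget ball.
    """
    geom = synapse_projections(problem, labels, m)
    margin, capped = min_certainty_margin(problem, labels, m, noise)
    certain = margin > _MARGIN_TOL and not capped
    ycr = y_critical(geom, noise.W)
    lo, hi = y_critical_noisy_bounds(geom, problem.y_target, noise)
    sign = int(np.sign(geom.e_y)) if certain else 0
    return CertaintyResult(
        neuron=problem.target_index if problem.target_index is not None else 0,
        presyn=int(problem.presyn_labels[m]),
        m=m,
        e_y=geom.e_y,
        e_sstar=geom.e_sstar,
        e_u=geom.e_u,
        theta=geom.theta,
        phi=geom.phi,
        alpha=geom.alpha,
        gamma=geom.gamma,
        y_cr=ycr,
        y_cr_linear=y_critical_linear(geom, noise.W),
        W_cr=w_critical(geom, float(np.linalg.norm(problem.y_target))),
        y_cr_min=lo,
        y_cr_max=hi,
        certain=certain,
        predicted_sign=sign,
        method="noisy_exact",
        note="bound-only: subset cap hit" if capped else "",
        extras={"min_margin": margin},
    )


def noisy_y_critical_scan(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    m: int,
    noise: NoiseModel,
    tol: float = 1e-3,
) -> float:
    """Empirical noisy critical magnitude via bisection on the exact decision.

    Scales the response vector along its own direction and locates the
    magnitude where the exact margin test flips from uncertain to certain.
    """
    y = problem.y_target
    y_norm = float(np.linalg.norm(y))
    if y_norm <= 0:
        return noise.W
    y_hat = y / y_norm

    def certain_at(s: float) -> bool:
        scaled = FeedforwardProblem(
            z=problem.z,
            y_target=s * y_hat,
            Z=problem.Z,
            Z_inv=problem.Z_inv,
            presyn_labels=problem.presyn_labels,
            target_index=problem.target_index,
        )
        margin, _ = min_certainty_margin(scaled, labels, m, noise)
        return margin > _MARGIN_TOL

    hi = noise.W
    if not certain_at(hi):
        return noise.W
    lo = max(noise.epsilon, 1e-9)
    if certain_at(lo * (1 + 1e-9)):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if certain_at(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def y_critical_nonorthogonal_bound(
    problem: FeedforwardProblem, m: int, W: float
) -> float:
    """Conservative critical magnitude for linearly independent patterns.

    The weight-norm ball maps to an ellipsoid in eta coordinates; enclosing
    it in the sphere of radius ``W * sigma_max(Z)`` and applying the
    orthonormal formula to the unit normal of the ``w_m = 0`` hyperplane in
    eta coordinates yields a magnitude above which all solutions inside the
    encompassing sphere — hence all true solutions — share the synapse sign.
    Reduces exactly to :func:`y_critical` for orthonormal patterns.  Capped
    at ``W``; a value of ``W`` means the synapse cannot be certified within
    the bound.
    """
    svals = np.linalg.svd(problem.Z, compute_uv=False)
    if svals[-1] <= 1e-12 * svals[0]:
        raise ValueError("singular pattern matrix")
    nu = problem.Z_inv[m, :].astype(float)
    nu_hat = nu / np.linalg.norm(nu)
    labels = classify_dimensions(problem.y_target, problem.n_synapses)
    y = problem.y_target
    y_norm = float(np.linalg.norm(y))
    if y_norm <= 0:
        raise ValueError("no constrained dimensions; every synapse uncertain for y = 0")
    c_idx, s_idx, u_idx = labels.constrained, labels.semiconstrained, labels.unconstrained
    e_y = float(np.dot(y[c_idx], nu_hat[c_idx])) / y_norm
    sgn = 1.0 if e_y >= 0 else -1.0
    semi = nu_hat[s_idx]
    es2 = float(np.sum(semi[semi * sgn > 0] ** 2))
    eu2 = float(np.sum(nu_hat[u_idx] ** 2))
    K = es2 + eu2
    denom = e_y**2 + K
    if denom <= _TINY:
        return 0.0
    return float(min(W * svals[0] * np.sqrt(K / denom), W))


def _result_from_geometry(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    m: int,
    noise: NoiseModel,
    method: str,
) -> CertaintyResult:
    geom = synapse_projections(problem, labels, m)
    y_norm = float(np.linalg.norm(problem.y_target))
    ycr = y_critical(geom, noise.W)
    if noise.epsilon > 0:
        lo, hi = y_critical_noisy_bounds(geom, problem.y_target, noise)
    else:
        lo = hi = ycr
    certain = y_norm > hi and noise.W >= y_norm
    note = ""
    if noise.W < y_norm:
        certain = False
        note = "no solutions within weight bound"
    sign = int(np.sign(geom.e_y)) if certain else 0
    return CertaintyResult(
        neuron=problem.target_index if problem.target_index is not None else 0,
        presyn=int(problem.presyn_labels[m]),
        m=m,
        e_y=geom.e_y,
        e_sstar=geom.e_sstar,
        e_u=geom.e_u,
        theta=geom.theta,
        phi=geom.phi,
        alpha=geom.alpha,
        gamma=geom.gamma,
        y_cr=ycr,
        y_cr_linear=y_critical_linear(geom, noise.W),
        W_cr=w_critical(geom, y_norm),
        y_cr_min=lo,
        y_cr_max=hi,
        certain=certain,
        predicted_sign=sign,
        method=method,
        note=note,
    )


def certain_synapses(
    spec: NetworkSpec,
    patterns: PatternSet,
    noise: NoiseModel,
    method: str = "auto",
    orthonormal_tol: float = 1e-8,
) -> list[CertaintyResult]:
    """Certainty results for every permitted synapse of every driven neuron.

    Each driven neuron is analyzed through its own feedforward problem
    (self-synapses are columns like any other).  Orthonormal — or orthogonal,
    after exact row rescaling — presynaptic patterns take the exact path;
    otherwise the conservative encompassing-sphere bound is used.
    """
    if method not in ("auto", "exact", "bounds", "conservative"):
        raise ValueError(f"unknown method {method!r}")
    results: list[CertaintyResult] = []
    problems: list = []
    for i in range(spec.n_driven):
        try:
            problems.append(target_problem(spec, patterns, i))
        except ValueError as exc:
            # degenerate per-neuron problem (e.g. rank-deficient patterns):
            # record the failure for its synapses instead of aborting the run
            from .config_io import presynaptic_indices

            for m, presyn in enumerate(presynaptic_indices(spec, i)):
                results.append(
                    CertaintyResult(
                        neuron=i, presyn=int(presyn), m=m,
                        e_y=float("nan"), e_sstar=float("nan"), e_u=float("nan"),
                        theta=float("nan"), phi=float("nan"),
                        alpha=float("nan"), gamma=float("nan"),
                        y_cr=float("nan"), y_cr_linear=float("nan"),
                        W_cr=float("nan"), y_cr_min=float("nan"),
                        y_cr_max=float("nan"),
                        certain=False, predicted_sign=0,
                        method="unavailable", note=str(exc),
                    )
                )
    for problem in problems:
        P, N = problem.n_patterns, problem.n_synapses
        gram = problem.z @ problem.z.T
        off = gram - np.diag(np.diag(gram))
        orthogonal = np.max(np.abs(off)) <= orthonormal_tol * max(1.0, float(np.max(np.abs(gram))))
        use_exact = orthogonal and method != "conservative"
        if use_exact and not problem.is_orthonormal(orthonormal_tol):
            z_n, y_n = normalize_rows(problem.z, problem.y_target)
            presyn = problem.presyn_labels
            problem = feedforward_problem(z_n, y_n, problem.target_index)
            problem.presyn_labels = presyn
        if use_exact:
            y_norm = float(np.linalg.norm(problem.y_target))
            if y_norm <= 0:
                for m in range(N):
                    results.append(
                        CertaintyResult(
                            neuron=problem.target_index or 0,
                            presyn=int(problem.presyn_labels[m]),
                            m=m,
                            e_y=0.0, e_sstar=0.0, e_u=0.0,
                            theta=0.0, phi=0.0, alpha=0.0, gamma=0.0,
                            y_cr=noise.W, y_cr_linear=noise.W,
                            W_cr=0.0, y_cr_min=noise.W, y_cr_max=noise.W,
                            certain=False, predicted_sign=0,
                            method="orthonormal_exact",
                            note="all-zero responses: no certain synapses",
                        )
                    )
                continue
            labels = classify_dimensions(problem.y_target, N)
            for m in range(N):
                if method == "exact" and noise.epsilon > 0:
                    results.append(
                        certain_with_noise_exact(problem, labels, m, noise)
                    )
                else:
                    path = "orthonormal_exact" if noise.epsilon == 0 else "noisy_bound"
                    results.append(
                        _result_from_geometry(problem, labels, m, noise, path)
                    )
        else:
            y_norm = float(np.linalg.norm(problem.y_target))
            for m in range(N):
                if y_norm <= 0:
                    bound = noise.W
                else:
                    bound = y_critical_nonorthogonal_bound(problem, m, noise.W)
                certain = noise.epsilon == 0 and 0 < y_norm and y_norm > bound and noise.W >= y_norm
                nu_hat = problem.Z_inv[m, :] / np.linalg.norm(problem.Z_inv[m, :])
                e_y = float(np.dot(problem.y_target, nu_hat[:P]) / y_norm) if y_norm > 0 else 0.0
                note = "conservative bound; noise not supported on this path" if noise.epsilon > 0 else ""
                results.append(
                    CertaintyResult(
                        neuron=problem.target_index or 0,
                        presyn=int(problem.presyn_labels[m]),
                        m=m,
                        e_y=e_y, e_sstar=float("nan"), e_u=float("nan"),
                        theta=float("nan"), phi=float("nan"),
                        alpha=float("nan"), gamma=float("nan"),
                        y_cr=bound,
                        y_cr_linear=float("nan"),
                        W_cr=float("nan"),
                        y_cr_min=bound, y_cr_max=bound,
                        certain=bool(certain),
                        predicted_sign=int(np.sign(e_y)) if certain else 0,
                        method="nonorthogonal_conservative",
                        note=note,
                    )
                )
    return results
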