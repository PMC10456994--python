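"""The exact solution space: sampling, membership, and error-surface events.

In eta coordinates the zero-error solution space of one target neuron is a
product of a point (constrained coordinates pinned to the responses), a
nonpositive orthant (semiconstrained coordinates), and a free subspace
(unconstrained coordinates), intersected with the image of the weight-norm
ball.  Sampling is uniform over that region; membership is a per-coordinate
check.  As the tolerated error grows, semi-infinite cylinders open along
semiconstrained directions whenever the error can absorb a response
component — the transition schedule lists those error levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DimensionLabels, FeedforwardProblem

__all__ = [
    "SolutionSample",
    "TransitionSchedule",
    "sample_solutions",
    "contains",
    "transition_errors",
    "feedforward_error",
    "relu",
]


def relu(s: np.ndarray | float) -> np.ndarray | float:
    """Threshold-linear transfer function max(0, s)."""
    return np.maximum(0.0, s)


@dataclass
class SolutionSample:
    """One weight vector from the solution space, with its eta coordinates."""

    weights: np.ndarray
    eta: np.ndarray
    norm: float


@dataclass
class TransitionSchedule:
    """Sorted topological-transition error levels of the error surface."""

    events: list[tuple[float, frozenset[int]]]

    def levels(self) -> np.ndarray:
        return np.array([e for e, _ in self.events])


def _uniform_ball(rng: np.random.Generator, n: int, dim: int, radius: float) -> np.ndarray:
    g = rng.standard_normal((n, dim))
    g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-300)
    r = radius * rng.random(n) ** (1.0 / dim)
    return g * r[:, None]


def sample_solutions(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    W: float,
    n: int,
    seed: int | np.random.Generator = 0,
    gibbs_threshold: int = 20,
) -> list[SolutionSample]:
    """Draw ``n`` weight vectors uniformly from the exact solution space.

    Constrained eta coordinates are fixed at the responses; the free
    (semiconstrained + unconstrained) coordinates are drawn uniformly from
    the intersection of the nonpositive-semiconstrained region with the
    ellipsoid that the weight-norm ball induces in eta coordinates (a ball
    when the patterns are orthonormal).  Rejection sampling is used up to
    ``gibbs_threshold`` semiconstrained dimensions; beyond that a seeded
    Gibbs sweep over the free coordinates takes over.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = problem.y_target
    c_idx = labels.constrained
    free_idx = np.concatenate([labels.semiconstrained, labels.unconstrained]).astype(int)
    semi_mask = np.array(
        [i in set(labels.semiconstrained.tolist()) for i in free_idx], dtype=bool
    )
    y_c = y[c_idx]
    V = problem.Z_inv[:, free_idx]
    w0 = problem.Z_inv[:, c_idx] @ y_c if len(c_idx) else np.zeros(problem.n_synapses)
    F = len(free_idx)
    if F == 0:
        if np.linalg.norm(w0) > W * (1 + 1e-12):
            raise ValueError("no solutions within weight bound")
        w = w0
        eta = problem.to_eta(w)
        return [SolutionSample(weights=w.copy(), eta=eta, norm=float(np.linalg.norm(w)))] * n

    M = V.T @ V
    b = V.T @ w0
    f_center = -np.linalg.solve(M, b)
    rho2 = W**2 - float(w0 @ w0) - float(b @ f_center)
    if rho2 < -1e-12:
        raise ValueError("no solutions within weight bound")
    rho = float(np.sqrt(max(rho2, 0.0)))
    R = np.linalg.cholesky(M).T  # M = R^T R; f = f_center + R^{-1} g, |g| <= rho

    samples: list[SolutionSample] = []
    n_semi = int(semi_mask.sum())
    # zero-tolerance for the semiconstrained sign check: a degenerate
    # residual region (W at the feasibility boundary) otherwise rejects
    # its single point forever through rounding residue
    sign_slack = 1e-12 * max(W, 1.0)
    if n_semi <= gibbs_threshold:
        empty_batches = 0
        while len(samples) < n:
            if empty_batches > 500:
                raise RuntimeError(
                    "sampling failed: acceptance region empty or vanishingly small"
                )
            batch = max(64, 2 * (n - len(samples)) * (2**n_semi if n_semi < 16 else 1 << 16))
            batch = min(batch, 1 << 18)
            g = _uniform_ball(rng, batch, F, rho)
            f = f_center[None, :] + np.linalg.solve(R, g.T).T
            ok = (
                np.all(f[:, semi_mask] <= sign_slack, axis=1)
                if n_semi
                else np.ones(batch, bool)
            )
            empty_batches = 0 if np.any(ok) else empty_batches + 1
            for fv in f[ok][: n - len(samples)]:
                fv = fv.copy()
                fv[semi_mask] = np.minimum(fv[semi_mask], 0.0)
                w = w0 + V @ fv
                eta = np.zeros(problem.n_synapses)
                eta[c_idx] = y_c
                eta[free_idx] = fv
                samples.append(
                    SolutionSample(weights=w, eta=eta, norm=float(np.linalg.norm(w)))
                )
    else:
        # Gibbs sweeps over f coordinates; each conditional is a uniform draw
        # from an interval cut out of the ellipsoid (and the nonpositive
        # half-line for semiconstrained coordinates).
        f = np.minimum(f_center.copy(), np.where(semi_mask, -1e-9 * rho, np.inf))
        A = M
        c0 = float(w0 @ w0) - W**2

        def interval(fv: np.ndarray, j: int) -> tuple[float, float]:
            a = A[j, j]
            rest = np.delete(np.arange(F), j)
            bj = 2 * b[j] + 2 * float(A[j, rest] @ fv[rest])
            cj = c0 + 2 * float(b[rest] @ fv[rest]) + float(fv[rest] @ A[np.ix_(rest, rest)] @ fv[rest])
            disc = bj**2 - 4 * a * cj
            if disc <= 0:
                return fv[j], fv[j]
            root = np.sqrt(disc)
            lo, hi = (-bj - root) / (2 * a), (-bj + root) / (2 * a)
            if semi_mask[j]:
                hi = min(hi, 0.0)
            return lo, hi

        burn, thin = 100, 5
        total = burn + thin * n
        for sweep in range(total):
            for j in range(F):
                lo, hi = interval(f, j)
                f[j] = lo + (hi - lo) * rng.random() if hi > lo else min(hi, f[j])
            if sweep >= burn and (sweep - burn) % thin == 0:
                w = w0 + V @ f
                eta = np.zeros(problem.n_synapses)
                eta[c_idx] = y_c
                eta[free_idx] = f.copy()
                samples.append(
                    SolutionSample(weights=w, eta=eta, norm=float(np.linalg.norm(w)))
                )
    return samples[:n]


def contains(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    w: np.ndarray,
    W: float,
    tol: float = 1e-8,
) -> bool:
    """True iff ``w`` reproduces the responses exactly and fits the bound."""
    w = np.asarray(w, dtype=float).ravel()
    if np.linalg.norm(w) > W * (1 + tol) + tol:
        return False
    eta = problem.to_eta(w)
    y = problem.y_target
    for mu in labels.constrained:
        if abs(eta[mu] - y[mu]) > tol:
            return False
    for mu in labels.semiconstrained:
        if eta[mu] > tol:
            return False
    return True


def transition_errors(
    y_target: np.ndarray,
    ceiling: float | None = None,
    tol: float = 1e-12,
    cap: int = 1 << 20,
) -> TransitionSchedule:
    """Error levels at which the error surface changes topology.

    Every subset of positive response indices can be zeroed once the error
    budget covers its root-sum-square cost; zero responses are
    semiconstrained already at zero error, and negative responses (possible
    only for noisy data) must all be absorbed before any solution exists,
    contributing a feasibility offset to every event.
    """
    y = np.asarray(y_target, dtype=float).ravel()
    pos = np.flatnonzero(y > tol)
    neg = np.flatnonzero(y < -tol)
    zero = np.flatnonzero(np.abs(y) <= tol)
    base = frozenset(int(i) for i in neg)
    offset2 = float(np.sum(y[neg] ** 2))

    events: list[tuple[float, frozenset[int]]] = [
        (0.0, frozenset({int(i)})) for i in zero
    ]
    if base:
        events.append((float(np.sqrt(offset2)), base))

    limit = np.inf if ceiling is None else float(ceiling)
    vals = y[pos]
    order = np.argsort(vals)
    sorted_vals = vals[order]
    sorted_idx = pos[order]
    count = 0
    stack: list[tuple[tuple[int, ...], float, int]] = [((), 0.0, 0)]
    while stack:
        subset, cost2, start = stack.pop()
        for j in range(start, len(sorted_vals)):
            c2 = cost2 + sorted_vals[j] ** 2
            level = float(np.sqrt(offset2 + c2))
            if level > limit * (1 + 1e-12):
                break
            new = subset + (j,)
            count += 1
            if count > cap:
                raise RuntimeError("transition subset cap exceeded")
            events.append(
                (level, base | frozenset(int(sorted_idx[k]) for k in new))
            )
            stack.append((new, c2, j + 1))

    events.sort(key=lambda e: (e[0], len(e[1]), sorted(e[1])))
    return TransitionSchedule(events=events)


def feedforward_error(problem: FeedforwardProblem, w: np.ndarray) -> float:
    """Distance between specified and realized responses, feedforward case."""
    w = np.asarray(w, dtype=float).ravel()
    realized = relu(problem.z @ w)
    return float(np.sqrt(np.sum((problem.y_target - realized) ** 2)))
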