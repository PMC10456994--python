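"""Weight-space geometry of one target neuron at a time.

A recurrent steady-state inference problem decouples into one feedforward
problem per driven neuron: the target's P responses constrain only its own
incoming weight vector, driven by the steady-state activities of its
presynaptic partners.  Extending the P x N presynaptic pattern matrix ``z``
to a full-rank N x N matrix ``Z`` defines eta coordinates ``eta = Z w`` in
which the fixed-point constraints act one coordinate at a time:

* constrained   (response > 0):   eta_mu = y_mu
* semiconstrained (response = 0): eta_mu <= 0
* unconstrained (mu > P):         eta_mu free

Per-synapse certainty is then governed by a handful of projections of the
synapse's physical basis direction e_m (whose eta-basis components are the
m-th column of ``Z``): the signed correlation ``e_y`` with the response
direction, the unconstrained-mass ``e_u``, and the adverse semiconstrained
mass ``e_s*`` — the activity the presynaptic neuron showed, with the same
sign as its overall response correlation, in patterns where the target was
silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .config_io import NetworkSpec, PatternSet, presynaptic_matrix

__all__ = [
    "FeedforwardProblem",
    "DimensionLabels",
    "SynapseGeometry",
    "decompose_recurrent",
    "feedforward_problem",
    "target_problem",
    "extend_to_full_rank",
    "classify_dimensions",
    "synapse_projections",
    "normalize_rows",
]

_CONSTRAINED = "constrained"
_SEMI = "semiconstrained"
_FREE = "unconstrained"


@dataclass
class FeedforwardProblem:
    """One target neuron's presynaptic patterns, responses and eta basis."""

    z: np.ndarray          # (P, N) presynaptic steady-state patterns
    y_target: np.ndarray   # (P,) target responses
    Z: np.ndarray          # (N, N) full-rank extension of z
    Z_inv: np.ndarray      # inverse of Z
    presyn_labels: np.ndarray  # global neuron index per column
    target_index: int | None = None

    @property
    def n_patterns(self) -> int:
        return self.z.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.z.shape[1]

    def is_orthonormal(self, tol: float = 1e-8) -> bool:
        P = self.n_patterns
        return bool(np.max(np.abs(self.z @ self.z.T - np.eye(P))) <= tol)

    def to_eta(self, w: np.ndarray) -> np.ndarray:
        return self.Z @ np.asarray(w, dtype=float)

    def from_eta(self, eta: np.ndarray) -> np.ndarray:
        return self.Z_inv @ np.asarray(eta, dtype=float)


@dataclass
class DimensionLabels:
    """Trichotomy of the eta coordinates for one target neuron."""

    labels: list[str]  # per eta index

    @property
    def constrained(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == _CONSTRAINED], dtype=int)

    @property
    def semiconstrained(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == _SEMI], dtype=int)

    @property
    def unconstrained(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == _FREE], dtype=int)

    @property
    def n_constrained(self) -> int:
        return len(self.constrained)

    @property
    def n_semiconstrained(self) -> int:
        return len(self.semiconstrained)

    @property
    def n_unconstrained(self) -> int:
        return len(self.unconstrained)


@dataclass
class SynapseGeometry:
    """Projections and angles of one synapse's physical basis direction."""

    m: int
    basis_components: np.ndarray  # eta-basis components of e_m (column m of Z)
    e_y: float       # signed projection onto the response direction
    e_sstar: float   # magnitude of the adverse semiconstrained projection
    e_u: float       # magnitude of the unconstrained projection
    e_p: float       # projection into the activity-constrained subspace
    theta: float
    phi: float
    alpha: float
    gamma: float
    r_y: float
    r_sstar: float
    sprime_components: np.ndarray  # s-hat' over semiconstrained indices
    constrained_idx: np.ndarray
    semiconstrained_idx: np.ndarray
    unconstrained_idx: np.ndarray


def feedforward_problem(
    x: np.ndarray, y_target: np.ndarray, target_index: int | None = None
) -> FeedforwardProblem:
    """Build a FeedforwardProblem directly from a pattern matrix ``x``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y_target = np.asarray(y_target, dtype=float).ravel()
    if y_target.shape[0] != x.shape[0]:
        raise ValueError("dimension mismatch between patterns and responses")
    Z, Z_inv = extend_to_full_rank(x)
    return FeedforwardProblem(
        z=x,
        y_target=y_target,
        Z=Z,
        Z_inv=Z_inv,
        presyn_labels=np.arange(x.shape[1]),
        target_index=target_index,
    )


def target_problem(
    spec: NetworkSpec, patterns: PatternSet, i: int
) -> FeedforwardProblem:
    """The feedforward problem of a single driven neuron ``i``.

    Useful when only one neuron's presynaptic patterns have the structure
    an analysis needs (e.g. orthonormality) and the other neurons' problems
    may be degenerate.
    """
    z, labels = presynaptic_matrix(spec, patterns, i)
    if patterns.n_patterns > z.shape[1]:
        raise ValueError(
            f"underdetermined regime not supported: neuron {i} has "
            f"{z.shape[1]} synapses for {patterns.n_patterns} patterns"
        )
    Z, Z_inv = extend_to_full_rank(z)
    return FeedforwardProblem(
        z=z,
        y_target=patterns.y[:, i].copy(),
        Z=Z,
        Z_inv=Z_inv,
        presyn_labels=labels,
        target_index=i,
    )


def decompose_recurrent(
    spec: NetworkSpec, patterns: PatternSet
) -> list[FeedforwardProblem]:
    """Split a recurrent problem into one feedforward problem per driven neuron.

    For driven neuron ``i`` the columns of ``z`` are the steady-state
    activities of exactly its permitted presynaptic neurons — driven
    activities taken from ``y``, input activities from ``x`` — ordered as
    driven neurons first, then inputs.
    """
    return [target_problem(spec, patterns, i) for i in range(spec.n_driven)]


def extend_to_full_rank(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Append an orthonormal null-space basis to make ``z`` square full rank.

    The appended rows span the null space of ``z`` so that, when the rows of
    ``z`` are orthonormal, the extension is an orthogonal matrix.  The sign
    of each appended row is fixed by making its first nonzero entry positive,
    so the extension is reproducible across runs and platforms.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    P, N = z.shape
    if np.linalg.matrix_rank(z) < P:
        raise ValueError("rank-deficient pattern matrix")
    if P == N:
        return z.copy(), np.linalg.inv(z)
    ns = null_space(z).T  # (N - P, N), orthonormal rows
    for row in ns:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    Z = np.vstack([z, ns])
    return Z, np.linalg.inv(Z)


def normalize_rows(
    z: np.ndarray, y_target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale pattern rows to unit norm, scaling responses to match.

    The threshold-linear transfer function is positively homogeneous, so
    scaling pattern row mu and response y_mu by the same positive factor
    leaves the solution space untouched.  This turns mutually orthogonal
    rows into orthonormal ones, on which the exact certainty formulas apply.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    y_target = np.asarray(y_target, dtype=float).ravel()
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms <= 0):
        raise ValueError("zero pattern row cannot be normalized")
    return z / norms[:, None], y_target / norms


def classify_dimensions(
    y_target: np.ndarray, n_dims: int, tol: float = 1e-9
) -> DimensionLabels:
    """Label each eta dimension constrained / semiconstrained / unconstrained."""
    y_target = np.asarray(y_target, dtype=float).ravel()
    P = y_target.shape[0]
    if P > n_dims:
        raise ValueError("more patterns than dimensions")
    if np.any(y_target < -tol):
        raise ValueError("noisy responses; classify via error-aware path")
    labels = []
    for mu in range(n_dims):
        if mu >= P:
            labels.append(_FREE)
        elif y_target[mu] > tol:
            labels.append(_CONSTRAINED)
        else:
            labels.append(_SEMI)
    return DimensionLabels(labels=labels)


def _sgn(value: float) -> float:
    # Sgn(0) := +1; at e_y = 0 the choice is irrelevant to y-critical.
    return 1.0 if value >= 0 else -1.0


def synapse_projections(
    problem: FeedforwardProblem,
    labels: DimensionLabels,
    m: int,
    tol: float = 1e-12,
) -> SynapseGeometry:
    """Projections and orientation angles of synapse ``m``'s basis direction.

    Requires orthonormal presynaptic patterns (so that the eta basis is a
    rotation of the physical basis) and a nonzero response vector.
    """
    y = problem.y_target
    y_norm = float(np.linalg.norm(y))
    if y_norm <= 0:
        raise ValueError(
            "no constrained dimensions; every synapse uncertain for y = 0"
        )
    col = problem.Z[:, m].astype(float)
    c_idx = labels.constrained
    s_idx = labels.semiconstrained
    u_idx = labels.unconstrained

    e_y = float(np.dot(y[c_idx], col[c_idx])) / y_norm
    cos2 = float(np.sum(col[c_idx] ** 2))
    s2 = float(np.sum(col[s_idx] ** 2))
    u2 = float(np.sum(col[u_idx] ** 2))

    sgn = _sgn(e_y)
    semi = col[s_idx]
    adverse = semi * sgn > tol
    es2 = float(np.sum(semi[adverse] ** 2))

    if s2 > tol:
        sprime = -sgn * semi / np.sqrt(s2)
    else:
        sprime = np.zeros_like(semi)

    total = cos2 + s2 + u2  # = 1 for orthogonal Z
    cos_theta = np.sqrt(np.clip(cos2 / total, 0.0, 1.0))
    theta = float(np.arccos(cos_theta))
    phi = float(np.arctan2(np.sqrt(u2), np.sqrt(s2))) if s2 + u2 > tol else 0.0
    if cos2 > tol:
        alpha = float(np.arccos(np.clip(e_y / np.sqrt(cos2), -1.0, 1.0)))
    else:
        alpha = np.pi / 2
    # gamma := pi/2 when the semiconstrained projection vanishes (empty sum)
    gamma = float(np.arccos(np.sqrt(np.clip(es2 / s2, 0.0, 1.0)))) if s2 > tol else np.pi / 2

    e_u = float(np.sqrt(u2))
    e_p = float(np.sqrt(np.clip(cos2 + s2, 0.0, None)))
    r_y = abs(e_y) / e_p if e_p > tol else 0.0
    denom = e_p**2 - e_y**2
    r_sstar = float(np.sqrt(np.clip(es2 / denom, 0.0, 1.0))) if denom > tol else 0.0

    return SynapseGeometry(
        m=m,
        basis_components=col,
        e_y=e_y,
        e_sstar=float(np.sqrt(es2)),
        e_u=e_u,
        e_p=e_p,
        theta=theta,
        phi=phi,
        alpha=alpha,
        gamma=gamma,
        r_y=r_y,
        r_sstar=r_sstar,
        sprime_components=sprime,
        constrained_idx=c_idx,
        semiconstrained_idx=s_idx,
        unconstrained_idx=u_idx,
    )
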