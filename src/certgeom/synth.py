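"""Generators for synthetic configurations with the structure the theory assumes.

Random orthonormal pattern matrices come from exponentiating random
antisymmetric matrices; response vectors place a chosen number of positive
components (direction uniform over the positive orthant of the sphere) at a
norm matching the median norm of vectors in the unit ball of the constrained
subspace.  Also houses the small printed fixtures used throughout: the
two-input toy problem, the three illustrative 3-synapse problems, the
two-parameter orthogonal pattern family, and a recurrent configuration with
orthonormal presynaptic patterns for one target neuron.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm, sqrtm

from .config_io import NetworkSpec, PatternSet
from .geometry import FeedforwardProblem, feedforward_problem

__all__ = [
    "random_orthogonal",
    "random_configuration",
    "transition_configuration",
    "recurrent_orthogonal_config",
    "fig2_toy",
    "toy_two_semiconstrained",
    "toy_two_constrained",
    "toy_one_of_each",
    "orthogonal_family",
    "self_synapse_network",
    "paper_fixtures",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def median_ball_norm(c: int) -> float:
    """Median norm of a uniform vector in the unit c-ball, 1 - ln2/c approx."""
    return 1.0 - np.log(2.0) / c


def random_orthogonal(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random special-orthogonal matrix exp(A), A antisymmetric Gaussian.

    Upper-triangle entries are independent N(0, 1/n); any full-measure choice
    gives an orthogonal output, the scale only shapes the distribution.
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = _rng(seed)
    if n == 1:
        return np.ones((1, 1))
    A = np.triu(rng.normal(0.0, 1.0 / np.sqrt(n), (n, n)), 1)
    return expm(A - A.T)


def _positive_orthant_direction(rng: np.random.Generator, c: int) -> np.ndarray:
    d = np.abs(rng.standard_normal(c))
    return d / np.linalg.norm(d)


def random_configuration(
    N: int,
    P: int,
    C: int,
    seed: int | np.random.Generator = 0,
    y_norm: float | None = None,
) -> FeedforwardProblem:
    """Random orthonormal feedforward configuration with C positive responses.

    ``z`` is the first P rows of a random orthogonal matrix; the response
    vector has C positive components (first C patterns), direction uniform
    on the positive orthant, and norm ``y_norm`` (default: the median norm
    of the unit C-ball, 1 - ln2/C).
    """
    if not (1 <= C <= P <= N):
        raise ValueError("need 1 <= C <= P <= N")
    rng = _rng(seed)
    X = random_orthogonal(N, rng)
    y = np.zeros(P)
    norm = median_ball_norm(C) if y_norm is None else float(y_norm)
    y[:C] = norm * _positive_orthant_direction(rng, C)
    return FeedforwardProblem(
        z=X[:P].copy(),
        y_target=y,
        Z=X,
        Z_inv=X.T.copy(),
        presyn_labels=np.arange(N),
        target_index=None,
    )


def transition_configuration(
    I: int,
    P: int,
    C: int = 2,
    seed: int | np.random.Generator = 0,
    small_range: tuple[float, float] = (0.02, 0.1),
    y_norm: float | None = None,
) -> FeedforwardProblem:
    """Configuration engineered for one early topological transition.

    One constrained component is small (uniform in ``small_range`` times the
    response norm) so that modest error budgets can zero it; the remaining
    constrained mass is concentrated so no further subsets fall within such
    budgets.
    """
    if not (1 <= C <= P <= I):
        raise ValueError("need 1 <= C <= P <= I")
    rng = _rng(seed)
    X = random_orthogonal(I, rng)
    norm = median_ball_norm(C) if y_norm is None else float(y_norm)
    y = np.zeros(P)
    if C == 1:
        y[0] = norm
    else:
        small = norm * rng.uniform(*small_range)
        rest = np.sqrt(norm**2 - small**2)
        y[0] = small
        if C == 2:
            y[1] = rest
        else:
            y[1:C] = rest * _positive_orthant_direction(rng, C - 1)
    return FeedforwardProblem(
        z=X[:P].copy(),
        y_target=y,
        Z=X,
        Z_inv=X.T.copy(),
        presyn_labels=np.arange(I),
        target_index=None,
    )


def recurrent_orthogonal_config(
    I: int,
    D: int,
    P: int,
    seed: int | np.random.Generator = 0,
    C: int | None = None,
    y_norm: float | None = None,
) -> tuple[NetworkSpec, PatternSet, int]:
    """Recurrent network (no self-synapses) with orthonormal presynaptic
    patterns for one driven neuron.

    The target neuron (index 0) receives the other D-1 driven neurons and
    all I inputs (N = I + D - 1 synapses).  Its presynaptic pattern matrix is
    built with orthonormal rows while keeping the driven columns — which are
    other neurons' steady-state responses — entrywise nonnegative: when
    P > I, P - I patterns get disjoint-support unit driven activity and no
    input drive; the remaining rows mix small nonnegative driven activity
    with input patterns chosen to restore row orthonormality.
    """
    N = I + D - 1
    if P > N:
        raise ValueError("more patterns than synapses")
    k_extra = max(0, P - I)
    if k_extra > D - 1:
        raise ValueError(
            "infeasible construction: need P - I <= D - 1 nonneg driven columns"
        )
    rng = _rng(seed)
    C = C if C is not None else max(1, int(round(3 * P / 8)))
    C = min(C, P)

    n_drv = D - 1
    P0 = P - k_extra  # rows carrying input drive
    z_d = np.zeros((P, n_drv))
    x = np.zeros((P, I))
    # input-free patterns: unit nonnegative driven activity with disjoint
    # supports (keeps the rows orthonormal); spreading each over two driven
    # neurons lets them drive each other, so the activity is realizable
    # within a unit weight bound once the target also responds there
    width = 2 if 2 * k_extra <= n_drv else 1
    for k in range(k_extra):
        cols = np.arange(width * k, width * (k + 1))
        z_d[P0 + k, cols] = 1.0 / np.sqrt(width)
    free_cols = np.arange(width * k_extra, n_drv)
    if P0 > 0:
        if free_cols.size:
            B = np.abs(rng.standard_normal((P0, free_cols.size)))
            G = B @ B.T
            lam = np.linalg.eigvalsh(G)[-1]
            if lam > 0:
                B *= np.sqrt(0.5 / lam)
            z_d[:P0, free_cols] = B
        G = z_d[:P0] @ z_d[:P0].T
        S = np.eye(P0) - G
        root = np.real(sqrtm(S))
        Q = random_orthogonal(I, rng)[:P0]
        x[:P0] = root @ Q
    spec = NetworkSpec(n_input=I, n_driven=D, allow_self_synapse=False)
    if C < k_extra:
        raise ValueError(
            "need C >= P - I: the input-free patterns must be constrained "
            "for the target so they can drive the driven-only activity"
        )
    norm = median_ball_norm(C) if y_norm is None else float(y_norm)
    # constrained responses: all input-free (driven-only) patterns — the
    # target is the only possible drive there — plus leading regular patterns
    c_idx = np.concatenate([np.arange(C - k_extra), np.arange(P0, P)]).astype(int)
    y_target = np.zeros(P)
    y_target[c_idx] = norm * _positive_orthant_direction(rng, C)
    y = np.column_stack([y_target] + [z_d[:, j] for j in range(n_drv)])
    return spec, PatternSet(x=x, y=y), 0


# ---------------------------------------------------------------------------
# printed fixtures


def fig2_toy() -> tuple[NetworkSpec, PatternSet]:
    """Two inputs driving one neuron: responds to (1,1), silent for (1,-1)."""
    spec = NetworkSpec(n_input=2, n_driven=1, allow_self_synapse=False)
    patterns = PatternSet(x=np.array([[1.0, 1.0], [1.0, -1.0]]), y=np.array([[1.0], [0.0]]))
    return spec, patterns


def _complete_orthogonal(first_col: np.ndarray) -> np.ndarray:
    """Deterministic orthogonal matrix with the given (unit) first column."""
    n = len(first_col)
    drop = int(np.argmax(np.abs(first_col)))  # identity column parallel to col
    others = np.eye(n)[:, [j for j in range(n) if j != drop]]
    M = np.column_stack([first_col, others])
    Q, R = np.linalg.qr(M)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs[None, :]


def toy_two_semiconstrained(theta: float, gamma: float, y3: float = 1.0) -> FeedforwardProblem:
    """3-synapse problem, responses (0, 0, y3): two semiconstrained dims.

    The first synapse direction makes angle ``theta`` with the constrained
    axis and its semiconstrained projection sits at angle ``gamma`` from the
    solution region, so its critical magnitude is
    W*sqrt(sin^2(theta)cos^2(gamma) / (cos^2(theta) + sin^2(theta)cos^2(gamma))).
    """
    col = np.array(
        [-np.sin(theta) * np.cos(gamma), np.sin(theta) * np.sin(gamma), -np.cos(theta)]
    )
    # orthogonal pattern matrix whose first column is the synapse direction's
    # eta-basis components (rows are the patterns)
    z = _complete_orthogonal(col)
    return feedforward_problem(z, np.array([0.0, 0.0, y3]))


def toy_two_constrained(
    theta: float, alpha: float, y_norm: float = 1.0, beta: float = np.pi / 4
) -> FeedforwardProblem:
    """3-synapse problem, responses (y1, y2, 0): one semiconstrained dim.

    ``alpha`` is the angle between the response vector and the constrained
    projection of the first synapse direction; ``beta`` orients that
    projection within the constrained plane and drops out of the critical
    value.  Requires ``beta - alpha`` in (0, pi/2) so both responses are
    positive.
    """
    if not (0 < beta - alpha < np.pi / 2):
        raise ValueError("need 0 < beta - alpha < pi/2 for positive responses")
    col = np.array(
        [np.cos(theta) * np.cos(beta), np.cos(theta) * np.sin(beta), np.sin(theta)]
    )
    z = _complete_orthogonal(col)
    y = y_norm * np.array([np.cos(beta - alpha), np.sin(beta - alpha), 0.0])
    return feedforward_problem(z, y)


def toy_one_of_each(theta: float, phi: float, y2: float = 1.0) -> FeedforwardProblem:
    """3-synapse problem with one constrained, one semiconstrained and one
    unconstrained dimension; equivalent to the acute branch of
    :func:`orthogonal_family`."""
    return orthogonal_family(theta, phi, y=y2)


def orthogonal_family(psi: float, chi: float, y: float = 1.0) -> FeedforwardProblem:
    """Two-parameter family of 3-input orthonormal patterns, responses (0, y).

    The first synapse's direction decomposes as cos(psi) along the
    constrained axis, sin(psi)cos(chi) along the semiconstrained axis and
    sin(psi)sin(chi) along the unconstrained axis, so its critical value is
    W*sqrt(s^2 t^2/(c^2 + s^2 t^2)) with (s, t, c) = (sin psi, sin chi,
    cos psi) when both angles are acute, and W*sin(psi) when chi is obtuse.
    """
    sp, cp = np.sin(psi), np.cos(psi)
    sc, cc = np.sin(chi), np.cos(chi)
    z = np.array([[-sp * cc, cp * cc, sc], [cp, sp, 0.0]])
    Z = np.vstack([z, [sp * sc, -cp * sc, cc]])
    return FeedforwardProblem(
        z=z,
        y_target=np.array([0.0, y]),
        Z=Z,
        Z_inv=Z.T.copy(),
        presyn_labels=np.arange(3),
        target_index=None,
    )


def self_synapse_network(
    chi: float, psi: float = -np.pi / 4, y1: float = 0.5
) -> tuple[NetworkSpec, PatternSet, int]:
    """Three-input, three-driven recurrent network with a self-synapse.

    Driven responses are tailored so every driven neuron sees the same
    orthonormal pair of presynaptic patterns: neuron 1's activity matches
    input 0's pattern and neuron 2's matches input 2's.  Neuron 2 (the
    returned target) synapses onto itself; its response norm is sin(chi)
    and the self-synapse critical value is cos(chi), so the self-synapse is
    certain exactly when chi > 45 degrees.  Requires ``chi`` acute and
    ``psi`` a negative acute angle (keeps driven responses nonnegative).
    """
    if not (0 < chi <= np.pi / 2):
        raise ValueError("chi must be acute")
    if not (-np.pi / 2 < psi < 0):
        raise ValueError("psi must be a negative acute angle")
    sp, cp = np.sin(psi), np.cos(psi)
    sc, cc = np.sin(chi), np.cos(chi)
    x = np.array([[-sp * cc, cp * cc, sc], [cp, sp, 0.0]])
    # driven activities: neuron 0 free choice, neuron 1 = input-0 pattern,
    # neuron 2 = input-2 pattern
    y = np.column_stack(
        [
            np.array([0.0, y1]),
            x[:, 0],
            x[:, 2],
        ]
    )
    mask = np.zeros((3, 6), dtype=bool)
    mask[0, 3:6] = True           # neuron 0: all inputs
    mask[1, [3, 4, 5]] = True     # neuron 1: all inputs
    mask[2, [1, 2, 4]] = True     # neuron 2: driven 1, itself, input 1
    spec = NetworkSpec(n_input=3, n_driven=3, allow_self_synapse=True, adjacency_mask=mask)
    return spec, PatternSet(x=x, y=y), 2


def paper_fixtures() -> dict:
    """Named collection of the printed fixtures."""
    return {
        "fig2_toy": fig2_toy,
        "toy1": toy_two_semiconstrained,
        "toy2": toy_two_constrained,
        "toy3": toy_one_of_each,
        "fig6_family": orthogonal_family,
        "fig6_self_synapse": self_synapse_network,
        "fig8_recurrent": lambda seed=0: recurrent_orthogonal_config(7, 4, 8, seed, C=3),
    }
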