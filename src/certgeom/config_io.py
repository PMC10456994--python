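"""Network/pattern domain types and plain-text readers and writers.

A *problem* is a network architecture together with a set of specified
steady-state responses: ``x`` holds the firing rates of the input neurons
(one row per stimulus pattern), ``y`` the nonnegative steady-state rates of
the recurrently connected driven neurons. On disk a problem is a small JSON
manifest pointing at delimited matrix files (comma or tab separated, patterns
as rows, neurons as columns) — human-inspectable and language-neutral.

Presynaptic index convention: ``m = 0..D-1`` are driven neurons,
``m = D..D+I-1`` are input neurons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkSpec",
    "PatternSet",
    "WeightMatrix",
    "ValidationReport",
    "load_problem",
    "save_problem",
    "validate_patterns",
    "presynaptic_indices",
    "presynaptic_matrix",
]


@dataclass
class NetworkSpec:
    """Architecture of a threshold-linear recurrent network.

    Parameters
    ----------
    n_input : int
        Number of input neurons (feedforward drive only).
    n_driven : int
        Number of recurrently connected driven neurons.
    allow_self_synapse : bool
        Whether a driven neuron may synapse onto itself.
    adjacency_mask : (n_driven, n_driven + n_input) bool array, optional
        ``mask[i, m]`` is True when presynaptic neuron ``m`` is permitted to
        synapse onto driven neuron ``i``.  ``None`` means all-to-all (minus
        self-synapses when those are disallowed).
    """

    n_input: int
    n_driven: int
    allow_self_synapse: bool = True
    adjacency_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_driven < 1:
            raise ValueError("at least one driven neuron is required")
        if self.n_input < 1:
            raise ValueError("at least one input neuron is required")
        if self.adjacency_mask is not None:
            mask = np.asarray(self.adjacency_mask, dtype=bool)
            expected = (self.n_driven, self.n_driven + self.n_input)
            if mask.shape != expected:
                raise ValueError(
                    f"dimension mismatch: adjacency mask {mask.shape} != {expected}"
                )
            if not self.allow_self_synapse and np.any(np.diag(mask[:, : self.n_driven])):
                raise ValueError("self-synapses present in mask but disallowed")
            if np.any(mask.sum(axis=1) < 1):
                raise ValueError("every driven neuron needs at least one synapse")
            self.adjacency_mask = mask

    @property
    def n_neurons(self) -> int:
        return self.n_driven + self.n_input

    def mask(self) -> np.ndarray:
        """Effective boolean mask, materialized even for all-to-all specs."""
        if self.adjacency_mask is not None:
            return self.adjacency_mask.copy()
        mask = np.ones((self.n_driven, self.n_neurons), dtype=bool)
        if not self.allow_self_synapse:
            mask[: self.n_driven, : self.n_driven] &= ~np.eye(self.n_driven, dtype=bool)
        return mask

    def n_synapses(self, i: int) -> int:
        """Number of permitted incoming synapses of driven neuron ``i``."""
        return int(self.mask()[i].sum())


@dataclass
class PatternSet:
    """Specified stimulus transformation: input patterns -> driven responses."""

    x: np.ndarray  # (P, I)
    y: np.ndarray  # (P, D)

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.size == 0 or self.y.size == 0:
            raise ValueError("dimension mismatch: empty pattern matrix")
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError(
                "dimension mismatch: x has "
                f"{self.x.shape[0]} patterns, y has {self.y.shape[0]}"
            )
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite input pattern entries")

    @property
    def n_patterns(self) -> int:
        return self.x.shape[0]


@dataclass
class WeightMatrix:
    """Synaptic weight matrix, rows = driven neurons, columns = presynaptic."""

    w: np.ndarray  # (D, D + I)

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))

    def respects(self, spec: NetworkSpec, tol: float = 0.0) -> bool:
        if self.w.shape != (spec.n_driven, spec.n_neurons):
            return False
        return bool(np.all(np.abs(self.w[~spec.mask()]) <= tol))

    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.w, axis=1)


def presynaptic_indices(spec: NetworkSpec, i: int) -> np.ndarray:
    """Global indices of the permitted presynaptic neurons of driven neuron i."""
    return np.flatnonzero(spec.mask()[i])


def presynaptic_matrix(spec: NetworkSpec, patterns: PatternSet, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state activity patterns of neuron ``i``'s presynaptic partners.

    Returns ``(z, labels)`` where ``z`` is (P, N_i) — driven activities taken
    from ``y``, input activities from ``x`` — and ``labels`` the global
    presynaptic indices of its columns.
    """
    labels = presynaptic_indices(spec, i)
    D = spec.n_driven
    cols = [
        patterns.y[:, m] if m < D else patterns.x[:, m - D]
        for m in labels
    ]
    return np.column_stack(cols), labels


@dataclass
class ValidationReport:
    """Report-only diagnostics from :func:`validate_patterns`."""

    pattern_count_ok: dict[int, bool] = field(default_factory=dict)
    x_rank: int = 0
    x_rank_ok: bool = False
    y_nonnegative: bool = True
    orthonormality: dict[int, str] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            all(self.pattern_count_ok.values())
            and self.x_rank_ok
            and self.y_nonnegative
            and all(v == "orthonormal" for v in self.orthonormality.values())
        )


def validate_patterns(
    spec: NetworkSpec, patterns: PatternSet, tol: float = 1e-8
) -> ValidationReport:
    """Check the assumptions the exact certainty formulas rely on.

    Flags, per driven neuron: pattern count not exceeding the synapse count,
    full row rank of the input patterns, and row-orthonormality of the
    presynaptic pattern matrix (the exact formulas require orthonormal rows;
    mutually orthogonal rows of unequal norm can be fixed by rescaling).
    Nonnegativity of ``y`` distinguishes noiseless from noisy response data.
    """
    report = ValidationReport()
    P = patterns.n_patterns
    report.x_rank = int(np.linalg.matrix_rank(patterns.x, tol=tol))
    report.x_rank_ok = report.x_rank == min(P, patterns.x.shape[1])
    if np.any(patterns.y < -tol):
        report.y_nonnegative = False
        report.messages.append("noisy responses: negative entry in y")
    for i in range(spec.n_driven):
        n_i = spec.n_synapses(i)
        report.pattern_count_ok[i] = P <= n_i
        if P > n_i:
            report.messages.append(
                f"neuron {i}: {P} patterns exceed {n_i} permitted synapses"
            )
        z, _ = presynaptic_matrix(spec, patterns, i)
        gram = z @ z.T
        off = gram - np.diag(np.diag(gram))
        if np.max(np.abs(gram - np.eye(P))) <= tol:
            report.orthonormality[i] = "orthonormal"
        elif np.max(np.abs(off)) <= tol * max(1.0, np.max(np.abs(gram))):
            report.orthonormality[i] = "orthogonal, not orthonormal"
        else:
            report.orthonormality[i] = "non-orthogonal"
    return report


def _detect_delimiter(path: Path) -> str:
    first = path.read_text().lstrip().splitlines()[0] if path.read_text().strip() else ""
    return "," if first.count(",") >= first.count("\t") and "," in first else "\t"


def _load_matrix(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"dimension mismatch: empty matrix file {path.name}")
    return np.loadtxt(path, delimiter=_detect_delimiter(path), ndmin=2)


def _save_matrix(path: Path, matrix: np.ndarray, delimiter: str = "\t") -> None:
    np.savetxt(path, np.atleast_2d(matrix), delimiter=delimiter, fmt="%.17g")


def load_problem(path: str | Path) -> tuple[NetworkSpec, PatternSet]:
    """Load a (NetworkSpec, PatternSet) pair from a JSON manifest.

    The manifest carries ``n_input``, ``n_driven``, ``allow_self_synapse``,
    ``x_file``, ``y_file``, an optional ``mask_file`` and optional
    ``weight_bound`` / ``noiseless`` fields. Matrix paths are resolved
    relative to the manifest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    manifest = json.loads(path.read_text())
    base = path.parent
    x = _load_matrix(base / manifest["x_file"])
    y = _load_matrix(base / manifest["y_file"])
    n_input = int(manifest["n_input"])
    n_driven = int(manifest["n_driven"])
    if x.shape[1] != n_input:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[1]} columns, manifest says {n_input}"
        )
    if y.shape[1] != n_driven:
        raise ValueError(
            f"dimension mismatch: y has {y.shape[1]} columns, manifest says {n_driven}"
        )
    mask = None
    if manifest.get("mask_file"):
        mask = _load_matrix(base / manifest["mask_file"]).astype(bool)
    if manifest.get("noiseless", False) and np.any(y < 0):
        raise ValueError("negative y entries in data declared noiseless")
    spec = NetworkSpec(
        n_input=n_input,
        n_driven=n_driven,
        allow_self_synapse=bool(manifest.get("allow_self_synapse", True)),
        adjacency_mask=mask,
    )
    return spec, PatternSet(x=x, y=y)


def load_weight_bound(path: str | Path, default: float | None = None) -> float | None:
    manifest = json.loads(Path(path).read_text())
    value = manifest.get("weight_bound", default)
    return None if value is None else float(value)


def save_problem(
    spec: NetworkSpec,
    patterns: PatternSet,
    path: str | Path,
    weight_bound: float | None = None,
    noiseless: bool = False,
) -> None:
    """Write the manifest plus matrix files such that load_problem inverts it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.stem
    manifest: dict = {
        "n_input": spec.n_input,
        "n_driven": spec.n_driven,
        "allow_self_synapse": spec.allow_self_synapse,
        "x_file": f"{stem}_x.tsv",
        "y_file": f"{stem}_y.tsv",
    }
    _save_matrix(path.parent / manifest["x_file"], patterns.x)
    _save_matrix(path.parent / manifest["y_file"], patterns.y)
    if spec.adjacency_mask is not None:
        manifest["mask_file"] = f"{stem}_mask.tsv"
        _save_matrix(path.parent / manifest["mask_file"], spec.adjacency_mask.astype(int))
    if weight_bound is not None:
        manifest["weight_bound"] = float(weight_bound)
    if noiseless:
        manifest["noiseless"] = True
    path.write_text(json.dumps(manifest, indent=2) + "\n")
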