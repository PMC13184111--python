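"""Concept-graph data model and bounded sigmoid reasoning dynamics.

An FCM is a directed graph over ``n`` named concepts.  The weight ``w[i, j]``
is the influence of concept ``i`` (row) on concept ``j`` (column); activations
are row vectors in ``[0, 1]^n`` and propagate as ``A @ W``.  Two reasoning
modes are supported:

* ``free`` — every concept is updated: ``A <- f(A @ W)``;
* ``clamped`` — the feature concepts are held fixed at their fuzzified
  values and only the designated diagnostic output node iterates:
  ``a_out <- f(sum_i A_i w[i, out] + a_out * w[out, out] + b)``.

With a sigmoid of steepness ``lambda`` the componentwise map has Lipschitz
constant ``L_f = lambda / 4``; whenever ``L_f * ||W|| < 1`` for an
operator-compatible matrix norm the fixed-weight reasoning map is a
contraction and the inner loop converges to a unique equilibrium from any
initial state (Banach fixed point).  :func:`contraction_report` checks this
sufficient condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_SUPPORTED_NORMS = ("spectral", "frobenius", "max_row_sum")
_SUPPORTED_STOP_NORMS = ("inf", "l2")
_SUPPORTED_MODES = ("free", "clamped")


@dataclass
class ConceptGraph:
    """Named concepts, binary topology mask, weight matrix, and output node.

    Parameters
    ----------
    names
        Ordered concept labels; ``len(names) == n >= 2``.
    mask
        ``(n, n)`` binary matrix; ``mask[i, j] == 1`` permits the edge from
        concept ``i`` to concept ``j``.
    weights
        ``(n, n)`` real matrix with entries in ``[-1, 1]``; zero wherever the
        mask forbids the edge.
    bias
        Scalar added to the output node's pre-activation in clamped mode.
    output_index
        0-based index of the diagnostic concept (default: last).
    """

    names: list[str]
    mask: np.ndarray
    weights: np.ndarray
    bias: float = 0.0
    output_index: int = -1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.names = list(self.names)
        n = len(self.names)
        if self.output_index < 0:
            self.output_index += n
        self.validate()

    @property
    def n(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        n = self.n
        if n < 2:
            raise ValueError(f"a concept graph needs at least 2 concepts, got {n}")
        if self.mask.shape != (n, n) or self.weights.shape != (n, n):
            raise ValueError(
                f"mask/weights must be {(n, n)}, got {self.mask.shape} and "
                f"{self.weights.shape}"
            )
        if not np.all(np.isin(self.mask, (0.0, 1.0))):
            raise ValueError("mask entries must be 0 or 1")
        if not (0 <= self.output_index < n):
            raise ValueError(f"output_index {self.output_index} outside 0..{n - 1}")
        if np.any(np.abs(self.weights) > 1.0 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")
        off_mask = self.mask == 0
        if np.any(self.weights[off_mask] != 0.0):
            raise ValueError("weights must be zero wherever the mask forbids an edge")

    def copy(self) -> "ConceptGraph":
        return ConceptGraph(
            names=list(self.names),
            mask=self.mask.copy(),
            weights=self.weights.copy(),
            bias=self.bias,
            output_index=self.output_index,
        )

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mask": self.mask.astype(int).tolist(),
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "output_index": int(self.output_index),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConceptGraph":
        return cls(
            names=d["names"],
            mask=np.asarray(d["mask"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d.get("bias", 0.0)),
            output_index=int(d.get("output_index", -1)),
        )

    def to_json(self, path: str | Path) -> None:
        """Serialize to JSON.  All indices on disk are 0-based."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConceptGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ReasoningConfig:
    """Inner-loop settings: sigmoid steepness, stop tolerance, iteration cap."""

    steepness: float = 1.0
    tol: float = 1e-4
    max_iter: int = 50
    mode: str = "clamped"
    stop_norm: str = "inf"

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError(f"steepness must be > 0, got {self.steepness}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if int(self.max_iter) != self.max_iter or self.max_iter < 1:
            raise ValueError(f"max_iter must be an integer >= 1, got {self.max_iter}")
        if self.mode not in _SUPPORTED_MODES:
            raise ValueError(f"mode must be one of {_SUPPORTED_MODES}, got {self.mode!r}")
        if self.stop_norm not in _SUPPORTED_STOP_NORMS:
            raise ValueError(
                f"stop_norm must be one of {_SUPPORTED_STOP_NORMS}, got {self.stop_norm!r}"
            )


@dataclass
class ActivationTrajectory:
    """Recorded inner-loop states, step count, and convergence flag."""

    states: np.ndarray  # (iterations + 1, n), includes the initial state
    iterations: int
    converged: bool

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class ContractionReport:
    """Sufficient-condition diagnostics for inner-loop contraction."""

    lipschitz_f: float
    norm_w: float
    kappa_bound: float
    factor: float
    contractive: bool
    norm_id: str = "spectral"


def sigmoid(x: np.ndarray | float, steepness: float = 1.0) -> np.ndarray:
    """Componentwise logistic function ``1 / (1 + exp(-steepness * x))``.

    Strictly increasing, maps the reals into ``(0, 1)``.  Non-finite input is
    rejected rather than silently saturated.
    """
    if steepness <= 0:
        raise ValueError(f"steepness must be > 0, got {steepness}")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sigmoid input must be finite")
    return 1.0 / (1.0 + np.exp(-steepness * arr))


def _check_state(state: np.ndarray, graph: ConceptGraph) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (graph.n,):
        raise ValueError(
            f"state has {state.shape[0] if state.ndim == 1 else state.shape} "
            f"components but the graph has {graph.n} concepts"
        )
    return state


def reasoning_step(
    state: np.ndarray, graph: ConceptGraph, config: ReasoningConfig
) -> np.ndarray:
    """One propagation step of the activation dynamics.

    Free mode returns ``f(state @ W)``.  Clamped mode leaves every non-output
    component untouched and updates only the output node from the *current*
    state (feature components stay at their clamped values throughout the
    inner loop, so the driving sum is constant there).
    """
    state = _check_state(state, graph)
    if config.mode == "free":
        return sigmoid(state @ graph.weights, config.steepness)
    out = graph.output_index
    pre = float(state @ graph.weights[:, out]) + graph.bias
    new = state.copy()
    new[out] = float(sigmoid(pre, config.steepness))
    return new


def run_inner(
    initial: np.ndarray, graph: ConceptGraph, config: ReasoningConfig
) -> ActivationTrajectory:
    """Iterate :func:`reasoning_step` until the stop norm of successive
    differences falls below ``config.tol`` or ``config.max_iter`` is reached.

    Hitting the iteration cap without convergence is a recorded outcome, not
    an error: the last state is still usable as the equilibrium estimate.
    """
    state = _check_state(initial, graph)
    states = [state]
    converged = False
    ord_ = np.inf if config.stop_norm == "inf" else 2
    for _ in range(config.max_iter):
        nxt = reasoning_step(states[-1], graph, config)
        states.append(nxt)
        if np.linalg.norm(nxt - states[-2], ord=ord_) <= config.tol:
            converged = True
            break
    return ActivationTrajectory(
        states=np.asarray(states), iterations=len(states) - 1, converged=converged
    )


def classify(activation: float, tau: float) -> int:
    """Threshold the diagnostic activation: positive iff ``activation >= tau``."""
    if not (0.0 <= activation <= 1.0):
        raise ValueError(f"activation must lie in [0, 1], got {activation}")
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    return int(activation >= tau)


def project_box(matrix: np.ndarray) -> np.ndarray:
    """Entrywise projection onto the admissible box ``[-1, 1]``; idempotent."""
    arr = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("project_box requires finite entries")
    return np.clip(arr, -1.0, 1.0)


def matrix_norm(w: np.ndarray, norm_id: str) -> float:
    if norm_id == "spectral":
        return float(np.linalg.norm(w, ord=2))
    if norm_id == "frobenius":
        return float(np.linalg.norm(w, ord="fro"))
    if norm_id == "max_row_sum":
        return float(np.linalg.norm(w, ord=np.inf))
    raise ValueError(f"unknown norm {norm_id!r}; supported: {_SUPPORTED_NORMS}")


def contraction_report(
    graph: ConceptGraph, config: ReasoningConfig, norm_id: str = "spectral"
) -> ContractionReport:
    """Check the sufficient contraction condition ``(lambda/4) * ||W|| < 1``.

    ``lipschitz_f = lambda / 4`` is the sharp Lipschitz constant of the
    steepness-``lambda`` sigmoid; ``kappa_bound = 1 / lipschitz_f`` is the
    supremum of admissible weight-matrix norms.  The spectral norm is the
    default because it is the operator norm compatible with the Euclidean
    vector norm used in the contraction argument.
    """
    l_f = config.steepness / 4.0
    nw = matrix_norm(graph.weights, norm_id)
    factor = l_f * nw
    return ContractionReport(
        lipschitz_f=l_f,
        norm_w=nw,
        kappa_bound=1.0 / l_f,
        factor=factor,
        contractive=bool(factor < 1.0),
        norm_id=norm_id,
    )


def inner_step_cost(graph: ConceptGraph, config: ReasoningConfig | None = None) -> int:
    """Multiply-accumulate count of one reasoning step.

    Free mode touches every permitted edge once; clamped mode touches only
    the in-edges of the output node.  Used for operation-count scaling
    diagnostics (cost grows with the number of permitted edges, i.e. ~n^2 at
    fixed edge density).
    """
    if config is not None and config.mode == "clamped":
        return int(np.count_nonzero(graph.mask[:, graph.output_index]))
    return int(np.count_nonzero(graph.mask))
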