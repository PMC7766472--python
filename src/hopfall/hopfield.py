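"""Discrete Hopfield associative memory: Hebbian training and recall.

A network of N fully connected bipolar neurons (N = 25 for the 5x5 fall
template, but any N is supported).  Weights are trained one-shot by the
Hebb rule, W = eta * sum_p (p p^T) with a forced zero diagonal, which makes
each stored pattern (and its negation) an attractor of the dynamics

    u_i <- sum_j W_ij v_j + I_i ,     v_i <- sgn(u_i)

with the tie convention that u_i == 0 keeps the previous state.  Updates
run either asynchronously (one neuron at a time, seeded random order per
sweep — the classical setting in which the quadratic energy

    E(v) = -1/2 sum_ij W_ij v_i v_j - sum_i I_i v_i

never increases) or synchronously (all neurons at once).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .features import PatternTemplate

__all__ = [
    "WeightMatrix",
    "RecallResult",
    "train_hebb",
    "recall",
    "energy",
    "is_fixed_point",
    "local_fields",
]


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric zero-diagonal synaptic weights with their learning rate."""

    w: np.ndarray
    eta: float = 1.0

    def __post_init__(self) -> None:
        w = self.w
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got {w.shape}")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have a zero diagonal (no self-feedback)")

    @property
    def n(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class RecallResult:
    """Outcome of a recall run: final states, convergence and energy trace."""

    v: np.ndarray
    converged: bool
    sweeps: int
    energy: np.ndarray
    mode: str


def _as_bipolar(vec, n: int | None = None, name: str = "vector") -> np.ndarray:
    arr = np.asarray(vec.vector if isinstance(vec, PatternTemplate) else vec, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.isin(arr, (-1.0, 1.0)).all():
        raise ValueError(f"{name} must be bipolar (+1/-1)")
    if n is not None and arr.size != n:
        raise ValueError(f"{name} has length {arr.size}, expected {n}")
    return arr


def train_hebb(
    patterns: Iterable[np.ndarray | PatternTemplate] | np.ndarray | PatternTemplate,
    eta: float = 1.0,
) -> WeightMatrix:
    """One-shot Hebbian storage: W = eta * sum_p outer(p, p), zero diagonal.

    Accepts a single pattern or any iterable of equal-length bipolar
    patterns (templates or raw vectors).  Storing p and storing -p give
    the same weights, since the sign cancels in the outer product.
    """
    if eta <= 0:
        raise ValueError("learning rate eta must be positive")
    if isinstance(patterns, (PatternTemplate, np.ndarray)):
        patterns = [patterns]
    vecs = [_as_bipolar(p, name="pattern") for p in patterns]
    if not vecs:
        raise ValueError("at least one pattern required")
    n = vecs[0].size
    w = np.zeros((n, n))
    for v in vecs:
        if v.size != n:
            raise ValueError(f"pattern length mismatch: {v.size} != {n}")
        w += np.outer(v, v)
    w *= eta
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w=w, eta=eta)


def local_fields(W: WeightMatrix, v: np.ndarray, I: np.ndarray | None = None) -> np.ndarray:
    """u = W v + I, the post-synaptic input of every neuron."""
    u = W.w @ np.asarray(v, dtype=float)
    if I is not None:
        u = u + np.asarray(I, dtype=float)
    return u


def _threshold(u: np.ndarray, prev: np.ndarray, tie: str) -> np.ndarray:
    """Sign map with the configured convention at u == 0."""
    if tie == "keep":
        return np.where(u > 0, 1.0, np.where(u < 0, -1.0, prev))
    if tie == "down":
        return np.where(u > 0, 1.0, -1.0)
    raise ValueError(f"unknown tie rule {tie!r}; use 'keep' or 'down'")


def energy(W: WeightMatrix, v, I: np.ndarray | None = None) -> float:
    """Quadratic network energy E = -1/2 v'Wv - I'v."""
    v = _as_bipolar(v, W.n, "state")
    e = -0.5 * float(v @ W.w @ v)
    if I is not None:
        e -= float(np.asarray(I, dtype=float) @ v)
    return e


def is_fixed_point(W: WeightMatrix, v, I: np.ndarray | None = None, tie: str = "keep") -> bool:
    """True iff one synchronous sweep (with the tie rule) leaves v unchanged."""
    v = _as_bipolar(v, W.n, "state")
    return bool(np.array_equal(_threshold(local_fields(W, v, I), v, tie), v))


def recall(
    W: WeightMatrix,
    init,
    I: np.ndarray | None = None,
    mode: str = "async",
    max_sweeps: int = 100,
    seed: int = 0,
    tie: str = "keep",
) -> RecallResult:
    """Relax the network from ``init`` until a full sweep changes nothing.

    ``mode="async"`` updates one neuron at a time in a seeded random
    permutation per sweep (energy is then non-increasing after every
    single update, recorded in the energy trace); ``mode="sync"`` updates
    all neurons simultaneously (energy recorded once per sweep).
    """
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    if mode not in ("async", "sync"):
        raise ValueError(f"unknown update mode {mode!r}; use 'async' or 'sync'")
    v = _as_bipolar(init, W.n, "init").copy()
    I_arr = None if I is None else np.asarray(I, dtype=float)
    if I_arr is not None and I_arr.shape != (W.n,):
        raise ValueError(f"external input has shape {I_arr.shape}, expected ({W.n},)")
    rng = np.random.default_rng(seed)
    trace = [energy(W, v, I_arr)]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        changed = False
        if mode == "async":
            for i in rng.permutation(W.n):
                u_i = float(W.w[i] @ v + (0.0 if I_arr is None else I_arr[i]))
                new = 1.0 if u_i > 0 else (-1.0 if u_i < 0 else (v[i] if tie == "keep" else -1.0))
                if new != v[i]:
                    v[i] = new
                    changed = True
                trace.append(energy(W, v, I_arr))
        else:
            new = _threshold(local_fields(W, v, I_arr), v, tie)
            changed = not np.array_equal(new, v)
            v = new
            trace.append(energy(W, v, I_arr))
        if not changed:
            converged = True
            break
    return RecallResult(
        v=v, converged=converged, sweeps=sweeps, energy=np.asarray(trace), mode=mode
    )


def enumerate_fixed_points(
    W: WeightMatrix, I: np.ndarray | None = None, tie: str = "keep"
) -> list[tuple[int, ...]]:
    """Exhaustively list all fixed points of the synchronous sweep (N <= 20).

    Intended as a brute-force oracle for small test networks.
    """
    n = W.n
    if n > 20:
        raise ValueError("exhaustive enumeration limited to N <= 20")
    states = np.array([[1.0 if (s >> i) & 1 else -1.0 for i in range(n)] for s in range(2**n)])
    u = states @ W.w.T
    if I is not None:
        u = u + np.asarray(I, dtype=float)[None, :]
    nxt = np.where(u > 0, 1.0, np.where(u < 0, -1.0, states if tie == "keep" else -1.0))
    fixed = np.all(nxt == states, axis=1)
    return [tuple(int(x) for x in s) for s in states[fixed]]
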