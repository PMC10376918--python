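"""Constrained non-negative matrix factorization age-group classifier.

The expression matrix D (scaled to [0, 1] by its maximum) is decomposed as
D ~ T P with box constraints 0 <= T, P <= 1 and each column of P summing to
1, so P columns read as age-group membership probabilities. Samples are
labelled by the argmax of their P column; because rows of P are only defined
up to permutation, accuracy against the known age groups is maximized over
all k! label permutations.

Solver: alternating projected least squares. The T-step solves the
row-separable least-squares problem and clips to [0, 1]; the P-step solves
column-wise least squares followed by Euclidean projection onto the
probability simplex. Best-of-restarts by final objective; the best iterate
seen is returned, so the reported objective never exceeds the initial one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AgeFactorization",
    "normalize_max",
    "fit_age_nmf",
    "classify_and_score",
    "simplex_projection",
]

AGE_GROUP_NAMES = ("young", "middle", "old")


def normalize_max(x: np.ndarray) -> np.ndarray:
    """Scale a non-negative matrix into [0, 1] by dividing by its maximum."""
    x = np.asarray(x, dtype=float)
    mx = x.max() if x.size else 0.0
    if mx <= 0:
        raise ValueError("normalize_max requires a matrix with a positive maximum")
    if (x < 0).any():
        raise ValueError("normalize_max requires non-negative entries")
    return x / mx


def simplex_projection(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, v.size + 1) > (css - 1))[0][-1]
    theta = (css[rho] - 1) / (rho + 1)
    return np.maximum(v - theta, 0.0)


@dataclass
class AgeFactorization:
    """Result of the constrained factorization D ~ T P."""

    D: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    k: int = 3
    objective: float = float("nan")
    labels: np.ndarray = field(default=None, repr=False)  # argmax indices, 0-based
    accuracy: float = float("nan")
    permutation_used: tuple[str, ...] | None = None
    n_restarts: int = 0
    n_iterations: int = 0
    seed: int = 0


def _objective(D: np.ndarray, T: np.ndarray, P: np.ndarray) -> float:
    return float(np.linalg.norm(D - T @ P, "fro") ** 2)


def _fit_single(
    D: np.ndarray, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int]:
    m, n = D.shape
    T = rng.uniform(0.0, 1.0, size=(m, k))
    P = rng.dirichlet(np.ones(k), size=n).T
    best = (_objective(D, T, P), T.copy(), P.copy())
    prev = best[0]
    it = 0
    for it in range(1, max_iter + 1):
        # T-step: rows independent; unconstrained LS then clip to the box
        Tn, *_ = np.linalg.lstsq(P.T, D.T, rcond=None)
        T = np.clip(Tn.T, 0.0, 1.0)
        # P-step: columns independent; LS then simplex projection
        Pn, *_ = np.linalg.lstsq(T, D, rcond=None)
        P = np.apply_along_axis(simplex_projection, 0, Pn)
        obj = _objective(D, T, P)
        if obj < best[0]:
            best = (obj, T.copy(), P.copy())
        if prev > 0 and abs(prev - obj) / max(prev, 1e-300) < tol:
            break
        prev = obj
    obj, T, P = best
    return T, P, obj, it


def fit_age_nmf(
    D: np.ndarray,
    k: int = 3,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> AgeFactorization:
    """Fit the constrained factorization, best of ``n_restarts`` seeded starts.

    ``D`` must already be scaled into [0, 1] (see :func:`normalize_max`).
    Initialization per restart: T uniform on [0, 1], P columns flat-Dirichlet.
    Deterministic for a fixed seed.
    """
    D = np.asarray(D, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if not np.isfinite(D).all():
        raise ValueError("D contains non-finite entries")
    m, n = D.shape
    if m < k or n < k:
        raise ValueError(f"matrix {m}x{n} too small for k={k}")
    rng = np.random.default_rng(seed)
    best = None
    total_iter = 0
    for _ in range(n_restarts):
        T, P, obj, it = _fit_single(D, k, max_iter, tol, rng)
        total_iter += it
        if best is None or obj < best[2]:
            best = (T, P, obj)
    T, P, obj = best
    labels = np.argmax(P, axis=0)  # ties resolved to the lowest index by argmax
    return AgeFactorization(
        D=D,
        T=T,
        P=P,
        k=k,
        objective=obj,
        labels=labels,
        n_restarts=n_restarts,
        n_iterations=total_iter,
        seed=seed,
    )


def classify_and_score(
    f: AgeFactorization,
    truth: Sequence[str],
    group_names: Sequence[str] = AGE_GROUP_NAMES,
) -> AgeFactorization:
    """Score predicted labels against truth, maximizing over label permutations.

    ``truth`` holds one group name per sample. Accuracy is the maximum, over
    all k! bijections from predicted indices to group names, of the fraction
    of samples mapped to their true group. The maximizing permutation is
    stored on the factorization, which is returned with ``labels``,
    ``accuracy`` and ``permutation_used`` filled in.
    """
    truth = list(truth)
    n = f.P.shape[1]
    if len(truth) != n:
        raise ValueError(f"truth length {len(truth)} != number of samples {n}")
    if len(group_names) != f.k:
        raise ValueError("group_names must have k entries")
    unknown = set(truth) - set(group_names)
    if unknown:
        raise ValueError(f"unknown truth labels: {sorted(unknown)}")
    truth_arr = np.asarray(truth)
    pred = np.argmax(f.P, axis=0)
    best_acc, best_perm = -1.0, None
    for perm in itertools.permutations(group_names):
        mapped = np.asarray(perm)[pred]
        acc = float((mapped == truth_arr).mean())
        if acc > best_acc:
            best_acc, best_perm = acc, perm
    f.labels = pred
    f.accuracy = best_acc
    f.permutation_used = best_perm
    return f
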