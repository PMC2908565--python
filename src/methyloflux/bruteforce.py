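"""Exhaustive reference solver for small flux polytopes.

The feasible set of FBA is the polytope {v : S v = 0, l <= v <= u}.
When every bound is finite, a linear objective attains its optimum at a
vertex, and every vertex has at least n - rank(S) coordinates pinned to
a bound.  Enumerating all such pinnings and solving the residual linear
system is exponential in the number of reactions but exact, which makes
it a trustworthy independent check of the LP path on networks of a
dozen reactions or fewer.  Never use it on anything larger.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

__all__ = ["enumerate_vertices", "brute_force_lp"]


def enumerate_vertices(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-8,
) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} (finite bounds only).

    Returns an array of shape (n_vertices, n); duplicate vertices are
    merged.  Raises if any bound is infinite.
    """
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex enumeration needs finite bounds")
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    n_fix = n - rank
    vertices: list[np.ndarray] = []
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for choice in product((0, 1), repeat=n_fix):
            v = np.empty(n)
            for j, side in zip(fixed, choice):
                v[j] = ub[j] if side else lb[j]
            b = -S[:, fixed] @ v[list(fixed)] if fixed else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return np.empty((0, n))
    arr = np.array(vertices)
    # deduplicate within tolerance
    keep: list[int] = []
    for i in range(len(arr)):
        if all(np.max(np.abs(arr[i] - arr[k])) > tol for k in keep):
            keep.append(i)
    return arr[keep]


def brute_force_lp(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
) -> tuple[float, np.ndarray]:
    """max c·v over the flux polytope by exhaustive vertex enumeration.

    Returns (optimum, argmax vertex); raises if the polytope is empty.
    """
    verts = enumerate_vertices(S, lb, ub)
    if len(verts) == 0:
        raise ValueError("empty flux polytope")
    values = verts @ c
    best = int(np.argmax(values))
    return float(values[best]), verts[best]
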