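"""Exact solutions of the consistent condensed system and their geometry.

When the joint genotype probability vector g is exactly compatible with
the system matrix M(p) (same allele probability; a'g = 0 and 1'g = 1),
the linear system g = M delta is consistent but under-determined: the
solution set is a two-parameter family

    delta_tilde = delta_particular + xi * z1 + eta * z2

with (z1, z2) the null-space directions.  Requiring delta_tilde >= 0
intersects nine half-planes in the (xi, eta) plane; the resulting convex
polygon is the set of all valid probability-vector solutions.  The
identifiable parameters theta = Q delta are constant across the polygon.

A particular solution can be taken from the Moore-Penrose pseudoinverse
(minimum norm) or from Gaussian elimination, which, at the generic rank
of seven, zeroes the trailing free coefficients Delta8 and Delta9 --
a vivid illustration that individual state probabilities can be pinned
to arbitrary values without changing the data distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .identity_core import (
    A_CONSTRAINT,
    CondensedSystem,
    NullDirections,
    null_directions,
)

__all__ = ["ConsistencyError", "SolutionManifold", "solve_consistent", "feasible_region"]

_VERTEX_DEDUP = 1e-8
_FEAS_TOL = 1e-10


class ConsistencyError(ValueError):
    """g is not exactly compatible with the system (use the CLS fit)."""


@dataclass
class SolutionManifold:
    """The non-negative solution set of a consistent system.

    ``polygon`` lists the (xi, eta) vertices in counter-clockwise order
    (empty if no non-negative solution exists).  ``ranges`` gives the
    attainable [min, max] of each coefficient over the polygon.
    ``chebyshev_center`` is a canonical interior representative (a
    display convention, not an estimate).
    """

    particular: np.ndarray
    null: NullDirections
    polygon: np.ndarray
    ranges: np.ndarray
    chebyshev_center: tuple[float, float] | None

    @property
    def empty(self) -> bool:
        return self.polygon.shape[0] == 0

    def delta_at(self, xi: float, eta: float) -> np.ndarray:
        return self.particular + xi * self.null.z1 + eta * self.null.z2

    def contains(self, delta: np.ndarray, atol: float = 1e-8) -> bool:
        """Whether a 9-vector lies on the manifold inside the polygon."""
        d = np.asarray(delta, dtype=float) - self.particular
        Z = np.column_stack([self.null.z1, self.null.z2])
        coef, *_ = np.linalg.lstsq(Z, d, rcond=None)
        if np.abs(Z @ coef - d).max() > atol:
            return False
        cand = self.delta_at(coef[0], coef[1])
        return bool(cand.min() >= -atol)


def solve_consistent(
    g: np.ndarray, m: CondensedSystem, method: str = "pseudoinverse"
) -> np.ndarray:
    """One particular solution of the consistent system g = M delta.

    Entries may be negative but always sum to one (any solution does,
    because the columns of M sum to one).  ``method="gaussian"`` returns
    the row-echelon solution, which has Delta8 = Delta9 = 0 whenever M
    has the generic rank seven.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != (9,):
        raise ValueError("g must be a 9-vector")
    if abs(g.sum() - 1.0) > 1e-8:
        raise ConsistencyError("g must sum to one")
    if abs(A_CONSTRAINT @ g) > 1e-8:
        raise ConsistencyError(
            "a'g = 0 violated: the system is inconsistent; "
            "use the constrained least-squares fit instead"
        )
    M = m.m
    if M.shape != (9, 9):
        raise ValueError("expected the 9x9 condensed system")
    if method == "pseudoinverse":
        delta = np.linalg.pinv(M) @ g
    elif method == "gaussian":
        # free variables Delta8, Delta9 set to zero: solve on columns 1..7
        delta7, *_ = np.linalg.lstsq(M[:, :7], g, rcond=None)
        delta = np.concatenate([delta7, [0.0, 0.0]])
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.abs(M @ delta - g).max() > 1e-8:
        raise ConsistencyError("no exact solution found; system inconsistent")
    return delta


def _polygon_vertices(b: np.ndarray, Zk: np.ndarray) -> np.ndarray:
    """Vertices of {x in R^2 : b + Zk @ x >= 0} by pairwise intersection."""
    nc = b.size
    pts = []
    for i in range(nc):
        for j in range(i + 1, nc):
            A2 = np.array([Zk[i], Zk[j]])
            det = np.linalg.det(A2)
            if abs(det) < 1e-14:
                continue
            x = np.linalg.solve(A2, -b[[i, j]])
            if np.all(b + Zk @ x >= -_FEAS_TOL):
                pts.append(x)
    if not pts:
        return np.empty((0, 2))
    uniq_list: list[np.ndarray] = []
    for x in pts:
        if not any(np.abs(x - u).max() < _VERTEX_DEDUP for u in uniq_list):
            uniq_list.append(x)
    uniq = np.array(uniq_list)
    if uniq.shape[0] > 2:
        c = uniq.mean(axis=0)
        ang = np.arctan2(uniq[:, 1] - c[1], uniq[:, 0] - c[0])
        uniq = uniq[np.argsort(ang)]
    return uniq


def feasible_region(particular: np.ndarray, p: float) -> SolutionManifold:
    """Map the solution set of M(p) delta = g to its (xi, eta) polygon.

    The nine half-planes ``particular_k + xi z1_k + eta z2_k >= 0`` are
    intersected; vertices are enumerated, per-coefficient attainable
    ranges are computed over the vertices (the coefficients are linear
    in (xi, eta), so vertex scan is exact), and the Chebyshev center is
    located by linear programming.  An empty polygon is reported as
    such, not raised.
    """
    particular = np.asarray(particular, dtype=float)
    nd = null_directions(p)
    Zk = np.column_stack([nd.z1, nd.z2])  # 9 x 2
    polygon = _polygon_vertices(particular, Zk)
    if polygon.shape[0] == 0:
        # the polygon may be a single point or genuinely empty; try LP
        res = linprog(
            c=[0.0, 0.0],
            A_ub=-Zk,
            b_ub=particular,
            bounds=[(None, None)] * 2,
            method="highs",
        )
        if res.success:
            polygon = np.array([res.x])
    if polygon.shape[0] == 0:
        ranges = np.full((9, 2), np.nan)
        return SolutionManifold(particular, nd, polygon, ranges, None)
    deltas = particular[None, :] + polygon @ Zk.T  # n_vertices x 9
    ranges = np.column_stack([deltas.min(axis=0), deltas.max(axis=0)])
    center = _chebyshev_center(particular, Zk)
    return SolutionManifold(particular, nd, polygon, ranges, center)


def _chebyshev_center(b: np.ndarray, Zk: np.ndarray):
    """Center of the largest disc inscribed in {b + Zk x >= 0}."""
    norms = np.linalg.norm(Zk, axis=1)
    ok = norms > 0
    # maximize r s.t. Zk x + b >= r * ||Zk row||
    A_ub = np.column_stack([-Zk[ok], norms[ok]])
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=A_ub,
        b_ub=b[ok],
        bounds=[(None, None), (None, None), (0, None)],
        method="highs",
    )
    if not res.success:
        return None
    return (float(res.x[0]), float(res.x[1]))
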