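"""Constrained least-squares fitting of the condensed identity coefficients.

For each pair the fit minimizes the residual sum of squares

    sigma(delta) = (gbar - Mbar @ delta)' (gbar - Mbar @ delta)

over the probability simplex (delta_k >= 0, sum delta_k = 1).  This is
a small convex quadratic program; the production solver turns it into a
non-negative least-squares problem by appending a heavily weighted
sum-to-one row (Lawson-Hanson NNLS then solves it exactly up to the
penalty weight, 1e6 by default, which bounds the equality violation far
below the 1e-8 convergence tolerance).  An SLSQP route is kept for
cross-checking.

Fit modes restrict the parameter set:

``full9``      all nine coefficients free on the simplex.
``reduced7``   transpose-pair states merged (3+5 and 4+6), seven
               parameters; reported expanded to nine slots with an
               equal split, and the per-individual parameters
               (theta2i, theta2j, theta4) left undefined.
``cotterman``  no inbreeding: states 1-6 fixed at zero; optionally with
               the genealogical-feasibility constraint
               Delta8^2 >= 4 Delta7 Delta9.
``unrelated``  all related states (1, 3, 5, 7, 8) fixed at zero.

Self pairs are fit on the one-parameter family
alpha*e1 + (1-alpha)*e7 (an individual is always IBD with itself,
either inbred or not); the solution is the clipped 1-D least-squares
projection and alpha is the inbreeding estimate.

The state probabilities themselves are not identified: the solver
returns one point of the optimal set, and the identifiable parameters
theta = Q @ delta_hat are always reported alongside (they are constant
across the optimal set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar, nnls

from .genotype_io import FrequencyVector, GenotypeMatrix, average_system, pair_count_matrices
from .identity_core import (
    CondensedSystem,
    IdentifiableTheta,
    Q_MATRIX,
    STATE_SWAP,
    expand_reduced,
    identifiable_transform,
    reduce_system,
)

__all__ = ["FitConfig", "PairFit", "JacquardField", "fit_pair", "fit_self", "fit_all"]

MODES = ("full9", "reduced7", "cotterman", "unrelated", "self")

#: Free columns per restricted mode (0-based state indices).
_MODE_COLUMNS = {
    "full9": np.arange(9),
    "cotterman": np.array([6, 7, 8]),
    "unrelated": np.array([1, 3, 5, 8]),
}

_SUM_PENALTY = 1e6


@dataclass
class FitConfig:
    """Settings for the per-pair constrained least-squares fit."""

    mode: str = "full9"
    tolerance: float = 1e-8
    thompson_constraint: bool = False
    max_iterations: int = 200
    solver: str = "nnls"  # "nnls" (penalized NNLS) or "slsqp"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.thompson_constraint and self.mode != "cotterman":
            raise ValueError(
                "the Delta8^2 >= 4 Delta7 Delta9 constraint applies to "
                "cotterman mode only"
            )


@dataclass
class PairFit:
    """Result of one pairwise fit."""

    delta_hat: np.ndarray
    rss: float
    converged: bool
    theta_hat: IdentifiableTheta
    mode: str = "full9"
    delta_reduced: np.ndarray | None = None


class JacquardField:
    """Nine n x n matrices of pairwise state probabilities.

    Constructed from ordered fits with i < j; the (j, i) entries follow
    from the state permutation under pair reversal, so the transpose
    structure (Delta3 = Delta5', Delta4 = Delta6', symmetry of the
    rest) holds exactly by construction.  Diagonals carry the self-pair
    fits: only Delta1 and Delta7 are non-zero there and they sum to one.
    """

    def __init__(self, sample_ids: list[str], mode: str = "full9"):
        n = len(sample_ids)
        self.sample_ids = list(sample_ids)
        self.mode = mode
        self.deltas = np.zeros((9, n, n))
        self.rss = np.zeros((n, n))
        self.converged = np.zeros((n, n), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def delta(self, k: int) -> np.ndarray:
        """Matrix of coefficient k (1-based, as the states are named)."""
        return self.deltas[k - 1]

    def set_pair(self, i: int, j: int, fit: PairFit) -> None:
        if i == j:
            self.deltas[:, i, i] = fit.delta_hat
        else:
            self.deltas[:, i, j] = fit.delta_hat
            self.deltas[:, j, i] = fit.delta_hat[STATE_SWAP]
        self.rss[i, j] = self.rss[j, i] = fit.rss
        self.converged[i, j] = self.converged[j, i] = fit.converged

    def inbreeding(self) -> np.ndarray:
        """Realized/estimated inbreeding: diagonal of Delta1."""
        return np.diagonal(self.deltas[0]).copy()

    def validate(self, atol: float = 1e-8) -> None:
        """Check the simplex, transpose and diagonal structure."""
        total = self.deltas.sum(axis=0)
        if not np.allclose(total, 1.0, atol=atol):
            raise ValueError("state probabilities must sum to one for every pair")
        if self.deltas.min() < -atol:
            raise ValueError("negative state probability")
        if not np.allclose(self.deltas[2], self.deltas[4].T, atol=atol):
            raise ValueError("Delta3 must equal Delta5 transposed")
        if not np.allclose(self.deltas[3], self.deltas[5].T, atol=atol):
            raise ValueError("Delta4 must equal Delta6 transposed")
        for k in (0, 1, 6, 7, 8):
            if not np.allclose(self.deltas[k], self.deltas[k].T, atol=atol):
                raise ValueError(f"Delta{k + 1} must be symmetric")
        for k in (1, 2, 3, 4, 5, 7, 8):
            if np.abs(np.diagonal(self.deltas[k])).max() > atol:
                raise ValueError(f"Delta{k + 1} must have a zero diagonal")

    def permute(self, order: np.ndarray) -> "JacquardField":
        """Relabel samples: consistent permutation of every matrix."""
        order = np.asarray(order)
        out = JacquardField([self.sample_ids[i] for i in order], mode=self.mode)
        out.deltas = self.deltas[:, order][:, :, order]
        out.rss = self.rss[order][:, order]
        out.converged = self.converged[order][:, order]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of per-pair coefficients (ordered pairs)."""
        n = self.n
        rows = []
        for i in range(n):
            for j in range(n):
                rows.append(
                    {
                        "id_i": self.sample_ids[i],
                        "id_j": self.sample_ids[j],
                        **{f"delta{k + 1}": self.deltas[k, i, j] for k in range(9)},
                        "rss": self.rss[i, j],
                        "converged": self.converged[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _simplex_nnls(A: np.ndarray, b: np.ndarray, penalty: float = _SUM_PENALTY):
    """min ||A x - b|| s.t. x >= 0, 1'x = 1 via a penalized NNLS."""
    k = A.shape[1]
    A_aug = np.vstack([A, penalty * np.ones((1, k))])
    b_aug = np.concatenate([b, [penalty]])
    x, _ = nnls(A_aug, b_aug)
    s = x.sum()
    if s > 0:
        x = x / s
    return x


def _simplex_slsqp(A: np.ndarray, b: np.ndarray, tol: float, maxiter: int):
    k = A.shape[1]
    x0 = np.full(k, 1.0 / k)

    def obj(x):
        r = A @ x - b
        return r @ r

    def grad(x):
        return 2.0 * A.T @ (A @ x - b)

    res = minimize(
        obj,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
        options={"ftol": tol, "maxiter": maxiter},
    )
    return np.clip(res.x, 0.0, None), bool(res.success)


def _rss(A: np.ndarray, x: np.ndarray, b: np.ndarray) -> float:
    r = A @ x - b
    return float(r @ r)


def _fit_cotterman_thompson(
    m: np.ndarray, gbar: np.ndarray, free: np.ndarray, tol: float, maxiter: int
) -> np.ndarray:
    """Cotterman fit under Delta8^2 >= 4 Delta7 Delta9.

    The feasible set is the 3-simplex on (Delta7, Delta8, Delta9) minus
    the open region below the Hardy-Weinberg-like curve
    Delta8^2 = 4 Delta7 Delta9.  If the unconstrained simplex optimum is
    feasible it is returned; otherwise the optimum lies on the curve,
    which is parametrized as (t^2, 2t(1-t), (1-t)^2), t in [0, 1], and
    minimized as a 1-D problem.
    """
    A = m[:, free]
    x = _simplex_nnls(A, gbar)
    if x[1] ** 2 >= 4.0 * x[0] * x[2] - tol:
        return x

    def obj(t):
        xt = np.array([t * t, 2.0 * t * (1.0 - t), (1.0 - t) ** 2])
        r = A @ xt - gbar
        return r @ r

    res = minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    # guard against local dips: coarse grid comparison
    ts = np.linspace(0.0, 1.0, 513)
    vals = [obj(t) for t in ts]
    t_grid = ts[int(np.argmin(vals))]
    t = res.x if obj(res.x) <= obj(t_grid) else t_grid
    return np.array([t * t, 2.0 * t * (1.0 - t), (1.0 - t) ** 2])


def fit_pair(
    gbar: np.ndarray, mbar: CondensedSystem, config: FitConfig | None = None
) -> PairFit:
    """Constrained least-squares fit of one ordered pair.

    ``gbar`` is the observed joint genotype proportion vector (sums to
    one); ``mbar`` the (averaged) condensed system.  Solver failures are
    flagged on the returned fit rather than raised.
    """
    config = config or FitConfig()
    gbar = np.asarray(gbar, dtype=float)
    if gbar.shape != (9,):
        raise ValueError("gbar must be a 9-vector")
    if config.mode == "self":
        return fit_self(gbar, mbar)

    m = mbar.m
    if config.mode == "reduced7":
        if m.shape == (9, 9):
            mred = reduce_system(mbar).m
        elif m.shape == (9, 7):
            mred = m
        else:
            raise ValueError("reduced fit expects a 9x9 or 9x7 system")
        converged = True
        try:
            if config.solver == "slsqp":
                x, converged = _simplex_slsqp(
                    mred, gbar, config.tolerance, config.max_iterations
                )
            else:
                x = _simplex_nnls(mred, gbar)
        except Exception:
            x = np.full(7, 1.0 / 7.0)
            converged = False
        delta = expand_reduced(x)
        t = Q_MATRIX @ delta
        theta = IdentifiableTheta(t[0], np.nan, np.nan, t[3], np.nan)
        return PairFit(
            delta_hat=delta,
            rss=_rss(mred, x, gbar),
            converged=converged,
            theta_hat=theta,
            mode="reduced7",
            delta_reduced=x,
        )

    if m.shape != (9, 9):
        raise ValueError(f"mode {config.mode!r} expects a 9x9 system")
    free = _MODE_COLUMNS[config.mode]
    converged = True
    try:
        if config.mode == "cotterman" and config.thompson_constraint:
            x = _fit_cotterman_thompson(
                m, gbar, free, config.tolerance, config.max_iterations
            )
        elif config.solver == "slsqp":
            x, converged = _simplex_slsqp(
                m[:, free], gbar, config.tolerance, config.max_iterations
            )
        else:
            x = _simplex_nnls(m[:, free], gbar)
    except Exception:
        x = np.full(free.size, 1.0 / free.size)
        converged = False
    delta = np.zeros(9)
    delta[free] = x
    return PairFit(
        delta_hat=delta,
        rss=_rss(m[:, free], x, gbar),
        converged=converged,
        theta_hat=identifiable_transform(delta),
        mode=config.mode,
    )


def fit_self(gbar_self: np.ndarray, mbar: CondensedSystem) -> PairFit:
    """Fit of an individual with itself: delta = alpha*e1 + (1-alpha)*e7.

    The 1-D least-squares solution has a closed form; alpha is clipped
    to [0, 1] and equals the inbreeding estimate.
    """
    gbar_self = np.asarray(gbar_self, dtype=float)
    m = mbar.m
    if m.shape != (9, 9):
        raise ValueError("self fit expects a 9x9 system")
    c1, c7 = m[:, 0], m[:, 6]
    d = c1 - c7
    denom = d @ d
    alpha = float((gbar_self - c7) @ d / denom) if denom > 0 else 0.0
    alpha = float(np.clip(alpha, 0.0, 1.0))
    delta = np.zeros(9)
    delta[0], delta[6] = alpha, 1.0 - alpha
    r = gbar_self - (alpha * c1 + (1.0 - alpha) * c7)
    return PairFit(
        delta_hat=delta,
        rss=float(r @ r),
        converged=True,
        theta_hat=identifiable_transform(delta),
        mode="self",
    )


def fit_all(
    g: GenotypeMatrix,
    freqs: FrequencyVector,
    config: FitConfig | None = None,
    pairs: list[tuple[int, int]] | None = None,
    locus_mask: np.ndarray | None = None,
) -> JacquardField:
    """Fit every requested pair and assemble the coefficient field.

    Each unordered pair is fit once in the order i < j; the reverse
    order follows from the state permutation.  Diagonals come from the
    self-pair fit.  A failing pair is flagged, not fatal.
    """
    config = config or FitConfig()
    mbar = average_system(freqs, locus_mask)
    mred = reduce_system(mbar) if config.mode == "reduced7" else None
    C, n_valid = pair_count_matrices(g, locus_mask)
    n = g.n_individuals
    field = JacquardField(g.sample_ids, mode=config.mode)
    if pairs is None:
        pair_list = [(i, j) for i in range(n) for j in range(i, n)]
    else:
        pair_list = [(min(i, j), max(i, j)) for i, j in pairs]
        pair_list += [(i, i) for i in sorted({k for ij in pair_list for k in ij})]
        pair_list = sorted(set(pair_list))
    system = mred if mred is not None else mbar
    for i, j in pair_list:
        nv = n_valid[i, j]
        if nv == 0:
            field.converged[i, j] = field.converged[j, i] = False
            continue
        gbar = C[:, i, j] / nv
        if i == j:
            fit = fit_self(gbar, mbar)
        else:
            fit = fit_pair(gbar, system, config)
        field.set_pair(i, j, fit)
    return field
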