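"""Algebra of the bi-allelic condensed identity-state system.

The nine condensed identity states describe the possible patterns of
identity by descent (IBD) among the four alleles carried by an ordered
pair of diploid individuals at one locus, when maternal/paternal origin
is ignored.  States 1-6 involve within-individual IBD (inbreeding);
states 7-9 are the non-inbred states whose renormalized probabilities
are the Cotterman coefficients.

For a bi-allelic locus with minor-allele probability ``p`` the joint
genotype probabilities of a pair are linear in the state probabilities
``Delta_1..Delta_9``::

    g = M(p) @ delta

with ``M(p)`` the 9x9 condensed-system matrix built here.  ``M`` is
structurally singular: its columns sum to one and it annihilates a fixed
row vector, so its rank is at most 7 and the state probabilities are not
identifiable from bi-allelic data.  The five-parameter linear transform
``theta = Q @ delta`` (kinship, the two pairwise inbreeding-type
probabilities, the three-allele IBD probability and the 4/6 asymmetry)
*is* identifiable: ``Q`` annihilates both null-space directions of
``M(p)``.

State ordering is fixed throughout the package: genotype-pair rows are
(0/0,0/0), (0/0,0/1), (0/0,1/1), (0/1,0/0), (0/1,0/1), (0/1,1/1),
(1/1,0/0), (1/1,0/1), (1/1,1/1) -- i.e. row index = 3*d_i + d_j for
minor-allele dosages d -- and columns are Delta_1..Delta_9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GENOTYPE_PAIR_ORDER",
    "Q_MATRIX",
    "A_CONSTRAINT",
    "Z1",
    "STATE_SWAP",
    "RANK_RTOL",
    "CondensedSystem",
    "IdentifiableTheta",
    "NullDirections",
    "build_condensed_matrix",
    "condensed_entries",
    "build_reduced_matrix",
    "identifiable_transform",
    "null_directions",
    "matrix_rank",
]

#: Ordered genotype-pair rows as (dosage_i, dosage_j).
GENOTYPE_PAIR_ORDER = [(a, b) for a in range(3) for b in range(3)]

#: 5x9 transform from state probabilities to the identifiable parameters
#: (theta1, theta2i, theta2j, theta3, theta4).
Q_MATRIX = np.array(
    [
        [1, 0, 0.5, 0, 0.5, 0, 0.5, 0.25, 0],
        [1, 1, 1, 1, 0, 0, 0, 0, 0],
        [1, 1, 0, 0, 1, 1, 0, 0, 0],
        [1, 1, 1, 0.5, 1, 0.5, 1, 0.5, 0],
        [0, 0, 0, 0.5, 0, -0.5, 0, 0, 0],
    ]
)

#: Row vector annihilated by M(p) from the left: A_CONSTRAINT @ M(p) = 0.
A_CONSTRAINT = np.array([0, -1, -2, 1, 0, -1, 2, 1, 0], dtype=float)

#: p-free null-space direction of M(p).
Z1 = np.array([0, 1, 0, -1, 0, -1, -1, 2, 0], dtype=float)

#: 0-based permutation of state indices under pair-order reversal
#: (states 3<->5 and 4<->6 swap; all others are symmetric).
STATE_SWAP = np.array([0, 1, 4, 5, 2, 3, 6, 7, 8])

#: Relative singular-value cutoff for numeric rank determination.
RANK_RTOL = 1e-10


@dataclass
class CondensedSystem:
    """A condensed-system matrix (9x9, or 9x7 in the reduced mode).

    Parameters
    ----------
    m
        The matrix mapping state probabilities to joint genotype
        probabilities.
    p_source
        Free-text description of the allele-frequency input (a single
        value, or an average over loci).
    """

    m: np.ndarray
    p_source: str = ""

    @property
    def n_params(self) -> int:
        return self.m.shape[1]

    def rank(self) -> int:
        return matrix_rank(self.m)

    def validate(self, atol: float = 1e-10) -> None:
        """Check the structural constraints (column sums; a'M = 0)."""
        colsums = self.m.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=atol):
            raise ValueError("condensed-system columns must sum to one")
        if self.m.shape[1] == 9:
            if not np.allclose(A_CONSTRAINT @ self.m, 0.0, atol=atol):
                raise ValueError("a'M = 0 violated")


@dataclass
class IdentifiableTheta:
    """The five identifiable relatedness parameters of an ordered pair."""

    theta1: float
    theta2i: float
    theta2j: float
    theta3: float
    theta4: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.theta1, self.theta2i, self.theta2j, self.theta3, self.theta4]
        )


@dataclass
class NullDirections:
    """Basis of the null space of M(p) for generic p.

    ``z1`` is frequency-free; ``z2`` depends on the allele probability
    through the product pq.  Both directions are annihilated by Q, which
    is what makes the theta parameters identifiable while the state
    probabilities themselves are not.
    """

    z1: np.ndarray
    z2: np.ndarray
    p: float


def matrix_rank(m: np.ndarray, rtol: float = RANK_RTOL) -> int:
    """Numeric rank with a relative singular-value cutoff."""
    s = np.linalg.svd(m, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def condensed_entries(p: np.ndarray) -> np.ndarray:
    """Condensed-system matrices for an array of allele probabilities.

    Returns an array of shape ``p.shape + (9, 9)``; used to average the
    system over loci without a per-locus Python loop.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("allele probability must lie in [0, 1]")
    q = 1.0 - p
    o = np.zeros(np.shape(p))
    pq = p * q
    p2, p3, p4 = p * p, p**3, p**4
    q2, q3, q4 = q * q, q**3, q**4
    pq2 = p * q2  # p q^2
    p2q = p2 * q  # p^2 q
    p2q2 = p2 * q2
    rows = [
        [q, q2, q2, q3, q2, q3, q2, q3, q4],
        [o, o, pq, 2 * pq2, o, o, o, pq2, 2 * p * q3],
        [o, pq, o, p2q, o, pq2, o, o, p2q2],
        [o, o, o, o, pq, 2 * pq2, o, pq2, 2 * p * q3],
        [o, o, o, o, o, o, 2 * pq, p2q + pq2, 4 * p2q2],
        [o, o, o, o, pq, 2 * p2q, o, p2q, 2 * p3 * q],
        [o, pq, o, pq2, o, p2q, o, o, p2q2],
        [o, o, pq, 2 * p2q, o, o, o, p2q, 2 * p3 * q],
        [p, p2, p2, p3, p2, p3, p2, p3, p4],
    ]
    m = np.array([[np.broadcast_to(e, np.shape(p)) for e in row] for row in rows])
    # m currently has shape (9, 9) + p.shape; move row/col axes last
    return np.moveaxis(m, (0, 1), (-2, -1))


def build_condensed_matrix(p: float) -> CondensedSystem:
    """The 9x9 condensed-system matrix M(p) for one allele probability.

    Rows are ordered genotype pairs (row index ``3*d_i + d_j``), columns
    are Delta_1..Delta_9.  Degenerate p in {0, 1} is allowed (columns
    collapse); callers decide whether to filter such loci.
    """
    p = float(p)
    return CondensedSystem(m=condensed_entries(p), p_source=f"p={p}")


def build_reduced_matrix(p: float) -> CondensedSystem:
    """The 9x7 reduced system merging the transpose-pair states.

    States 3/5 and 4/6 swap under reversal of the pair order, so their
    probabilities may be summed into a single parameter each.  The
    merged column is the arithmetic mean of the two parent columns, so
    the merged parameter represents the total Delta3+Delta5
    (resp. Delta4+Delta6) under the equal-split convention.  Columns
    still sum to one.  Note that both null directions of M(p) respect
    the merged structure, so the reduced matrix has numeric rank 5 at
    generic p: the reduction lowers the parameter count, it does not
    restore identifiability.
    """
    m = condensed_entries(float(p))
    merged35 = 0.5 * (m[:, 2] + m[:, 4])
    merged46 = 0.5 * (m[:, 3] + m[:, 5])
    red = np.column_stack(
        [m[:, 0], m[:, 1], merged35, merged46, m[:, 6], m[:, 7], m[:, 8]]
    )
    return CondensedSystem(m=red, p_source=f"p={float(p)} (reduced)")


def reduce_system(system: CondensedSystem) -> CondensedSystem:
    """Merge the Delta3/5 and Delta4/6 columns of an existing 9x9 system."""
    m = system.m
    if m.shape != (9, 9):
        raise ValueError("expected a 9x9 condensed system")
    red = np.column_stack(
        [
            m[:, 0],
            m[:, 1],
            0.5 * (m[:, 2] + m[:, 4]),
            0.5 * (m[:, 3] + m[:, 5]),
            m[:, 6],
            m[:, 7],
            m[:, 8],
        ]
    )
    return CondensedSystem(m=red, p_source=system.p_source + " (reduced)")


def expand_reduced(delta7: np.ndarray) -> np.ndarray:
    """Expand a 7-vector from the reduced fit back to 9 state slots.

    The merged totals are split equally between states 3/5 and 4/6; the
    individual split is not identified, so only sum-based derived
    quantities (theta1, theta3) are meaningful afterwards.
    """
    d = np.asarray(delta7, dtype=float)
    if d.shape != (7,):
        raise ValueError("expected a 7-vector")
    return np.array(
        [d[0], d[1], d[2] / 2, d[3] / 2, d[2] / 2, d[3] / 2, d[4], d[5], d[6]]
    )


def identifiable_transform(delta: np.ndarray) -> IdentifiableTheta:
    """theta = Q @ delta, the identifiable relatedness parameters.

    The transform is linear and is applied as-is; non-negativity of the
    input is not required (exact-solver particular solutions may carry
    negative entries, yet their theta is well defined).
    """
    d = np.asarray(delta, dtype=float)
    if d.shape != (9,):
        raise ValueError(f"expected a 9-vector of state probabilities, got {d.shape}")
    t = Q_MATRIX @ d
    return IdentifiableTheta(*t)


def null_directions(p: float) -> NullDirections:
    """Null-space basis (z1, z2) of M(p) for 0 < p < 1.

    z1 = (0, 1, 0, -1, 0, -1, -1, 2, 0) is frequency-free;
    z2 = (0, 0, 0, 0, 0, 0, 1, -2, 1) + pq (-1, -1, 2, 0, 2, 0, -2, 0, 0).
    Both satisfy M(p) z = 0, 1'z = 0 and Q z = 0, so the identifiable
    parameters are constant along the solution manifold
    delta + xi*z1 + eta*z2.
    """
    p = float(p)
    pq = p * (1.0 - p)
    z2 = np.array([0, 0, 0, 0, 0, 0, 1, -2, 1], dtype=float) + pq * np.array(
        [-1, -1, 2, 0, 2, 0, -2, 0, 0], dtype=float
    )
    return NullDirections(z1=Z1.copy(), z2=z2, p=p)
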