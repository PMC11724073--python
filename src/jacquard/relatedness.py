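"""Relationship parameters derived from a field of identity coefficients.

From the nine pairwise coefficient matrices this module derives:

* the kinship/coancestry matrix
  ``theta1 = Delta1 + (Delta3 + Delta5 + Delta7)/2 + Delta8/4``,
  whose diagonal is (1 + F)/2 with F the individual inbreeding
  coefficient (the diagonal of Delta1);
* the pairwise inbreeding-type matrices
  ``theta2i = Delta1 + Delta2 + Delta3 + Delta4`` (and its transpose
  for the second member of the pair);
* the probability of at least one IBD pair among three sampled alleles
  (theta3) and the skew-symmetric 4/6 asymmetry (theta4);
* relative coancestry and inbreeding (psi1, psi2): coancestry measured
  against the average pairwise coancestry theta_S of the sample, so the
  off-diagonal mean of psi1 is zero by construction;
* frequency-free allele-sharing statistics: the mean proportion of
  identical-in-state allele pairs among the 2x2 cross-pairs of a pair
  of individuals (A_ij), individual homozygosity (A_i), and their
  relative estimators (A_ij - A_S)/(1 - A_S), (A_i - A_S)/(1 - A_S).

Per-locus IBS sharing for dosages (x_i, x_j) is
``[x_i x_j + (2 - x_i)(2 - x_j)] / 4``; over the nine genotype pairs
this equals 1 for identical homozygotes, 0 for opposite homozygotes,
1/2 whenever at least one member is heterozygous, and 1/2 for a
het-het pair (two of the four cross-pairs match).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cls_estimator import JacquardField
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "ThetaField",
    "RelativeField",
    "AlleleSharing",
    "derive_theta",
    "relative_coefficients",
    "allele_sharing",
]


@dataclass
class ThetaField:
    """Matrices of the identifiable relatedness parameters."""

    theta1: np.ndarray
    theta2i: np.ndarray
    theta3: np.ndarray
    theta4: np.ndarray
    inbreeding: np.ndarray
    sample_ids: list[str]

    @property
    def theta2j(self) -> np.ndarray:
        return self.theta2i.T

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class RelativeField:
    """Coancestry and inbreeding relative to the sample average."""

    psi1: np.ndarray
    psi2: np.ndarray
    theta_s: float
    sample_ids: list[str]


@dataclass
class AlleleSharing:
    """Frequency-free identity-in-state statistics."""

    a_ij: np.ndarray
    a_i: np.ndarray
    a_s: float
    psi1_hat: np.ndarray
    psi2_hat: np.ndarray
    sample_ids: list[str]


def derive_theta(field: JacquardField, check: bool = True) -> ThetaField:
    """All theta matrices from a coefficient field.

    The field must satisfy the transpose/diagonal structure; set
    ``check=False`` to skip the validation (e.g. for large fields
    already validated upstream).
    """
    if check:
        field.validate()
    d = field.deltas
    theta1 = d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7]
    theta2i = d[0] + d[1] + d[2] + d[3]
    theta3 = d[0] + d[1] + d[2] + d[4] + d[6] + 0.5 * (d[3] + d[5] + d[7])
    theta4 = 0.5 * (d[3] - d[5])
    return ThetaField(
        theta1=theta1,
        theta2i=theta2i,
        theta3=theta3,
        theta4=theta4,
        inbreeding=np.diagonal(d[0]).copy(),
        sample_ids=list(field.sample_ids),
    )


def average_coancestry(theta1: np.ndarray) -> float:
    """Mean of theta1 over all n(n-1) ordered off-diagonal pairs."""
    n = theta1.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    W = 1.0 - np.eye(n)
    return float((theta1 * W).sum() / (n * (n - 1)))


def relative_coefficients(theta: ThetaField) -> RelativeField:
    """Relative coancestry/inbreeding: center on the sample average.

    psi1 = (theta1 - theta_S J) / (1 - theta_S);
    psi2 = (F - theta_S) / (1 - theta_S) = diag(psi1).
    The off-diagonal mean of psi1 is zero by construction.
    """
    ts = average_coancestry(theta.theta1)
    if ts >= 1.0:
        raise ValueError("average coancestry of one: relative scale degenerate")
    psi1 = (theta.theta1 - ts) / (1.0 - ts)
    psi2 = (theta.inbreeding - ts) / (1.0 - ts)
    # the diagonal carries relative inbreeding (centered F), not the
    # centered self-kinship (1 + F)/2, so that diag(psi1) == psi2
    np.fill_diagonal(psi1, psi2)
    return RelativeField(
        psi1=psi1, psi2=psi2, theta_s=ts, sample_ids=list(theta.sample_ids)
    )


def allele_sharing(g: GenotypeMatrix) -> AlleleSharing:
    """Mean IBS allele sharing and the derived relative estimators.

    Missing data: pairwise-complete loci for A_ij, per-individual
    non-missing loci for A_i.  Self-pairs are excluded from A_S (the
    diagonal of A_ij is reported but conveys homozygosity-like
    information only).
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    X = g.dosages.astype(np.float64)
    obs = g.dosages != MISSING
    Xo = np.where(obs, X, 0.0)
    Yo = np.where(obs, 2.0 - X, 0.0)
    num = Xo @ Xo.T + Yo @ Yo.T
    n_pair = obs.astype(np.float64) @ obs.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        a_ij = np.where(n_pair > 0, num / (4.0 * np.maximum(n_pair, 1)), np.nan)
    hom = (g.dosages == 0) | (g.dosages == 2)
    n_obs = obs.sum(axis=1)
    a_i = np.where(n_obs > 0, (hom & obs).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    n = g.n_individuals
    off = ~np.eye(n, dtype=bool)
    a_s = float(np.nanmean(a_ij[off]))
    with np.errstate(invalid="ignore", divide="ignore"):
        # a_s == 1 (every pair shares everything) leaves the relative
        # scale undefined; estimates come out NaN rather than raising
        psi1_hat = np.where(a_s < 1.0, (a_ij - a_s) / (1.0 - a_s), np.nan)
        psi2_hat = np.where(a_s < 1.0, (a_i - a_s) / (1.0 - a_s), np.nan)
    return AlleleSharing(
        a_ij=a_ij,
        a_i=a_i,
        a_s=a_s,
        psi1_hat=psi1_hat,
        psi2_hat=psi2_hat,
        sample_ids=list(g.sample_ids),
    )
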