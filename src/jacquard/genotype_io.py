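"""Genotype input, allele frequencies, pair tallies and system averaging.

Genotypes are held as minor-allele dosage matrices (individuals x loci,
values 0/1/2, -1 for missing).  Two on-disk formats are supported: VCF
with bi-allelic records (GT field, read through cyvcf2) and a plain TSV
dosage matrix (first column the sample id, header row the variant ids,
cells 0/1/2/NA).

The joint genotype tally of a pair over loci is the data vector of the
condensed-system fit: category k counts the loci whose ordered genotype
pair equals row k of the system matrix.  Tallies for all pairs at once
are computed with indicator cross-products (three boolean indicator
matrices and nine matrix products) rather than a per-locus loop; the
result is identical to naive tabulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .identity_core import CondensedSystem, condensed_entries

__all__ = [
    "GenotypeMatrix",
    "FrequencyVector",
    "PairCounts",
    "read_genotypes",
    "write_dosage_matrix",
    "allele_frequencies",
    "pair_counts",
    "pair_count_matrices",
    "average_system",
    "maf_mask",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Dosage matrix of minor-allele counts.

    ``dosages`` is an (n_individuals, n_loci) integer array with values
    in {0, 1, 2} and -1 for missing.  ``flipped`` records per-variant
    whether the dosage orientation was reversed to keep the counted
    allele the minor one.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, L = self.dosages.shape
        if n != len(self.sample_ids) or L != len(self.variant_ids):
            raise ValueError("dosage dimensions inconsistent with id lists")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        if self.flipped is None:
            self.flipped = np.zeros(L, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass
class FrequencyVector:
    """Per-locus frequencies of the counted (minor) allele."""

    p: np.ndarray
    source: str = "all"
    all_missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.all_missing is None:
            self.all_missing = np.zeros(self.p.size, dtype=bool)


@dataclass
class PairCounts:
    """Joint genotype tally of one ordered pair over loci."""

    counts: np.ndarray
    n_valid: int

    def gbar(self) -> np.ndarray:
        """Observed joint genotype proportions (the CLS data vector)."""
        if self.n_valid == 0:
            raise ValueError("no loci with both genotypes observed")
        return self.counts / self.n_valid


def read_genotypes(path, fmt: str = None, strict: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a TSV dosage matrix.

    Dosages count the ALT/"1" allele as written in the file; call
    :func:`orient_minor` to flip variants whose counted allele is the
    major one under a chosen frequency source.

    Parameters
    ----------
    path
        Input file.
    fmt
        "vcf" or "dosage-matrix"; inferred from the suffix when None.
    strict
        If True, a non-bi-allelic VCF record raises; otherwise it is
        skipped with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".bcf"} or path.name.endswith(
            ".vcf.gz"
        ) else "dosage-matrix"
    if fmt == "vcf":
        return _read_vcf(path, strict=strict)
    if fmt == "dosage-matrix":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf(path: Path, strict: bool = True) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            msg = f"non-bi-allelic record {v.CHROM}:{v.POS} ({v.REF}->{v.ALT})"
            if strict:
                raise ValueError(msg)
            warnings.warn(f"skipping {msg}")
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dos)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    dosages = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(dosages=dosages, sample_ids=samples, variant_ids=ids)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
    )


def write_dosage_matrix(g: GenotypeMatrix, path) -> None:
    """Write the TSV dosage-matrix format (NA for missing)."""
    df = pd.DataFrame(
        g.dosages.astype(object), index=g.sample_ids, columns=g.variant_ids
    )
    df = df.where(df != MISSING, "NA")
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def allele_frequencies(
    g: GenotypeMatrix, subset: list[str] | None = None, source: str | None = None
) -> FrequencyVector:
    """Sample frequencies of the counted allele over a sample subset.

    p_l = (sum of dosages over the subset, skipping missing) /
    (2 x number of non-missing genotypes).  Loci where the whole subset
    is missing are flagged (frequency reported as 0).
    """
    if subset is None:
        idx = np.arange(g.n_individuals)
        source = source or "all"
    else:
        if len(subset) == 0:
            raise ValueError("empty sample subset")
        idx = np.array([g.sample_index(s) for s in subset])
        source = source or "subset"
    X = g.dosages[idx]
    valid = X != MISSING
    n_obs = valid.sum(axis=0)
    total = np.where(valid, X, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, total / (2.0 * np.maximum(n_obs, 1)), 0.0)
    return FrequencyVector(p=p, source=source, all_missing=n_obs == 0)


def orient_minor(g: GenotypeMatrix, freqs: FrequencyVector):
    """Flip variants whose counted allele is the major one (p > 1/2).

    Ties (p = 1/2) keep the file orientation.  Returns a new matrix and
    the frequency vector of the re-oriented allele.
    """
    flip = freqs.p > 0.5
    dosages = g.dosages.copy()
    miss = dosages == MISSING
    dosages[:, flip] = 2 - dosages[:, flip]
    dosages[miss] = MISSING
    p = np.where(flip, 1.0 - freqs.p, freqs.p)
    gm = GenotypeMatrix(
        dosages=dosages,
        sample_ids=list(g.sample_ids),
        variant_ids=list(g.variant_ids),
        flipped=g.flipped ^ flip,
    )
    return gm, FrequencyVector(p=p, source=freqs.source, all_missing=freqs.all_missing)


def pair_counts(
    g: GenotypeMatrix, i: int, j: int, locus_mask: np.ndarray | None = None
) -> PairCounts:
    """Joint genotype tally of the ordered pair (i, j).

    Loci with either genotype missing are excluded (pairwise-complete
    deletion).  For a self pair (i == j) only categories 1, 5 and 9 can
    be non-zero.
    """
    n = g.n_individuals
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("sample index out of range")
    xi, xj = g.dosages[i], g.dosages[j]
    if locus_mask is not None:
        xi, xj = xi[locus_mask], xj[locus_mask]
    valid = (xi != MISSING) & (xj != MISSING)
    cat = 3 * xi[valid].astype(int) + xj[valid].astype(int)
    counts = np.bincount(cat, minlength=9)
    return PairCounts(counts=counts, n_valid=int(valid.sum()))


def pair_count_matrices(
    g: GenotypeMatrix, locus_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Tallies for all ordered pairs at once via indicator cross-products.

    Returns ``(C, n_valid)`` where ``C`` has shape (9, n, n) with
    ``C[3*a + b, i, j]`` the number of loci at which individual i has
    dosage a and individual j has dosage b (both observed), and
    ``n_valid[i, j]`` the number of pairwise-complete loci.
    """
    X = g.dosages
    if locus_mask is not None:
        X = X[:, locus_mask]
    n = X.shape[0]
    ind = [((X == a).astype(np.float64)) for a in range(3)]
    C = np.empty((9, n, n))
    for a in range(3):
        for b in range(3):
            C[3 * a + b] = ind[a] @ ind[b].T
    valid = (X != MISSING).astype(np.float64)
    n_valid = valid @ valid.T
    return C, n_valid


def average_system(
    freqs: FrequencyVector, locus_mask: np.ndarray | None = None
) -> CondensedSystem:
    """Unweighted average of the per-locus system matrices.

    Mbar = (1/L') sum_l M(p_l) over unmasked loci.  Powers of p are
    averaged as averages of the per-locus powers; no small-sample bias
    correction is applied.
    """
    p = freqs.p if locus_mask is None else freqs.p[locus_mask]
    if p.size == 0:
        raise ValueError("no unmasked loci to average over")
    mbar = condensed_entries(p).mean(axis=0)
    return CondensedSystem(
        m=mbar, p_source=f"average over {p.size} loci ({freqs.source})"
    )


def maf_mask(freqs: FrequencyVector, threshold: float | None) -> np.ndarray:
    """Locus mask keeping minor-allele frequency strictly above threshold.

    ``threshold=0`` keeps polymorphic loci only; ``threshold=None``
    bypasses filtering (all loci kept, monomorphic included).
    """
    if threshold is None:
        return np.ones(freqs.p.size, dtype=bool)
    if not (0.0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    maf = np.minimum(freqs.p, 1.0 - freqs.p)
    return maf > threshold
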