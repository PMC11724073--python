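"""Pedigree simulation, gene dropping and realized identity coefficients.

The generator emulates a closed breeding population: a founder
generation of unrelated individuals followed by non-overlapping
generations in which every female mates with one randomly chosen
breeding male (a random fraction of the males, one half by default, is
allowed to breed, which accelerates the build-up of relatedness) and
produces a Poisson-distributed number of offspring.

Founder minor-allele frequencies are independent Beta(1, 10) draws --
positively skewed, so most variants are rare.  Gene dropping transmits
founder-haplotype *labels* together with the alleles along a single
chromosome of equally spaced markers: each meiosis draws a Poisson
number of crossovers (mean = map length in Morgans), places them
uniformly on the marker grid, and switches the template haplotype at
each crossover position.

Because every founder haplotype carries a unique label, the condensed
identity state of any pair at any locus can be read off exactly from
the four labels; the per-pair state fractions over loci are the
realized ("gold") identity coefficients against which estimators are
benchmarked.  Realized coefficients fluctuate around their pedigree
expectations because meiosis is random and the map is finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cls_estimator import JacquardField

__all__ = [
    "SimConfig",
    "Pedigree",
    "LabeledGenomes",
    "GoldRecord",
    "PedigreeError",
    "generate_pedigree",
    "draw_founder_frequencies",
    "gene_drop",
    "condensed_state",
    "condensed_state_codes",
    "gold_coefficients",
]


class PedigreeError(RuntimeError):
    """A generation cannot be produced (e.g. no breeding males left)."""


@dataclass
class SimConfig:
    """Simulation settings.

    Defaults reproduce the benchmark design: 20 founders (10 male,
    10 female), seven non-overlapping generations in total, Poisson
    fertility with mean two per female, half of the males breeding,
    20,000 equally spaced loci on a five-Morgan map, Beta(1, 10)
    founder frequencies.
    """

    n_founder_males: int = 10
    n_founder_females: int = 10
    n_generations: int = 7
    fertility: float = 2.0
    male_breeding_fraction: float = 0.5
    L: int = 20_000
    map_length_morgans: float = 5.0
    beta_alpha: float = 1.0
    beta_beta: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_founder_males, self.n_founder_females) < 1:
            raise ValueError("need at least one founder of each sex")
        if self.n_generations < 1 or self.L < 1:
            raise ValueError("generations and locus count must be positive")
        if self.fertility <= 0 or self.map_length_morgans < 0:
            raise ValueError("fertility must be positive, map length non-negative")
        if not (0.0 < self.male_breeding_fraction <= 1.0):
            raise ValueError("male breeding fraction must lie in (0, 1]")
        if self.beta_alpha <= 0 or self.beta_beta <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass
class Pedigree:
    """Non-overlapping-generation pedigree; -1 marks a founder parent."""

    ids: list[str]
    sex: np.ndarray  # 'M'/'F'
    generation: np.ndarray
    mother: np.ndarray
    father: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def founders(self) -> np.ndarray:
        return np.where(self.generation == 0)[0]

    def last_generation(self) -> np.ndarray:
        return np.where(self.generation == self.generation.max())[0]

    def validate(self) -> None:
        """Acyclicity via strict generation ordering of parents."""
        for child in range(self.n):
            for par in (self.mother[child], self.father[child]):
                if par >= 0 and self.generation[par] != self.generation[child] - 1:
                    raise ValueError(
                        "parents must belong to the previous generation"
                    )
                if par < 0 and self.generation[child] != 0:
                    raise ValueError("non-founder with missing parent")

    def to_frame(self) -> pd.DataFrame:
        def name(k):
            return self.ids[k] if k >= 0 else "NA"

        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": self.sex,
                "generation": self.generation,
                "mother": [name(m) for m in self.mother],
                "father": [name(f) for f in self.father],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ids = [str(i) for i in df["id"]]
        lookup = {s: k for k, s in enumerate(ids)}
        def idx(v):
            return lookup[str(v)] if str(v) != "NA" else -1

        return cls(
            ids=ids,
            sex=df["sex"].to_numpy(dtype="U1"),
            generation=df["generation"].to_numpy(dtype=int),
            mother=np.array([idx(v) for v in df["mother"]]),
            father=np.array([idx(v) for v in df["father"]]),
        )


@dataclass
class LabeledGenomes:
    """Founder-labelled haplotypes for every pedigree member.

    ``labels[k, h, l]`` is the founder-haplotype label carried by
    individual k on haplotype h at locus l; ``founder_alleles[label, l]``
    the allele (0/1) of that founder haplotype, so the label determines
    the allele everywhere.
    """

    labels: np.ndarray  # (n, 2, L) int32
    founder_alleles: np.ndarray  # (2 * n_founders, L) int8
    pedigree: Pedigree

    def dosages(self) -> np.ndarray:
        loci = np.arange(self.labels.shape[2])
        a0 = self.founder_alleles[self.labels[:, 0, :], loci]
        a1 = self.founder_alleles[self.labels[:, 1, :], loci]
        return (a0 + a1).astype(np.int8)

    def genotype_matrix(self):
        from .genotype_io import GenotypeMatrix

        return GenotypeMatrix(
            dosages=self.dosages(),
            sample_ids=list(self.pedigree.ids),
            variant_ids=[f"snp{l}" for l in range(self.labels.shape[2])],
        )


@dataclass
class GoldRecord:
    """Realized identity coefficients from founder-allele labels."""

    field: JacquardField
    inbreeding: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inbreeding is None:
            self.inbreeding = self.field.inbreeding()


def generate_pedigree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> Pedigree:
    """Simulate the generation structure (no genetics yet).

    Each generation, a random ``male_breeding_fraction`` of the previous
    generation's males may breed; every female is paired with one of
    them uniformly at random and bears Poisson(fertility) offspring of
    random sex.  The total pedigree size is therefore stochastic.
    Raises :class:`PedigreeError` if a generation has no breeding males
    or no females.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids: list[str] = []
    sex: list[str] = []
    gen: list[int] = []
    mother: list[int] = []
    father: list[int] = []

    def add(s: str, g: int, mo: int, fa: int) -> int:
        k = len(ids)
        ids.append(f"G{g}I{k}")
        sex.append(s)
        gen.append(g)
        mother.append(mo)
        father.append(fa)
        return k

    for _ in range(config.n_founder_males):
        add("M", 0, -1, -1)
    for _ in range(config.n_founder_females):
        add("F", 0, -1, -1)

    prev = list(range(len(ids)))
    for g in range(1, config.n_generations):
        males = [k for k in prev if sex[k] == "M"]
        females = [k for k in prev if sex[k] == "F"]
        if not males:
            raise PedigreeError(f"no males available in generation {g - 1}")
        if not females:
            raise PedigreeError(f"no females available in generation {g - 1}")
        n_breed = max(1, round(config.male_breeding_fraction * len(males)))
        breeding = rng.choice(males, size=n_breed, replace=False)
        new: list[int] = []
        for mo in females:
            fa = int(rng.choice(breeding))
            for _ in range(rng.poisson(config.fertility)):
                s = "M" if rng.random() < 0.5 else "F"
                new.append(add(s, g, mo, fa))
        if not new:
            raise PedigreeError(f"generation {g} is empty")
        prev = new

    ped = Pedigree(
        ids=ids,
        sex=np.array(sex, dtype="U1"),
        generation=np.array(gen),
        mother=np.array(mother),
        father=np.array(father),
    )
    ped.validate()
    return ped


def draw_founder_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
):
    """Founder minor-allele probabilities: L independent Beta draws."""
    from .genotype_io import FrequencyVector

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = rng.beta(config.beta_alpha, config.beta_beta, size=config.L)
    return FrequencyVector(p=p, source="founder-truth")


def _gamete(
    parent_labels: np.ndarray, map_length: float, rng: np.random.Generator
) -> np.ndarray:
    """One meiosis: recombine the parent's two label haplotypes.

    Crossover count ~ Poisson(map length); integer positions uniform on
    [0, L); the template switches from position x onward.  Duplicate
    positions cancel pairwise.
    """
    L = parent_labels.shape[1]
    start = int(rng.integers(2))
    k = int(rng.poisson(map_length))
    if k == 0:
        return parent_labels[start]
    pos = rng.integers(0, L, size=k)
    switches = np.bincount(pos, minlength=L)
    hap = (start + np.cumsum(switches)) % 2
    return parent_labels[hap, np.arange(L)]


def gene_drop(
    ped: Pedigree,
    freqs,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> LabeledGenomes:
    """Drop founder alleles (with labels) down the pedigree."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = np.asarray(freqs.p, dtype=float)
    L = p.size
    founders = ped.founders()
    n_f = founders.size
    founder_alleles = (rng.random((2 * n_f, L)) < p).astype(np.int8)
    labels = np.zeros((ped.n, 2, L), dtype=np.int32)
    hap_of = {}
    for slot, k in enumerate(founders):
        labels[k, 0, :] = 2 * slot
        labels[k, 1, :] = 2 * slot + 1
        hap_of[k] = slot
    order = np.argsort(ped.generation, kind="stable")
    for k in order:
        mo, fa = ped.mother[k], ped.father[k]
        if mo < 0:
            continue
        labels[k, 0, :] = _gamete(labels[mo], config.map_length_morgans, rng)
        labels[k, 1, :] = _gamete(labels[fa], config.map_length_morgans, rng)
    return LabeledGenomes(labels=labels, founder_alleles=founder_alleles, pedigree=ped)


def condensed_state_codes(
    a1: np.ndarray, a2: np.ndarray, b1: np.ndarray, b2: np.ndarray
) -> np.ndarray:
    """Condensed state (1..9) from the four founder-haplotype labels.

    (a1, a2) are the labels of individual i, (b1, b2) of individual j;
    label equality is identity by descent.  Vectorized over loci.
    """
    a1, a2, b1, b2 = (np.asarray(x) for x in (a1, a2, b1, b2))
    ii = a1 == a2
    jj = b1 == b2
    c11 = a1 == b1
    c12 = a1 == b2
    c21 = a2 == b1
    c22 = a2 == b2
    n_cross = (
        c11.astype(np.int8) + c12.astype(np.int8) + c21.astype(np.int8) + c22.astype(np.int8)
    )
    share_i = c11 | c12  # a1 (== a2 when ii) IBD with some allele of j
    out = np.where(
        ii & jj,
        np.where(c11, 1, 2),
        np.where(
            ii,
            np.where(share_i, 3, 4),
            np.where(
                jj,
                np.where(c11 | c21, 5, 6),
                np.where(n_cross == 2, 7, np.where(n_cross == 1, 8, 9)),
            ),
        ),
    )
    return out.astype(np.int8)


def condensed_state(labels_i, labels_j) -> int:
    """Scalar convenience wrapper for one locus."""
    (a1, a2), (b1, b2) = labels_i, labels_j
    return int(condensed_state_codes(*(np.asarray([v]) for v in (a1, a2, b1, b2)))[0])


def gold_coefficients(
    genomes: LabeledGenomes, pairs: list[tuple[int, int]] | None = None
) -> GoldRecord:
    """Per-pair realized state fractions over all loci.

    Fractions sum to one; the transpose/diagonal structure holds
    exactly; self-pairs occupy states 1 and 7 only, with realized
    inbreeding the fraction of loci carrying two identical labels.
    """
    lab = genomes.labels
    n, _, L = lab.shape
    field = JacquardField(list(genomes.pedigree.ids), mode="gold")
    if pairs is None:
        pair_list = [(i, j) for i in range(n) for j in range(i, n)]
    else:
        pair_list = sorted({(min(i, j), max(i, j)) for i, j in pairs} | {
            (i, i) for ij in pairs for i in ij
        })
    from .cls_estimator import PairFit
    from .identity_core import identifiable_transform

    for i, j in pair_list:
        if i == j:
            f_i = float((lab[i, 0] == lab[i, 1]).mean())
            delta = np.zeros(9)
            delta[0], delta[6] = f_i, 1.0 - f_i
        else:
            codes = condensed_state_codes(lab[i, 0], lab[i, 1], lab[j, 0], lab[j, 1])
            counts = np.bincount(codes, minlength=10)[1:10]
            delta = counts / L
        fit = PairFit(
            delta_hat=delta,
            rss=0.0,
            converged=True,
            theta_hat=identifiable_transform(delta),
            mode="gold",
        )
        field.set_pair(i, j, fit)
    return GoldRecord(field=field)
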