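# Methods

## The condensed identity model

For an ordered pair of diploid individuals at a bi-allelic locus, the
nine condensed identity states partition the IBD configurations of the
four alleles.  With minor-allele probability *p* (q = 1 − p), the
9-vector of joint genotype probabilities (rows ordered (0/0,0/0),
(0/0,0/1), …, (1/1,1/1), i.e. row index 3·dᵢ + dⱼ on dosages) is
g = M(p)Δ.  The matrix M(p) implemented in `identity_core` satisfies,
for every p:

* **1′M = 1′** — each column is a probability distribution over the
  nine genotype pairs;
* **a′M = 0′** with a′ = (0, −1, −2, 1, 0, −1, 2, 1, 0) — a second
  left-null constraint;
* rank 7 for generic p, dropping to 5 at p = ½ (and degenerating at
  p ∈ {0, 1}, where the matrix is still constructed and callers decide
  whether to filter such loci).

The two right-null directions are

    z1 = (0, 1, 0, −1, 0, −1, −1, 2, 0)
    z2 = (0, 0, 0, 0, 0, 0, 1, −2, 1) + pq·(−1, −1, 2, 0, 2, 0, −2, 0, 0)

(both verified by direct multiplication in the test suite; note the
−2 in the eighth slot of z2's constant part, which is required for
1′z2 = 0 and M z2 = 0).  The identifiable transform θ = QΔ
(θ₁, θ₂ᵢ, θ₂ⱼ, θ₃, θ₄; Q of rank 5) annihilates both directions, so θ
is constant on the solution manifold — this is the precise sense in
which kinship and inbreeding are estimable although the Δ themselves
are not.  The same invariance holds for the locus-averaged system M̄:
its null space remains two-dimensional (z1 and a direction of the form
z2-with-an-effective-pq) and Q annihilates it, which the noiseless
recovery tests exploit.

## Estimation

**Pairwise CLS.**  ḡ is the empirical joint-genotype proportion vector
of a pair over loci (pairwise-complete deletion of missing genotypes);
M̄ is the unweighted average of M(p_l), with powers of p averaged as
averages of per-locus powers and no small-sample bias correction.
σ(Δ) = ‖ḡ − M̄Δ‖² is minimized over the simplex.  The problem is a
convex QP; the production solver appends a sum-to-one row weighted
1e6 to the design and calls Lawson–Hanson NNLS, which solves the
penalized problem exactly (equality violation ≲ residual/1e12, far
below the 1e-8 tolerance; the returned Δ̂ is renormalized to sum one).
An SLSQP route (uniform start Δ = 1/9, tolerance 1e-8) is retained as
an independent cross-check and agrees to the reported precision in the
tests.  Because the optimum is generally a face of the simplex, Δ̂ is
one point of the optimal set; θ̂ = QΔ̂ is always reported alongside and
is the quantity users should interpret.

**Fit modes.**  `full9` fits all nine coefficients.  `reduced7` merges
the transpose-pair states (3, 5) and (4, 6) into single total
parameters; merged columns are the mean of the parent columns, so the
merged parameter is the total under an equal split.  The split itself
is not identified, hence θ₂ᵢ, θ₂ⱼ and θ₄ are reported as undefined in
this mode (θ₁ and θ₃ depend only on the totals and remain available).
Note the reduction does not restore identifiability: both null
directions respect the merged structure, so the 9×7 matrix has rank 5.
`cotterman` fixes the six inbred states at zero; optionally the
genealogical-feasibility constraint Δ₈² ≥ 4Δ₇Δ₉ is imposed, whose
feasible set is non-convex — if the unconstrained optimum violates it
the optimum lies on the boundary curve, parametrized as
(t², 2t(1−t), (1−t)²) and solved as a bounded 1-D minimization checked
against a coarse grid.  `unrelated` fixes the related states
(1, 3, 5, 7, 8) at zero.  Constraint nesting (full9 ⊇ reduced7 ⊇
cotterman) guarantees monotone residuals, asserted in the tests.

**Self-pairs.**  Only states 1 and 7 are possible for an individual
with itself; the fit is the closed-form 1-D projection of ḡ onto the
segment between the two pure-state columns, clipped to [0, 1], and α̂
is the inbreeding estimate.

**Pair order.**  Each unordered pair is fit once with i < j; the
(j, i) entries follow from the state permutation (3↔5, 4↔6), so the
transpose structure of the coefficient field holds exactly by
construction.  Fitting the reversed tally directly would give the same
optimum value (the design and data transform consistently under the
permutation), but may return a different point of a non-unique optimal
face; deriving the reverse by permutation is both cheaper and exactly
self-consistent.

**Exact solvers.**  When a′g = 0 and 1′g = 1 hold to 1e-8 the system
is consistent and `exact_solver` returns a particular solution by
Moore–Penrose pseudoinverse or Gaussian elimination (the latter pins
Δ̂₈ = Δ̂₉ = 0 at generic rank — an instructive artifact of variable
ordering, not an inference).  The full non-negative solution set is
the polygon {(ξ, η) : Δ̂ + ξz1 + ηz2 ≥ 0}, built by pairwise
intersection of the nine half-plane boundaries with vertices
deduplicated at 1e-8 and feasibility tested at 1e-10.  Per-coefficient
attainable ranges come from a vertex scan (the coordinates are linear
in (ξ, η)); the polygon can legitimately degenerate to a segment or a
point when the generating coefficients touch the boundary of the
simplex.  The Chebyshev center (largest inscribed disc, via linear
programming) is offered as a canonical display representative — a
convention, not an estimate.  An inconsistency triggers a dedicated
error directing callers to the CLS fit, which is the correct tool for
empirical proportions.

## Derived parameters and conventions

θ₁ = Δ₁ + ½(Δ₃+Δ₅+Δ₇) + ¼Δ₈; θ₂ᵢ = Δ₁+Δ₂+Δ₃+Δ₄ (θ₂ⱼ its transpose);
θ₃ = Δ₁+Δ₂+Δ₃+Δ₅+Δ₇ + ½(Δ₄+Δ₆+Δ₈); θ₄ = ½(Δ₄−Δ₆) (skew-symmetric);
F = diag(Δ₁) and diag(θ₁) = (1+F)/2.

The average coancestry θ_S is the mean of θ₁ over all n(n−1) ordered
off-diagonal pairs.  Relative coancestry is
ψ₁ = (θ₁ − θ_S J)/(1 − θ_S) off the diagonal; the diagonal of ψ₁ is
defined as the relative inbreeding ψ₂ = (F − θ_S)/(1 − θ_S) rather
than the centered self-kinship — with diag(θ₁) = (1+F)/2 the two
conventions differ, and carrying ψ₂ on the diagonal keeps the identity
diag(Ψ₁) = ψ₂ exact.  Benchmark RMSEs are unaffected (ψ₁ is compared
off-diagonal, ψ₂ as a vector).

Allele sharing uses the per-locus dosage formula
[xᵢxⱼ + (2−xᵢ)(2−xⱼ)]/4, which equals the fraction of identical-in-
state pairs among the four cross-pairs for every one of the nine
genotype combinations (1 for identical homozygotes, 0 for opposite
homozygotes, ½ whenever a heterozygote is involved).  A_S averages
A_ij over distinct pairs only; self-sharing is not defined by the
estimator and homozygosity A_i is reported separately.

## The simulator

The generator emulates the benchmark design: 10 male + 10 female
founders, seven non-overlapping generations, every female mated to one
uniformly chosen breeding male (a random half of the males breed,
which accelerates inbreeding build-up), offspring counts
Poisson(fertility = 2), offspring sex Bernoulli(½).  Exactly two
offspring per female would fix the total at 140; Poisson fertility
makes the total stochastic (unconditional mean 140, conditional on
viability ≈ 149) with realizations spanning the reference scale of
about 111.  The benchmark harness therefore draws its realization
inside a size window (90–150) so that reported RMSEs refer to that
scale; the window is an explicit argument, not a hidden default.

Founder minor-allele frequencies are Beta(1, 10) draws (mean 1/11,
positive skew — most variants rare, ~11% monomorphic in a 20-founder
sample).  Gene dropping transmits founder-haplotype labels and alleles
together along a single chromosome of L equally spaced markers
spanning 5 Morgans: per meiosis, a Poisson(map length) number of
crossovers at uniform integer positions, the template switching from
each crossover position onward (duplicate positions cancel pairwise).
Realized ("gold") coefficients are the per-pair state fractions read
off the four labels at every locus; they satisfy the simplex,
transpose and diagonal identities *exactly* and fluctuate around
pedigree expectations because meiosis is random and the map finite
(e.g. full-sib (Δ₇, Δ₈, Δ₉) centers on (¼, ½, ¼) with per-pair spread
of a few percent on a 5-Morgan map).

What the simulator does **not** model: mutation, selection,
genotyping error, overlapping generations, sex chromosomes,
multi-chromosome maps, population structure, and coalescent variation
among founders (founders are exactly unrelated and non-inbred).
Passing benchmarks therefore speak to estimator behaviour under clean
genotypes with strong pedigree relatedness and imprecise allele
frequencies — not to robustness against genotyping error or
stratification.

## Benchmark and evaluation

RMSE conventions: coefficient matrices are compared off-diagonal (the
self-pair fit is a different problem); pairwise θ/ψ matrices
off-diagonal; per-individual vectors on all entries.  Pairwise
inbreeding-type estimates θ̂₂ᵢ^(i,j) are compared against the
individual's realized inbreeding, which is constant across pairs.
Gold relative quantities are centered on the gold θ_S, estimates on
the estimated θ̂_S.  One pedigree realization is shared by all
scenario rows (frequency source × MAF filter × mode), mirroring the
single-realization design of the reference table; the qualitative-
ordering checks use medians over five replicate seeds.  Problem sizes
used by the shipped tests and the acceptance script: the full
20,000-SNP, ~111-individual benchmark for headline RMSEs (a few
seconds per scenario); 2,000-SNP realizations for structural checks;
200 independent full-sib families at 1,000 SNPs for the sib-pair
center.

## Numerical choices

* Numeric rank: singular values above 1e-10 × the largest.
* NNLS sum-penalty weight 1e6; convergence tolerance 1e-8 throughout.
* Consistency checks (1′g = 1, a′g = 0) at 1e-8.
* Polygon vertex deduplication 1e-8, feasibility tolerance 1e-10.
* Monomorphic loci are included by default everywhere; MAF filtering
  (strictly greater-than threshold on min(p, 1−p)) is opt-in.
* Minor-allele orientation: dosages count the file's ALT/"1" allele;
  M(p) is valid for any p ∈ [0, 1], so orientation affects labelling
  only.  `orient_minor` flips variants with p > ½ (ties keep file
  order) for users who want canonical minor-allele coding.
* All randomness flows through one seeded generator per run; pedigree
  draws that go extinct (or miss a requested size window) are retried
  with deterministically shifted seeds, keeping every artifact
  reproducible from its seed.

## Known limitations

Δ̂ per pair is one representative of a non-unique optimum — compare θ̂,
not Δ̂, across software.  Coefficients Δ₆, Δ₈, Δ₉ carry the largest
errors at the benchmark scale, and coancestry/inbreeding are
systematically underestimated when allele frequencies come from the
related sample itself; founder frequencies, when available, remove
most of this bias.  The non-negativity constraint floors estimates at
zero and pulls the average coancestry toward zero, which propagates
into the relative quantities.  Genotype uncertainty (NGS likelihoods),
multi-allelic variants and EM/ML fitting are out of scope.
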