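# Methods

## Model and estimation chain

The evaluation model is a single-trait animal model
`y = Xb + Wu + e`, `var(u) = Hσᵤ²`, `var(e) = Iσₑ²`, with contemporary
groups (CG) as the only fixed effect, coded one column per level (no
intercept), which is full rank whenever every CG has at least one record.
Variance components are inputs, not estimated. The mixed-model equations
are kept in λ-form (both sides divided by σₑ², λ = σₑ²/σᵤ²); the stored
inverse of the coefficient matrix is rescaled by σₑ² so its animal block
is the prediction-error covariance of GEBV on the trait-variance scale,
and `ACC_j = sqrt(1 − PEV_j/σᵤ²)`, floored at 0 with the floored count
reported.

`H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]`. A and the inbreeding coefficients
come from the recursive tabular method (exact, O(n²), adequate for the
desk scale this package targets — up to a few tens of thousands of
animals); A⁻¹ from Henderson's sparse rules with inbreeding
(`d_i = 0.5 − 0.25(F_s + F_d)` with both parents known, `0.75 − 0.25F_p`
with one, 1 for founders); A₂₂⁻¹ by dense Cholesky of the extracted
block, never the genotyped sub-block of A⁻¹. Unknown parents are coded 0;
there are no unknown-parent groups. Pedigrees are re-ordered by a
deterministic Kahn topological sort that preserves file order among ready
animals, so identical inputs give identical matrices.

G is VanRaden's type-1 matrix from dosages centered by twice the allele
frequency of the current genotyped population, blended with A₂₂
(default α = 0.05) and tuned so its mean matches the mean of A₂₂
(δ = mean(A₂₂) − mean(G), b = 1 − δ/2). The tuning is computed from the
pre-blend mixture `(1−α)G₀ + αA₂₂` — the matrix that actually enters
H⁻¹ — rather than raw G₀; the alternative is available via
`tune_on="g0"` and differs negligibly in practice. Missing dosages are
mean-imputed at centering time (centered value 0); monomorphic SNPs are
kept as zero columns so SNP indexing is stable across animal subsets.

The APY inverse partitions the genotyped animals into core and non-core;
non-core animals receive a diagonal Mendelian-error term
`m_i = g_ii − G_ic Gcc⁻¹ G_ci`. The default core size is the number of
leading eigenvalues of G explaining 99% of its variance, the core drawn
uniformly at random with a mandatory seed.

### SNP effects, PEC, and IP accuracy

With `c = (1−α)b/k`, `k = 2Σpᵢ(1−pᵢ)`:

- `â = c Z′G⁻¹û₂`
- `var(â) = c²(Z′G⁻¹Z σᵤ² − Z′G⁻¹ C^{u₂u₂} G⁻¹Z)`, symmetrized
- `PEC = σₐ²I − var(â)`, `σₐ² = (1−α)bσᵤ²/k`
- `IP_j = z_j â`, with z centered by the *training* run's frequencies
- `ACC_IP_j = sqrt(1 − (z_j PEC z_j′)/σᵤ² − (1−(1−α)b))`, floored at 0

Two formulations deserve comment because the design was genuinely open.

**var(â) uses only G⁻¹, never G.** The algebraically equivalent form with
an inner factor `Gσᵤ² − C^{u₂u₂}` is exact for a true inverse but mixes
two different relationship matrices when G⁻¹ is the APY approximation; in
that case it can make PEC indefinite. Writing everything through G⁻¹ is
consistent with whatever relationship matrix the mixed model actually
used (for APY, the implied APY-G), and keeps var(â) positive
semi-definite by construction.

**The polygenic share in the IP accuracy.** Under blending, the blended
prior `G = b(1−α)G₀ + bαA₂₂ + 11′δ` decomposes an average genotyped
animal's unit prior variance into a marker share `(1−α)b` — the part an
indirect prediction can carry, whose estimation error is exactly
`z PEC z′` — and a remainder the markers cannot touch. An accuracy that
divides only `z PEC z′` by σᵤ² would report `sqrt(1−(1−α)b)` (≈ 0.28 at
α = 0.05) for an animal with *no data at all* and systematically
overstate IP accuracies by ~0.05 at typical accuracy levels, breaking the
method's defining property that IP accuracies be compatible with GEBV
accuracies. We therefore add the non-marker share `(1−(1−α)b)σᵤ²` to the
IP prediction-error variance. The share is a scalar (per-animal pedigree
information is deliberately not required at prediction time); the
mean-inflation of the tuned G (δ) enters the benchmark and IP accuracy
conventions symmetrically through b and cancels in their comparison. At
α = 0 the correction vanishes and the whole chain reduces exactly to
SNP-BLUP: `â` equals the SNP-BLUP solutions (1e-8), PEC equals the
`C^{gg}` block of the SNP-BLUP inverse (1e-6), and every training
animal's IP accuracy equals its GEBV accuracy (1e-8). These identities,
against an independent SNP-BLUP solver, are the package's calibration
anchor.

In the scenario battery, SNP effects always come from the direct
reduced-data evaluation (the "official" run); a scenario changes only the
evaluation whose MME inverse feeds the PEC. Subset-scenario PEC
evaluations are fit with the official run's allele frequencies, since the
PEC describes the error of that run's SNP effects.

### PEC file

The PEC matrix is persisted as a little-endian binary file: magic bytes,
a header (m, α, b, k, σᵤ², CRC32 of the allele frequencies rounded to
1e-9), then m×m float64 row-major. Round-trips are bit exact; the reader
refuses truncated files and, when frequencies are supplied, files whose
checksum does not match — the guard against scoring genotypes in the
wrong centering basis.

## Synthetic populations

The generator emulates a closed beef-cattle-like population: discrete
generations (default 150 founders + cohorts of 600/600/600/550),
sex-assigned parents from the previous generation, 25 sires per
generation used with Dirichlet(0.35)-skewed frequencies (a few heavily
used sires, many small families), dams drawn uniformly. 1,000 unlinked
biallelic SNPs with founder frequencies uniform on (0.05, 0.95) are
transmitted by gene dropping (one uniformly chosen allele per parent per
locus). True breeding values are fully marker-driven:
`a ~ N(0, σᵤ²/k₀)` i.i.d. with k₀ from the founder frequencies,
`u = Z a`, so the α → 0 equivalence identities hold exactly on simulated
data. Phenotypes `y = CG + u + e` with `σₑ² = σᵤ²(1−h²)/h²`
(defaults h² = 0.4, σᵤ² = 0.4, so σₑ² = 0.6) are recorded for the
intermediate generations only, six CG per generation with effects
N(0, 0.25). Genotyping is Bernoulli per animal with per-generation
probabilities (0.5, 0.85, 0.95, 0.95, 0.45); the genotyped animals of the
final generation form the validation cohort — no phenotypes, no progeny,
and their pedigree records are removed from the training data, exactly
the situation of young animals awaiting an interim prediction. All
randomness flows from one mandatory seed through stage-specific
substreams; identical seeds give byte-identical output files.

### What the standard benchmark can and cannot show

The standard benchmark (~2,500 animals, ~1,700 genotyped training, ~240
validation, 5-minute laptop scale) reproduces the method's qualitative
behaviour faithfully: IP recover benchmark GEBV at r ≈ 0.998; with all
training genotypes in the PEC the accuracy regression has slope ≈ 0.95–1
and intercept ≈ 0 with mean absolute accuracy differences ≈ 0.01; APY and
direct inverses agree to Δb1 ≤ 0.01; genotype subsets bias IP accuracies
downward, and heavier blending drags the calibration slope below 1.

Two quantitative features of large real populations do **not** scale
down, and tests pinned to them are expected to fail at this scale:

1. *Accuracy spread.* With unlinked common SNPs, marker information is
   population-wide, so genotyped-unphenotyped validation animals have
   nearly uniform theoretical accuracies (sd ≈ 0.016 here). Real LD-
   structured genomes concentrate information in families and produce the
   wide spreads seen in practice. With so little signal, the correlation
   between benchmark and IP accuracies saturates near 0.97, not 0.99, and
   the regression slope is seed-sensitive around 0.95: the residual noise
   is the information the benchmark has about the validation cohort's own
   genotypes, which the reduced run by definition lacks (building the PEC
   from the complete-data run instead gives r ≈ 0.99 and slope ≈ 1.0 —
   the chain itself is calibrated to ~1%).
2. *Effective dimensionality.* 1,000 unlinked SNPs give a G whose 99%
   eigenvalue count is ≈ m (≈ 58% of the training animals), whereas an
   LD-limited genome's dimension is a small fraction of the population.
   A random 27% genotype subset here spans only half of the marker space,
   so subset PEC accuracies degrade much faster (r ≈ 0.73) than in a real
   population where a same-fraction subset covers the full dimension.

## Numerical choices

Dense Cholesky factorizations throughout (no iterative solvers); all
inverses symmetrized `(M+M′)/2`. PEC must have minimum eigenvalue
≥ −1e-6·σₐ² (else an error, signalling inconsistent inputs); accuracies
floor negative reliabilities at 0 and report the floored count. The APY
error terms m_i must be strictly positive. Singular coefficient matrices
raise with a hint at the offending effect. Degenerate inputs (monomorphic
SNPs, all-missing SNP columns, empty CGs, cycles or duplicates in
pedigrees, ragged genotype rows) are rejected with specific messages.

## Known limitations

No linkage/LD in the generator; no residual polygenic effect in the
evaluation model (blending is its only surrogate, and the polygenic-share
scalar uses an average relationship of 1 rather than per-animal 1+F);
single trait, homogeneous residual variance, known variance components;
dense algebra only; no unknown-parent groups or metafounders. The hacc
selection breaks ties by animal order; subset draws are seeded and
logged.
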