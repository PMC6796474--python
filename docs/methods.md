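# Methods

## The model

`sstblup` solves the multi-trait animal model

    y = Xb + Zu + e,   var(u) = H ⊗ G0,   var(e) built from R0,

where `b` collects one fixed factor per trait, `u` the additive genetic
effects (t traits nested within each of n animals), `G0` and `R0` are the
t×t genetic and residual covariance matrices (always treated as known
inputs — no variance estimation), and `H` is the combined pedigree–genomic
relationship matrix of single-step evaluation: the pedigree numerator
relationship matrix `A` with its genotyped diagonal block replaced by a
weighted genomic relationship

    G_w = γ M D M' + λ C,

with `M` the centred/scaled marker matrix (m_g × m_m), `D` an SPD marker
weight matrix (identity by default), `C` an SPD add-on — normally the
genotyped block `A₂,₂` of `A`, in which case λ is the residual polygenic
proportion and γ = 1 − λ — and the change propagated through the pedigree.

Henderson's mixed model equations need `H⁻¹`, which equals `A⁻¹` plus a
genomic correction confined to the genotyped block. The package realises
that correction three equivalent ways, as interchangeable matrix-free
operators:

| formulation | correction | prepared up front | dense cost / application |
|---|---|---|---|
| explicit (`H`) | `G_w⁻¹ − A₂,₂⁻¹` | both m_g×m_g inverses | m_g² |
| Schur-implicit (`Htilde`) | `G_w⁻¹ − (A²² − A²¹(A¹¹)⁻¹A¹²)` | `G_w⁻¹`, sparse factor of `A¹¹` | m_g² + 1 sparse solve |
| Woodbury (`Psi`) | `(λ⁻¹−1)A₂,₂⁻¹ − M*M*'` | `M† = λ⁻¹A₂,₂⁻¹M`, `K_u`, `M* = M†K_u⁻¹` | 2·m_g·m_m + 1 sparse solve |

Here `A¹¹`, `A¹²`, `A²²` are blocks of `A⁻¹` partitioned by genotype
status, and the Schur complement `A²² − A²¹(A¹¹)⁻¹A¹²` equals `A₂,₂⁻¹`
without `A₂,₂` ever being formed. `K_u` is the upper Cholesky factor of
`γ⁻¹D⁻¹ + M'M†` (m_m × m_m), the only dense factorisation the Woodbury
route needs. That route is the only viable one when m_g > m_m: `M D M'`
is then rank deficient and `G` has no inverse, while `G_w⁻¹` applications
through the Woodbury identity

    (γMDM' + λC)⁻¹ = λ⁻¹C⁻¹ − λ⁻¹C⁻¹M(γ⁻¹D⁻¹ + M'λ⁻¹C⁻¹M)⁻¹M'C⁻¹λ⁻¹

remain well defined for any λ > 0.

`flop_count` tallies the dense work per solver round under a one
multiply-add = one FLOP convention: m_g² for the two explicit corrections,
2·m_g·m_m for the Woodbury one (at 150 000 genotypes this is 2.25×10¹⁰
dense FLOP per round for the explicit forms). The sparse-solve cost shared
by the implicit formulations is deliberately outside this count.

## Pedigree machinery

`A` is built by the tabular method; `A⁻¹` by Henderson's rules with
inbreeding coefficients taken from the tabular diagonal (adequate at desk
scale; a recursive method could replace it behind the same contract).
Unknown parents are founders with zero contribution — genetic groups are
not modelled, and an animal listed with more than one pair of parents is
rejected. Unsorted pedigrees are re-ordered topologically (stable in input
order) rather than rejected; original ids are preserved in all outputs.

`A¹¹` is factorised once with SuperLU (`scipy.sparse.linalg.splu`) and
reused by every Schur-complement application. `diag(A₂,₂⁻¹)` — needed for
the block preconditioner — is computed exactly in column blocks at desk
scale; a Hutchinson estimator with ±1 Rademacher probes
(`sample_diag_A22inv`, unbiased, seeded) is provided for scales where the
exact sweep is too expensive. The probe distribution is a documented
estimator choice; no variance reduction is applied.

## Solver

The MME coefficient matrix is applied matrix-free: a data part
`W'R⁻¹W` evaluated per observed-trait pattern (each record carries one
trait; an animal's records across traits share the inverse of the matching
`R0` sub-matrix), plus `H⁻¹ ⊗ G0⁻¹` on the genetic block through the
pluggable operator. Equations are ordered fixed-effects first, then traits
nested within animal, which makes the preconditioner a scalar diagonal for
fixed levels and an exact t×t block per animal for the genetic equations.
The first level of each trait's fixed factor is dropped for full rank.

PCG stops when ‖y − Xb‖₂ / ‖y‖₂ ≤ tol, with tol = 2.68×10⁻⁹ by default
and max_iter = 10 × n_equations; hitting max_iter returns an unconverged
result with the full trace rather than raising. Because the three
formulations compute identical corrections through different
floating-point routes, their convergence traces overlay but the final
threshold crossing can differ by one round when the criterion lands within
round-off scatter of tol; the equivalence checks therefore require
round counts to differ by at most one (and to be exactly equal on most
instances), with solutions agreeing to 1e−6 relative.

Numerical choices: every matrix headed for Cholesky is symmetrised
((B+B')/2) first to absorb round-off; equivalence assertions use 1e−8
relative; `M*` is materialised explicitly as a preparation product rather
than kept as a triangular-solve closure.

## Synthetic data

The generator exists so that every module is testable without any external
download; its defaults define the study conditions used throughout the
tests:

- **Pedigree**: discrete generations, random mating among the previous
  generation (default 40 founders, 3 generations, n_founders/2 matings of
  2 offspring each). Size is exact: n_founders + Σ matings × offspring.
- **Genotypes**: founder haplotypes Bernoulli(p_j) with p_j ~ U(0.05,
  0.95), descendants by gene dropping (one random allele per parent per
  marker, markers independent). There is no linkage, LD or selection —
  sufficient to exercise the linear algebra, not a model of real marker
  data; passing tests therefore say nothing about LD-driven behaviour.
- **Phenotypes**: y = fixed + u + e with u ~ N(0, A ⊗ G0) in pedigree
  mode, or — for accuracy comparisons, where the truth must be linked to
  the markers — u composed of 90% marker-driven variance (additive effects
  on the centred/scaled genotypes) and 10% residual polygenic variance.
- **Dummy genotypes**: the regression-sampling scheme projects centred
  real counts onto related non-genotyped individuals, M̃ = A_{*,2}A₂,₂⁻¹M_c
  (computed columnwise through the Schur complement), restores the column
  mean allele count, truncates to [0, 2], and draws each integer genotype
  as Binomial(2, M̃_ij/2). The mean re-addition makes the binomial
  parameter well defined; a strict mode that truncates the centred
  regression directly (p clamped by the [0,2] clip) is available for
  comparison. Sampled dummy genotypes may be Mendelian-inconsistent by
  construction and are never asserted consistent; the truncated-outlier
  proportion is logged, not asserted.

All randomness flows from one master seed through independent named
streams (pedigree, genotypes, phenotypes, dummy, probes).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| λ | 0.05 | residual polygenic proportion (unitless, (0,1]) |
| γ | 0.95 | marker weight, 1 − λ when C = A₂,₂ |
| D | identity | marker weight matrix (equal weights) |
| C | A₂,₂ | Woodbury add-on; `diagonal_noise` variant available |
| tol | 2.68e−9 | PCG scaled-residual threshold |
| marker scaling | per-marker √(2p_j(1−p_j)) | makes E[diag(MM')/m_m] ≈ 1 under HWE; a global-denominator variant is exposed |
| diag probes | 10 000 | Hutchinson sample count for diag(A₂,₂⁻¹) |

## Problem sizes

Desk-scale verification uses pedigrees of 42–200 animals for algebraic
oracles (where dense inversion is exact and cheap), 20 instances spanning
both m_g < m_m and m_g > m_m for the three-way equivalence, and 10
replicates of a 2 000-animal, 400-genotype, 200-marker, two-trait design
for the accuracy comparison between single-step and pedigree-only
evaluation.

## Known limitations

- Genetic groups, multi-sire parentage, maternal and permanent
  environmental effects, repeated records and sire×herd interactions are
  out of scope; one fixed factor per trait.
- Variance components are inputs, never estimated.
- The gene-dropping generator has no linkage; genomic accuracy gains
  measured here reflect realised-relationship information only.
- Monomorphic markers are dropped (with a warning), missing genotypes are
  mean-imputed unless strict mode is requested.
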