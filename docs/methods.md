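# Methods

## The evaluation model

`ssnpblup` implements a single-trait single-step SNP-BLUP evaluation: a
linear mixed model that jointly predicts breeding values for genotyped and
ungenotyped animals while estimating SNP (marker) effects explicitly,

    y = X beta + W a + e,

where `y` stacks cow phenotype records and bull pseudo-phenotypes (DRPs),
`beta` holds the fixed effects (herd, age-at-calving class, lactation phase
for cow records; one artificial class per bull birth-year cohort for DRP
records, plus a global intercept), and `a` is the vector of breeding
values.  For genotyped animals

    a2 = Z2 g + u2,

with `Z2` the centered 0/1/2 genotype codes (centered by twice the allele
frequency), `g` the random SNP effects and `u` the residual polygenic
effect.  Priors:

    g   ~ N(0, I  (1-k) sigma_a^2 / sum_i 2 p_i q_i)
    u   ~ N(0, A  k sigma_a^2)
    e_j ~ N(0, sigma_e^2 / w_j)

`A` is the pedigree numerator relationship matrix; `k` is the proportion of
additive variance not captured by the markers.  Defaults follow the Polish
national stature evaluation: `sigma_a^2 = 5.50`, `sigma_e^2 = 4.63`,
`k = 0.2`.  Residual weights are `w = 1` for a cow record and `w = EDC`
(effective daughter contribution) for a bull DRP, i.e. a DRP with `n`
daughter equivalents has residual variance `sigma_e^2 / n`.  (The
alternative reading in which a DRP's residual variance *grows* with EDC
would make the most reliable bulls the least informative; the standard
deregression convention is used instead.)

### Non-genotyped animals: the hybrid parameterisation

The marker term of a non-genotyped animal is expressed through imputed
covariates

    T1 = A12 A22^-1 Z2,

(the conditional expectation of its centered genotypes given its genotyped
relatives) plus an explicit imputation residual `eps` with prior

    eps ~ N(0, (A^11)^-1 (1-k) sigma_a^2),

where `A^11` is the non-genotyped block of the animal-only `A^-1` — the
inverse of the Schur complement `A11 - A12 A22^-1 A21`.  The full solution
vector is `x = [beta; g; eps; u; genetic groups]`.  This hybrid form is
algebraically equivalent to single-step GBLUP with
`G = (1-k) Z2 Z2' / sum 2pq + k A22`, which the test suite verifies
numerically on complete-parentage instances (relative EBV difference below
1e-6); the ssGBLUP construction itself is kept as an independent oracle and
never used as the production path.  `T1` is computed by sparse LU solves on
`A^11` via the identity `A12 A22^-1 = -(A^11)^-1 A^12`; a dense
tabular-blocks route exists as a cross-oracle.

### Genetic groups

Unknown parents are replaced by unknown-parent (genetic) groups defined by
the slot's sex, the offspring's country class (PL / USCA / OTHER) and a
10-year window of the offspring's birth year (calendar-decade anchored,
configurable).  The offspring's metadata is used because an unknown
parent's own birth year is, by construction, unknown.  Groups enter through
the grouped `A^-1` (per-animal contribution rules with the group column
substituted for the unknown parent; groups carry no inbreeding and no
Mendelian-variance reduction).  Because every lineage eventually terminates
in unknown parents, a constant shift of all group and animal solutions is
absorbed by the intercept, making the grouped MME singular; the first
instantiated group is therefore constrained to zero (its column dropped),
mirroring the reference-level constraint applied to every fixed factor.
Solved animal effects then already contain the group contribution, so
EBV = T g + S eps + u with the group solutions reported separately.

## Relationship machinery

* Inbreeding: recursive coancestry with memoisation (`F_i` = kinship of the
  parents); exact at desk scale, unknown parents are unrelated non-inbred
  founders.
* `A^-1`: Henderson/Quaas per-animal contribution stencils with
  `1/d_i` weights, `d_i = 1/2 - (F_s + F_d)/4`, an unknown parent
  contributing `F = 0` and an extra founder variance of 1/4.
* The dense tabular (recursive) `A` serves as the oracle: the suite checks
  `dense(A^-1) x A = I` to 1e-8 on random pedigrees, and `F = diag(A) - 1`
  to 1e-10.

## Solver

The mixed model equations are exposed matrix-free: one operator application
costs two sparse design products, two dense products with the n x m marker
covariate matrix `T`, and sparse products with `A^-1` blocks.  The exact
diagonal of `C` is assembled analytically for the first-level Jacobi
preconditioner `M` (floored at 1e-12 of its maximum to guard rounding; a
non-positive diagonal is an error).  The second level is deflation over
effect-type subspaces — one indicator vector per nonempty block (fixed
effects, SNPs, imputation residuals, animals, genetic groups), applied in
the standard projection form of deflated PCG with the small coarse system
`E = W' C W` factored once.  Deflation can be disabled
(`second_level="none"`).

Convergence is tracked by three criteria, computed every iteration:

    CK = (1/mu_1)      ||M^-1 (b - C x_i)|| / ||x_i||
    CM = kappa(M^-1 C) ||M^-1 (b - C x_i)|| / ||M^-1 b||
    CD = ||x_{i-1} - x_i|| / ||x_i||

with Euclidean norms throughout.  `CD <= 1e-9` stops the iteration
(default; configurable), matching routine evaluation practice.  `mu_1` and
`kappa` are estimated online from the Lanczos tridiagonal implied by the CG
scalar recurrences (`alpha`, `beta`): its eigenvalues (Ritz values)
approximate the spectrum of the preconditioned matrix.  The smallest
*active* eigenvalue is the smallest Ritz value whose Ritz residual
(next off-diagonal times the last eigenvector component) is below 1e-2
relative, excluding values below 1e-10 of the largest (numerically zero
modes); before any Ritz pair has converged the smallest value above the
floor is used.  The final reported condition number uses the full scalar
history; the suite checks it against the dense eigenvalue ratio of
`M^-1/2 C M^-1/2` to within 5% on systems run to near-convergence.

Solutions are snapshotted at iterations 1, 1+s, 1+2s, ... (s = 20 by
default) plus the final iteration; per-snapshot statistics report the mean
and sample (n-1) SD of `|x_i - x_F|` per effect category: the four
information groups (G+P+, G-P+, G+P-, G-P-, each split by sex, measured on
reconstructed EBVs), SNP effects, and genetic-group effects.

Numerical notes: execution is serial and deterministic with a fixed
summation order; a non-finite recurrence value or a non-positive curvature
`p'Cp` raises immediately with the iteration number; a zero RHS returns the
zero solution at iteration 0; exact finite termination (residual at the
level of machine precision relative to `b`) also stops the loop.  CD at
iteration 1 is measured against the start vector (zeros by default), and a
zero current iterate yields an undefined-criterion signal (NaN) rather than
an exception.

## Scenario analysis

`run_scenario` executes load -> optional generation truncation -> genetic
groups -> `A^-1` -> MAF filter -> MME -> PCG -> trajectory statistics.
Truncation keeps every animal with phenotype or genotype data (generation
0) plus ancestors within `max_generations` parent steps of any such animal;
parents of retained animals that were dropped are reset to unknown.  MAF
filtering is inclusive (`MAF >= t`) with frequencies computed from the
evaluated genotyped animals.  `compare_scenarios` reports Pearson EBV
correlations per information group and sex over the common animals, the
top-K (default 50) bull ranking overlap with deterministic id tie-breaks,
the Pearson correlation of within-scenario ranks on the common top bulls,
and the ratio of estimated condition numbers with both iteration counts.

## The synthetic population

The generator emulates the information structure of a national dairy
evaluation at desk scale.  Defaults (one choice, documented here, not a
tuning dial): 600 founders plus 8 discrete generations of 275 matings x 2
offspring (5,000 animals), random mating, sexes Bernoulli(1/2), one birth
year per generation starting 1975 (so the 10-year group windows span two
decades), countries PL/USCA/OTHER at 0.8/0.1/0.1, parent links blanked at
15% in the first two generations and 2% later (unknown parents concentrated
early, as in real pedigrees).  2,000 unlinked SNPs with founder frequencies
uniform on [0.01, 0.5]; descendants gene-dropped (each parent transmits
allele A with probability code/2 — exact for unlinked loci).  Genotyping is
confined to the last three cohorts (p = 0.6); females are phenotyped and
males receive DRPs from cohort 6 on (p = 0.6 and 0.35).  Data confined to
late cohorts is what makes 5-generation truncation actually remove deep
dataless ancestors — the situation whose convergence consequences the
analysis layer studies.  EDCs are rounded lognormal(3, 0.8) floored at 1.

True effects mirror the model priors: `g ~ N(0, (1-k) sigma_a^2 / sum2pq)`
with `sum2pq` from the drawn founder frequencies, polygenic values by
pedigree recursion with Mendelian-sampling variance
`k sigma_a^2 (1/2 - (F_s + F_d)/4)`, phenotypes add herd (N(0, 2^2) per
herd), age-class and lactation effects plus `N(0, sigma_e^2)` noise; DRPs
add `N(0, sigma_e^2 / EDC)` noise around `mu + a_true`.

What the generator does *not* emulate: linkage disequilibrium beyond
pedigree transmission, selection (off by default; a truncation-selection
switch exists), genotyping-array error, MACE deregression mechanics, or
repeated lactation records.  Passing tests therefore demonstrate the
correctness of the algebra and the qualitative pedigree-depth effects, not
predictive accuracy on real national data.

## Problem sizes and test design

Tests run oracle comparisons at a few hundred animals (dense factorisations
are exact there) and the scenario contrast on the 5,000-animal default
population with ten replicate seeds; the variance calibration uses 20,000
founders per replicate, averaging over independent SNP-effect draws because
a single draw of m effects leaves the realised marker variance with a
relative sampling SD of about sqrt(2/m).  All randomness flows from
explicit seeds; reruns are byte-identical.

## Known limitations

* The inbreeding recursion and the dense tabular `A` are exact but
  desk-scale (tens of thousands of animals, not millions).
* The deflation space is fixed to effect-type indicators; richer coarse
  spaces (per-generation, per-herd) may deflate more of the low spectrum.
* Genetic-group estimability relies on the first-group constraint; group
  solutions are contrasts against that reference group.
* One record per animal; multi-trait and repeated-records models are out
  of scope.
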