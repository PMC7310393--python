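# Methods

`amaci` implements the estimation machinery behind international
beef-cattle genetic evaluations: measuring genetic connectedness between
national populations, sub-setting a dominant population to its best
connected herds, and estimating across-country genetic correlations with a
multi-trait maternal-effects animal model fitted by Monte Carlo EM REML.
This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic studies do and do not show.

## The model

Each of the `P` national populations is treated as a separate, genetically
correlated trait.  A record from population `i` is modelled as

    y_i = X_i b_i + C_i r_i + Z_i u_i + W_i m_i + P_i pe_i + e_i

with fixed national effects `b_i` (always including an intercept;
contemporary group by default), an optional extra national random
environmental effect `r_i` (e.g. herd-year), the animal's direct additive
genetic effect `u_i`, the dam's maternal additive genetic effect `m_i`, the
dam's permanent environmental effect `pe_i` (omitted for populations whose
national model does not fit it), and a residual.  The stacked genetic
vector `(u_1..u_P, m_1..m_P)` has covariance `G0 ⊗ A`, where `G0` is the
`2P x 2P` genetic covariance matrix and `A` the numerator relationship
matrix over the joint pedigree; `pe`, `r` and `e` are independent within
population with across-population covariances structurally zero (an animal
is recorded in exactly one population, and too few dams have offspring in
two countries for `pe` covariances to be estimable).  Across-country
genetic correlations are `r_g[k,l] = G0[k,l] / sqrt(G0[k,k] G0[l,l])`.

The mixed-model equations are assembled with each record weighted by the
inverse of its population's residual variance, `A^-1` built sparsely from
per-animal Mendelian-sampling contributions (inbreeding-adjusted by
default), and the genetic prior added as `A^-1 ⊗ G0^-1`.  Equations are
ordered fixed effects, extra random, permanent environment, then genetic
effects animal-major, so the `2P`-wide within-animal blocks are contiguous.

Rank deficiency of the fixed effects is removed by a reference-level
constraint (first level of every categorical factor dropped); solutions are
then unique and comparable across solvers.

## Connectedness coefficients

Connections between populations come from common bulls (CB, sires with
phenotyped offspring in two or more populations) and common maternal
grand-sires (CMGS).  "Offspring" always means a phenotyped record in the
edited dataset, and the population of an offspring is the population of its
record.  The package computes:

* `GS_ab`: genetic similarity — the proportion of the combined offspring of
  populations `a` and `b` sired by common bulls; herd-level variants
  compare one herd with a foreign population, from CB alone (`GS_CB`) or
  averaged with the CMGS version (`GS_TOT`).
* `BOD_i = 1 - Σ_j |n_ij - n̄_i| / (2 Σ_j n_ij)`: evenness of sire `i`'s
  offspring over all `N_P` populations (zeros included), and
  `AN_POP_i = N_P · BOD_i`, the equivalent number of evenly covered
  populations.
* `HM_i = 2 / (1/N_1 + 1/N_2)`: harmonic mean of a sire's progeny sizes in
  two units; summed over a herd's common bulls and all foreign populations
  it gives the herd score `HM_h`.

Herd-level averages over populations ignore pairs with an undefined
denominator rather than treating them as zero, and a herd is never
compared against its own population.

## Data edits and herd sub-setting

National edits run in a fixed order: (1) records in contemporary groups
below the population's minimum size, (2) embryo-transfer-flagged records,
(3) records beyond three phenotypic standard deviations of their
population-by-sex mean, the moments computed once on the survivors of
(1)-(2).  Cells with fewer than three records skip the outlier filter (no
meaningful dispersion estimate), contemporary-group sizes are not
re-checked after outlier removal, and re-applying the edits to an edited
table is a no-op.

Sub-setting applies to one dominant population only; all other populations
are kept whole.  Herds are ranked by mean herd-level `GS_CB`, `GS_TOT`, or
`HM_h`, and selected in rank order until the cumulative record count first
reaches the target (overshooting by at most the last herd); a top-fraction
mode replaces the record target when configured.  Ties break by record
count then herd id; herds with no computable score rank last and are
flagged as disconnected.  The random strategy partitions herds uniformly
into a configured number of subsets and ranks the subsets by their mean
genetic similarity with the other populations.

## Monte Carlo EM REML

Each REML round solves the mixed-model equations twice: once for the real
data and once (or `n_sim_per_round` times) for data simulated under the
current parameters with fixed effects set to zero — BLUP of random effects
is invariant to the true fixed-effect values, which the test suite checks.
The update for the genetic block is

    G0[k,l] <- [ û_k' A^-1 û_l + mean_s( u*_k' A^-1 u*_l - û*_k' A^-1 û*_l ) ] / q

with `q` the pedigree size: the real-data sum of squares plus a Monte Carlo
estimate of the prediction-error trace that exact EM would compute
analytically.  Scalar components update analogously with level counts
(permanent environment, extra random) or record counts (residuals).  The
expectation of this update equals the exact EM update — verified against a
dense implementation that evaluates the traces through the explicit inverse
of the mixed-model coefficient matrix — and the exact EM iteration is
confirmed likelihood-ascending against a dense restricted-likelihood
evaluator.

Convergence is declared when the least-squares slope of every component
over the last `slope_window` rounds, standardized by the component's window
mean, falls below `vce_slope_tol` (default 1e-9).  Slopes are standardized
so a 1e-9 criterion means the same thing for a 300 kg^2 residual variance
and a 20 kg^2 covariance; window length and tolerance are configurable and
logged.

Intermediate genetic matrices that drift off the positive-definite cone are
projected back by eigenvalue clipping at 1e-8 of the largest eigenvalue.
This is a numerical guard inside the iteration only; the reported final
matrix is never bent, and its positive definiteness is checked and
reported.

### Monte Carlo noise at desk scale

The defaults (one simulated dataset per round, slope criterion 1e-9) come
from million-record evaluations, where the relative Monte Carlo error of a
single simulated replicate is small.  At 10^3-10^4 records the same
settings turn the iteration into a visible random walk along weakly
informed directions — across-country correlations can swing by ±0.2 over
hundreds of rounds.  The desk-scale studies in this package therefore use
several simulated datasets per round and report the element-wise mean of
the last `average_last` rounds (iterate averaging); both knobs are plain
`REMLSettings` fields and default to the million-record conventions.

EM travel along weakly informed directions is slow (about 3e-4 correlation
units per round in the synthetic studies), consistent with the thousands of
rounds such evaluations are known to need.  The recovery study therefore
starts, as an established evaluation would, from routine-estimate-like
values: the true parameters perturbed by a realistic estimate drift
(variances about 7% low, correlations 0.05 low, residuals 10% high).

## Standard errors

Sampling (co)variances of the estimates are approximated in one extra
round with `se_n_sim` simulated datasets (500 by default, PCG iterations
unlimited).  For each simulated dataset the observed-data REML score equals
the conditional expectation of the complete-data score given that dataset,
which is the complete-data score evaluated at the replicate's BLUP
sufficient statistics plus a constant that is the same for every replicate.
The Fisher information is the sampling variance of the observed-data score,
so the empirical covariance of the per-replicate score vectors — in which
the constant cancels — estimates the information matrix directly; its
inverse is the sampling covariance of the variance components, and
correlation standard errors follow by the delta method on
`r = σ_kl / sqrt(σ_kk σ_ll)`.

A subtraction-based alternative (complete-data information minus the
conditional variance of the score, Louis' identity) is exact on paper but
numerically hopeless here: for the genetic block the observed information
is a ~1e-4 relative residue of two nearly equal matrices, far below the
resolution of a few hundred Monte Carlo replicates.  The covariance-of-
scores form has no such cancellation; against an analytic dense Fisher
information it agrees to within ~8% at 500 replicates on a 14-parameter
instance.

The validation oracle for these standard errors is a finite-difference
Hessian of the dense restricted log-likelihood.  A single dataset's
observed Hessian fluctuates around the expected information that the
standard errors estimate, so the oracle averages the Hessians of 96
independent datasets simulated at the same parameters.

## Synthetic data generator

The generator emulates the structure such evaluations see: several
national populations of very unequal size (the 8-population preset uses
record shares 87.1 / 4.1 / 2.9 / 2.8 / 1.1 / 1.0 / 0.7 / 0.3 percent, with
per-population mean herd sizes matching the same source and the
DEU-analogue fitting no permanent environmental effect), persistent herds
with log-normal size skew, year-based contemporary groups, overlapping
generations (dams produce for `dam_lifespan` generations; shortfalls are
covered by immigrant founder dams), and an international sire pool used
with probability `international_sire_fraction` — the single knob that
controls common-bull counts and genetic similarity, which the tests verify
increases monotonically with it.  Trait values are drawn from exactly the
analysis model: genetic effects by pedigree recursion (parent average plus
Mendelian sampling with the `2P`-wide within-animal covariance factorized
once, sampling variances inbreeding-adjusted), population mean and
contemporary-group effects added as fixed quantities.

Default true parameters are realistic for age-adjusted weaning weight:
direct variance 120 kg^2, maternal 60, direct-maternal covariance
corresponding to r = -0.2, permanent environment 40, residual 280,
population means about 250 kg, contemporary-group SD 25 kg.  The recovery
study uses a deliberately well-connected variant (direct 150, maternal 80,
residual 150, nearly all sires drawn from the shared pool) because the
question there is estimator behaviour, not typical field connectedness.

What the generator does **not** emulate: selection response across
generations, national pre-adjustment differences in trait definition,
heterogeneous residuals within population-by-sex, culling, or real
herd-management correlations.  Passing tests on this data show the
estimation machinery is correct and calibrated for the assumed model; they
do not show robustness to model misspecification.

## Validation study sizes

The self-validation studies (`amaci.validation`, driven by
`scripts/acceptance.py` and the acceptance tests) use these problem sizes,
chosen so every study runs comfortably on a single core:

* relationship-inverse oracle: 50 random pedigrees of 20-200 animals;
* solver oracle: assembled systems of up to 473 equations against dense
  direct solves;
* EM oracle: a two-population instance of 100 records / ~190 pedigree
  animals, 500 Monte Carlo replicates against the exact dense update;
* standard-error oracle: a two-population instance of 500 records,
  500-replicate Monte Carlo standard errors against the mean of 96
  finite-difference Hessians;
* recovery study: ten replicates of three populations with 2,292 phenotyped
  animals (~2,460 in the pedigree), 120 MC EM REML rounds with two
  simulated datasets per round, the last 60 rounds averaged, and
  100-replicate standard errors.

## Known limitations

* **Information content of small recovery studies.**  At the ~2,300-record
  scale of the synthetic recovery study, the Fisher information — measured
  with the package's own standard-error machinery, itself validated
  against a dense analytic oracle — puts the sampling SE of an individual
  across-country correlation at about 0.2 (direct) to 0.5-0.7 (maternal),
  even with implausibly favorable connectedness.  For calibration, the
  published full-scale analysis reports average SEs of 0.14 (direct) and
  0.19 (maternal) with 3.1 million records.  Point estimates at desk scale
  therefore scatter well beyond ±0.15 around the truth; the meaningful
  checks at this scale are approximate unbiasedness of the block means,
  coverage of the reported standard errors, and positive definiteness of
  the reported matrices, all of which the validation study reports.
* The slope convergence criterion at its 1e-9 default effectively never
  triggers at desk scale (Monte Carlo noise dominates); runs stop at
  `max_rounds`, which the study sizes here choose explicitly.
* Unknown-parent groups (genetic groups) are not implemented; unknown
  parents are treated as base-population founders.
* Heritabilities on the diagonal of exported correlation tables are
  whatever the configured formula produces; no single phenotypic-variance
  composition is canonical across national models, so none is hard-coded.
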