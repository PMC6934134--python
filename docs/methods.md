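# Methods

This note documents the models, algorithms, numerical choices and
limitations of `ssblend` at the level a maintainer or reviewer needs.

## Pedigree relationships

The numerator relationship matrix `A` is built by the tabular recursion
(parents before offspring; `A_ii = 1 + A_sd/2`, `A_ij = (A_sj + A_dj)/2`).
Inbreeding coefficients `F = diag(A) − 1` are computed either from that
recursion (default up to 5,000 animals) or by a recursive
Meuwissen–Luo-style traversal that generates each animal's row of the
`L·D·L′` factor over its ancestors only, keeping memory linear; both
methods agree to machine precision and are cross-tested. `A⁻¹` is
assembled directly by Henderson's rules with inbreeding-adjusted
Mendelian-sampling variances (`d_i = 0.5 − 0.25(F_s + F_d)` with both
parents known, `0.75 − 0.25 F_p` with one, `1` for founders), giving at
most nine contributions per animal and a sparse symmetric matrix.

Unknown parents are treated as unrelated base animals (no unknown-parent
groups or metafounders — out of scope). Pedigrees are pruned to
phenotyped/genotyped animals and their ancestors before analysis; rows
are re-ordered canonically by (generation depth, ID) so results do not
depend on input row order. `A₂₂`, the block for genotyped animals, is
computed from the full pruned pedigree via the same tabular recursion
restricted to the subset's ancestry.

## Genomic relationships

Genotypes are additive codes 0/1/2 (copies of the second allele).
QC proceeds in a fixed order — non-autosomal markers, per-marker call
rate (< 90%), minor allele frequency (< 5%), Hardy–Weinberg deviation
(1-df chi-square goodness of fit, p < 1e-8), then per-animal call rate
(< 90%) — with per-stage counts reported. A chi-square test rather than
an exact test is standard at sample sizes in the thousands; at the 1e-8
threshold the distinction is immaterial except at tiny n.

`G = (M−P)(M−P)′ / 2Σ pⱼqⱼ` with columns centered by `2pⱼ`. Although the
codes are 0/1/2, centering by `2pⱼ` is algebraically equivalent to the
`{−1,0,1}` coding with the `2(p−0.5)` shift; with observed frequencies
`G`'s rows sum to zero. Three frequency schemes exist: all 0.5,
observed, and a beta-rescaled variant whose denominator uses
method-of-moments beta parameters
(`α̂ = x̄(x̄(1−x̄)/v̄ − 1)`, `β̂ = (1−x̄)(x̄(1−x̄)/v̄ − 1)`). The published
formulation of the rescaled denominator is typographically ambiguous; the
implementation in `scaled_g_denominator` uses the reading
`m·[(p₀−q₀)² + 2(Σpⱼqⱼ/m)(α̂+β̂+2)/(α̂+β̂)]`, flags it as an
interpretation, and keeps the scheme out of every default and headline
result. Residual missing genotypes are mean-imputed (`2pⱼ`).

`Gw = wG + (1−w)A₂₂` (default `w = 0.90`, scheme observed) is inverted by
Cholesky; failure raises rather than silently regularizing, and no
diagonal stabilizer is added by default (a config switch exists). The
single-step `H⁻¹` augments `A⁻¹`'s genotyped block with `Gw⁻¹ − A₂₂⁻¹`;
with an empty genotyped set it equals `A⁻¹` exactly, and with every
pedigree animal genotyped the solutions coincide with GBLUP under kernel
`Gw` (both identities are tested).

## Derived traits

FCR is total feed intake over weight gain (missing when gain is not
positive). RFI is the residual of an OLS regression of intake on
metabolic mid-weight, gain and categorical hatch week, fitted within the
analyzed data, so it has mean zero by construction. Metabolic mid-weight
is mid-test body weight to the power 0.75 — the conventional metabolic
scaling; the exponent is config-exposed. BMY is breast weight as a
percentage of live slaughter weight. Walking score passes through as a
1–6 integer and is analyzed linearly.

## Mixed model and REML

Records are stacked animal-major with per-animal observed-trait patterns;
the residual covariance for an animal is `R0` restricted to its observed
traits, with pattern-level inverses cached. Equations are ordered fixed
effects first, then breeding values trait-major, so the genetic prior
inverse is the Kronecker product `G0⁻¹ ⊗ K⁻¹`. BLUP solves Henderson's
equations by sparse LU (default up to 20,000 equations) or
Jacobi-preconditioned conjugate gradients; the two agree to 1e-6
relative and this is tested.

REML uses EM updates

```
G0 ← (Û′K⁻¹Û + [tr(K⁻¹ C^{uu}_{rs})]) / q
R0 ← Σ_i E[e_i e_i′ | y] / n
```

with the conditional expectation for unobserved traits filled in through
the current `R0` (the standard data-augmentation EM for missing traits),
accelerated by average-information (AI) Newton steps. The score is
evaluated in matrix form from the same EM quantities; the AI matrix is
`½ F′PF` with one MME solve per parameter. Steps that would leave the
positive-definite cone are halved up to 30 times and fall back to the EM
update; variances collapsing below `1e-8 ×` the phenotypic scale are
clamped and flagged. Convergence is declared when the largest parameter
change relative to the phenotypic scale drops below the tolerance
(default 1e-8, cap 500 iterations). Approximate standard errors come from
the inverse AI matrix at the final estimates; they are approximations,
not a reproduction target.

Traces are computed exactly from a dense inverse of the coefficient
matrix (LAPACK `dpotrf`/`dpotri`), which is the honest choice at the
package's target scale of a few thousand animals; no stochastic trace
estimation is used. For multi-trait models whose traits share identical
incidence matrices and complete records — e.g. the two feed traits
recorded on the same males — an exact canonical-decomposition fast path
applies: the generalized eigendecomposition `G0 Φ = R0 Φ Λ`
(`Φ′R0Φ = I`) block-diagonalizes the coefficient matrix into `t`
single-trait-sized systems, and the full inverse is reassembled from
their inverses. The fast path is verified against the general path to
machine precision and cuts the bivariate REML cost about four-fold.

## Forward validation

The full pedigree model is fitted to all data, adjusted phenotypes are
`y − x′b̂` with the full-model fixed-effect solutions, and whole youngest
hatch cohorts are held out until at least the target share (default 10%)
of phenotyped animals is reached — whole cohorts so that no
contemporary-group information leaks from validation records into the
reduced fits (a sentinel test plants absurd validation values and asserts
the reduced solutions are unchanged). Every model in the comparison grid
is re-fitted on the masked data with the same split. Accuracy is the raw
Pearson correlation (no division by √h²); bias is the OLS slope of
adjusted phenotype on prediction with its standard OLS standard error.
Variance components are estimated once per kinship type on the full data
and reused across reduced runs.

## Synthetic populations

The generator produces discrete generations: founders (default 25 sires,
100 dams), random re-selection of parents each generation (an optional
truncation switch selects the highest true breeding values, with exact
incremental inbreeding, in pedigree mode only), a configurable number of
offspring per dam, and hatch-week cohorts (3 per generation-year by
default). Default scale is roughly 5,000 phenotyped birds over 10
generations — a desk scale, not the hundreds of thousands of records of a
production program.

True breeding values come in two modes. Pedigree mode draws founders
`N(0, R)` and descendants as parent average plus Mendelian sampling
scaled by `0.5 − 0.25(F_s + F_d)`, so `cov(vec U) = A ⊗ R` exactly.
Marker mode gene-drops founder haplotypes (per-marker frequencies from a
uniform 0.1–0.9 law by default) through the pedigree and sums centered
codes times i.i.d. multivariate normal marker effects scaled so the
founder breeding-value covariance is `R`; this gives the genomic
relationships real signal and is used for single-step recovery and
accuracy-ordering studies. Phenotypes add the trait mean, i.i.d. normal
hatch-cohort effects (SD 25% of the phenotypic SD), a sex effect for body
weight and walking score, and residuals with the configured residual
covariance; feed traits and breast meat yield are recorded on males only,
and walking score is a rounded, clipped latent Gaussian (simulated as a
threshold trait but analyzed linearly, matching how 1–6 scores are
handled in practice).

Default trait laws: means/SDs 2.58/0.39 (FCR, kg/kg), 0/2.51 (RFI, kg),
17.50/5.32 (BW, kg), 24.37/2.33 (BMY, %), 2.10/0.86 (WS); heritabilities
0.14, 0.12, 0.35, 0.27, 0.24; the genetic correlation matrix includes
FCR–RFI 0.68, BW–WS −0.47 and BMY–WS −0.35. The genotyping policy is
config-exposed (share per generation, optionally restricted to one sex)
rather than reverse-engineered from any particular data set. What the
generator does **not** emulate: linkage disequilibrium and realistic
haplotype structure (markers segregate independently), genotyping errors,
selection pressure by default, overlapping generations, or the real
data's record counts. Passing recovery tests therefore demonstrate that
the estimation machinery is correct under the assumed model, not that
real turkey data would yield these parameters.

## Recovery studies and problem sizes

The studies in `ssblend.studies` fix the following desk scales, chosen
once: single-trait pedigree heritability recovery uses ~4,000 phenotyped
animals of the recorded sex over 10 generations (male-only traits simulate
~8,000 birds so the male half reaches the target); the single-step study
uses ~3,000 phenotyped males with half genotyped at 2,000 markers and
`w = 0.90`; the bivariate feed-trait study uses ~4,000 males carrying
both traits. Reported values are means over a small number of seeded
replicates (2 for heritabilities, 3 for the genetic correlation) because
single-replicate REML estimates at these n have Monte-Carlo standard
deviations of roughly 0.03 (h²) and 0.08 (genetic correlation); the
replicate mean is the study's estimator, fixed in advance and identical
in the test suite and the acceptance script. Replicate seeds derive from
the user seed through `numpy` `SeedSequence` with a per-study tag.

## Known limitations

* Dense-inverse REML traces bound practical problem size to roughly ten
  thousand equations; production-scale data would need sparse-inverse
  (Takahashi) or Monte-Carlo trace machinery.
* The walking score is generated as an ordinal threshold trait but both
  generation targets and analysis treat it linearly; its recovered
  heritability is attenuated relative to the latent scale and is not used
  as a recovery target.
* Marker-mode genetic variance is referenced to the founder allele
  frequencies; with observed-frequency `G` in `H`, base-population
  definitions differ slightly, a known property of single-step models
  without explicit base alignment (tuning `G` to `A₂₂` beyond blending is
  out of scope).
* No genetic groups, dominance, maternal effects, or random effects
  beyond the additive animal effect.
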