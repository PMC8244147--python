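# Methods

This document defines the statistical model behind `gpacc`, the estimators
it implements, and the numerical and design choices made in the
implementation.

## 1. Populations, EBV kinds and accuracies

A *reference* population consists of genotyped and phenotyped individuals;
the *target* population consists of selection candidates (typically
genotyped but not yet phenotyped) whose GEBV accuracy is to be predicted.
Throughout, *accuracy* means population accuracy: the correlation between
EBV and true breeding values across a population, which is the quantity
relevant for response to selection.

Three kinds of EBV are distinguished:

* **PEBV** (`g_A`, accuracy `r_A`) from pedigree relationships `A`;
* **DEBV** (`g_D`, accuracy `r_D`) from genomic-minus-pedigree
  relationships `G − A`;
* **GEBV** (`g_G`, accuracy `r_G`) from genomic relationships `G`.

The central modelling assumption is that the sampling errors of `g_A` and
`g_D` are independent, because pedigree relationships are independent of
the deviations of genomic from pedigree relationships. GEBV accuracy then
follows from the other two by either of two equivalent systems.

### Fisher-information route

Each EBV carries an information statistic about the true breeding value,

    theta_i = r_i^2 (1 - r_i^2 q_i^2 h^2) / (q_i^2 - r_i^2),

where `q_i^2` is the proportion of genetic variance the information source
can capture and `h^2` the heritability of the training phenotypes.
Information adds over independent sources, `theta_G = theta_A + theta_D`.
The inverse mapping is the smaller root of the implied quadratic,

    r_i^2 = [ (1 + theta) - sqrt((1 + theta)^2 - 4 h^2 (q_i^2)^2 theta) ]
            / (2 q_i^2 h^2).

PEBV and GEBV carry whole-genome pedigree information, so `q_A^2 = q_G^2 =
1`; for DEBV, `q_D^2 = M / (M + Me)` is the fraction of genetic variance
captured by `M` markers.

### Selection-index route

Combining PEBV and DEBV with optimal index weights gives

    r_G^2 = (r_A^2 + r_D^2 - 2 r_A^2 r_D^2) / (1 - r_A^2 r_D^2),

with exact inverse

    r_D^2 = (r_G^2 - r_A^2) / (1 + r_A^2 (r_G^2 - 2)).

Sampling noise can produce `r_G < r_A`; the extraction then clamps `r_D^2`
to 0 with a warning (or raises, under `policy="strict"`).

## 2. The effective number of chromosome segments

`Me` is the number of independent genomic effects effectively estimated
from the reference data. It is treated as an inherent parameter of the
population (like effective population size `Ne`) rather than of a
particular trait or dataset. The reference-population DEBV information is

    theta_D = N q_D^2 h^2 / Me,      q_D^2 = M / (M + Me).

Four estimators are implemented:

1. **Fisher route** (`me_fisher`): convert observed reference (`r_A`,
   `r_G`) to information at `q^2 = 1`, extract `theta_D = theta_G -
   theta_A`, and solve the quadratic
   `theta_D Me^2 + theta_D M Me - N M h^2 = 0` for its positive root.
2. **Index route** (`me_index`): extract `r_D^2` with the index inverse and
   solve the coupled system `Me = N q_D^2 h^2 / theta_D(r_D^2, q_D^2, h^2)`
   with `q_D^2 = M/(M+Me)`. The undamped fixed-point iteration oscillates,
   so successive averaging (`Me ← (Me + step(Me))/2`) is used, with a
   bracketed Brent solve on `(0, M (1 - r_D^2)/r_D^2)` as fallback; the
   upper bound is where `q_D^2` falls to `r_D^2` and information diverges.
3. **Theoretical** (`me_theoretical`): `2 Ne L k`, or `2 Ne L k / ln(Ne L)`
   with the log correction. Provided for comparison; both are known to be
   poor in structured populations.
4. **Relationship variance** (`me_from_relationship_variance`): the
   reciprocal of the variance of the off-diagonal elements of `G − A` over
   the reference individuals. Known to undershoot badly under hierarchical
   family structures; implemented because it is a common benchmark.

Because `Me` is fitted from the same averaged accuracies it re-predicts,
predicted reference `r_G` equals the observed value exactly, for both
routes; this is a structural identity and is enforced by test.

## 3. Erosion of genomic information toward the target

Genomic information decays with meiotic distance from the reference. The
genome of `k` chromosomes of `L` Morgan is viewed as `Me` independent
segments of average size `gamma k L / Me` Morgan. The probability that a
target individual inherited both haplotypes of an average segment
unrecombined from its closest reference ancestors, `l_p` generations back
on the paternal and `l_m` on the maternal path, is

    p_rt = (1 - gamma k L / Me)^(l_p + l_m),

and DEBV **accuracy** (not squared accuracy) is retained proportionally:

    r_Dt = p_rt * r_Dr.

`gamma` inflates the average segment size because co-segregation
information (within-family linkage) erodes faster than population-level
linkage-disequilibrium information; `gamma = 2` is the default, and
`calibrate_gamma` refits it from observed target accuracies by bounded
least squares on `(0, Me/(kL))`.

For candidates that are progeny of reference animals, `l_p = l_m = 1`, so
the exponent grows by 2 per generation: the per-generation retention of
DEBV accuracy is `(1 - gamma k L / Me)^2`.

Target GEBV accuracy is obtained by combining `r_Dt` with the target
pedigree accuracy `r_At` (supplied by the user, from pseudo-BLUP software,
or measured in simulation) by either route. Under selection, accuracies in
the selected population can be mapped from unselected-population values via
`r^2 = 1 - (1 - r'^2) sigma'^2_G / sigma^2_G` (`selection_adjusted_r2`).

## 4. The decline regression on cross-validation data

With successive validation generations at gaps 1..T from a fixed reference,
`r_D` per gap is extracted with the index inverse, and ordinary least
squares of `ln(r_D)` on gap yields slope `b` and intercept `a`:

* the slope route solves `(1 - gamma k L / Me)^2 = e^b` for
  `Me = gamma k L / (1 - e^{b/2})`;
* the intercept route runs the Index-route `Me` solver on
  `r_Dr = e^a`, the DEBV accuracy extrapolated to gap 0.

Agreement of the two estimates validates both the `Me` estimator and the
erosion model. On the published layer-chicken regression (slope −0.0327,
intercept −1.2855, `h^2 = 0.523`, `N = 777`, `M = 23,356`, `kL = 30`) the
routes give 3,699.8 and 3,730.0 segments respectively. Gaps where genomic
accuracy does not exceed pedigree accuracy carry no genomic signal and are
dropped with a warning.

## 5. BLUP engine and empirical accuracies

`solve_blup` fits the single-trait animal model with the overall mean as
the only fixed effect, without forming `K^-1`: with phenotyped set `o`,

    V = K[o,o] + lambda I,  lambda = (1 - h^2)/h^2,
    mu = (1' V^-1 y) / (1' V^-1 1),
    g  = K[:,o] V^-1 (y - mu),

which equals the mixed-model-equations solution and extends EBV to
unphenotyped individuals through their relationships (verified against an
explicit-MME oracle).

`loo_ebv` computes exact leave-one-out EBV from one factorization: writing
`W = V^-1`, `u = W y`, `v = W 1`, `w = diag(W)`,

    K[i,-i] V[-i,-i]^-1 y[-i] = y_i - u_i / w_ii,
    K[i,-i] V[-i,-i]^-1 1     = 1  - v_i / w_ii,

and the GLS mean of the reduced data follows from rank-one downdates of
`1'W1` and `1'Wy`, so each LOO EBV costs O(1) after the O(n^3) factor. The
result is identical (to machine precision) to n refits that each
re-estimate the mean. LOO accuracy is `cor(g_loo, y)/sqrt(h^2)`; estimates
above 1 are capped with a warning by default. `add_own_phenotype` indexes
the LOO EBV with the individual's own record,

    r^2 = (r_loo^2 + h^2 - 2 h^2 r_loo^2) / (1 - h^2 r_loo^2),

with weights `b_loo = (1-h^2)/(1-h^2 r_loo^2)` and `b_y = h^2 (1 -
r_loo^2)/(1-h^2 r_loo^2)`; the weights are verified optimal by grid search.
`lr_accuracy` implements the part-whole relation `r_G = r_A / cor(g_A,
g_G)`.

`decompose_gebv` splits a GEBV vector into a pedigree-trackable part
`g_A* = A G^-1 g_G` and the deviation `g_D = g_G - g_A*`.

## 6. Relationship matrices

`build_A` uses the tabular method (`A_ij = (A_{s_i,j} + A_{d_i,j})/2`,
diagonal `1 + F`); pedigrees are validated (unique positive ids, parents
before offspring). `build_G` implements the two standard constructions from
0/1/2 dosages: cross-products of centered dosages scaled by the summed
heterozygosity, or the average of per-locus scaled cross-products over
polymorphic loci. Allele frequencies default to observed; base-population
frequencies may be supplied.

## 7. Simulator

The validation data generator is a forward-in-time simulator:

* **Historical phase**: `ne` diploids (half sires, half dams) random-mate
  for many generations from Bernoulli(0.5) haplotypes, building up
  drift–recombination linkage disequilibrium and a U-shaped frequency
  spectrum. Meiosis draws Poisson(`L`) crossovers per chromosome without
  interference, a random start phase per chromosome, and recurrent
  mutation at 1e-8 per locus.
* **Locus assignment**: loci with minor allele frequency above 0.1 are
  split into QTL (equal numbers per chromosome, independent standard-normal
  effects) and a marker panel (optionally thinned to a target count).
* **Breeding phase**: generation 0 is bred from the founder pool and forms
  the pedigree base. Each later generation mates `n_sires` sires to
  `n_dams` dams (nested hierarchically, reassigned each generation),
  selected from the previous generation at random or on GBLUP GEBV
  computed from all earlier phenotyped generations — i.e. before the
  candidates' own phenotypes exist. True breeding values are QTL-dosage
  sums scaled to mean 0, SD 1 in generation 0; phenotypes add
  N(0, (1-h^2)/h^2) noise so generation 0 has heritability `h^2` on that
  scale.

Everything is driven by one seeded generator per run; replicate seeds are
derived as `base_seed + replicate`. Under random selection, phenotypes can
be redrawn at a different heritability on the same genomes
(`SimDataset.with_phenotypes`), which keeps heritability comparisons on
matched genetic material; this is refused after GEBV selection because the
phenotypes then shaped the realized matings.

## 8. Validation experiments

Two replicated designs tie the chain together (`gpacc.workflows`):

* **Accumulating reference**: generations 0..t−1 train, generation t is the
  target, for t = 1..T — the ongoing-breeding-program setting; the
  generation distance stays (1, 1).
* **Single-generation reference**: each listed generation trains alone for
  a fixed target generation, varying the gap and hence the erosion.

Empirical reference accuracies are computed within-sample, centered within
generation so genetic trend does not inflate them; target individuals are
excluded from training. Following the validation convention, accuracies are
averaged over replicates first and the averages are then transformed into
`Me` estimates and predictions.

The shipped study uses a deliberately desk-sized design — 9 chromosomes ×
1.5 Morgan with 4,000 simulated loci, a 200-generation historical phase at
`Ne = 200`, ~2,000 markers, 270 QTL, 480 individuals per generation
(10 sires × 48 dams × 10 progeny) and six breeding generations, 10
replicates at heritabilities 0.4 and 0.2 — chosen so the full validation
ladder runs in minutes on a single CPU while preserving the qualitative
behaviour of interest: prediction error of target accuracy within 0.03,
near-identity of the Fisher and Index route predictions, the markedly
greater stability of Index-route `Me` across heritabilities, and the
undershoot of the relationship-variance estimator.

## 9. Numerical and design choices

* `r2_from_theta` clips a (provably non-negative) discriminant at 0 to
  absorb rounding noise; combined accuracies are clipped into [0, 1].
* The damped `Me` fixed point uses relative tolerance 1e-8 with at most 500
  iterations before the bracketed fallback.
* `p_rt` returns 0 with a warning when `gamma k L >= Me` (the inflated
  segment covers the whole map and certainly recombines), and 1 at distance
  0.
* BLUP uses a Cholesky factorization of `V`; non-positive-definite inputs
  raise rather than being silently regularized (a ridge is available where
  a near-singular `G` is legitimate, in `decompose_gebv`).
* Accuracy estimates above 1 (possible through sampling noise and the
  `1/sqrt(h^2)` rescaling) are capped with a warning by default; strict
  policies raise instead.

## 10. Known limitations

* The independence of PEBV and DEBV sampling errors is an approximation;
  its residual effect is absorbed into the empirical fit of `Me`.
* The erosion model treats all segments as equal-sized and independent;
  `gamma` is a calibration constant, not a derived quantity.
* The simulator is deliberately minimal: biallelic loci, no interference,
  no dominance or epistasis, discrete generations, equal litter sizes.
* The selection-variance adjustment assumes the infinitesimal model.
* `Me` estimates from a single reference dataset inherit its sampling
  noise; averaging accuracies over replicates (or traits) first is the
  supported workflow.
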