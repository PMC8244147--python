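# gpacc — predicting the accuracy of genomic breeding values

`gpacc` predicts how accurate genomic estimated breeding values (GEBV) will
be for selection candidates in a closed breeding population, before those
candidates are phenotyped. It implements a deterministic prediction chain
built on one central population parameter — the effective number of
chromosome segments, `Me` — and ships a forward-in-time breeding-program
simulator used to validate the chain end to end.

## The model in one paragraph

The accuracy of GEBV (`r_G`) is split into two sources with independent
sampling errors: pedigree information (PEBV accuracy, `r_A`) and genomic
relationships deviated from pedigree (DEBV accuracy, `r_D`). Two equivalent
bookkeeping systems connect the three accuracies — a Fisher-information
route, in which information statistics add, and a selection-index route.
Observed (`r_A`, `r_G`) in a genotyped-and-phenotyped reference population
yield an estimate of `Me`; `Me` in turn sets the rate at which genomic
information erodes toward younger animals: the DEBV accuracy of a target
individual `l_p + l_m` meioses away from its closest reference ancestors is
`r_Dt = r_Dr * (1 - gamma*k*L/Me)^(l_p+l_m)`, with `k` chromosomes of length
`L` Morgan and an inflation factor `gamma` (default 2, calibrated against
simulation). Recombining `r_Dt` with the target's pedigree accuracy gives
the predicted GEBV accuracy of the candidates.

## Worked example

A multi-generation layer-chicken reference population of `N = 777` birds
genotyped for `M = 23,356` SNPs on a ~30 Morgan map (average trait
heritability 0.523) shows a log-linear decline of cross-validation DEBV
accuracy over validation generations with slope −0.0327 and intercept
−1.2855. Both decline-based routes to `Me` agree:

```bash
$ gpacc decline --slope -0.0327 --intercept -1.2855 \
      --h2 0.523 --n 777 --m 23356 --kl 30 --json
{
  "slope": -0.0327,
  "intercept": -1.2855,
  "r_Dr": 0.2765,              # DEBV accuracy extrapolated to gap 0
  "per_gen_factor_D": 0.9678,  # e^slope: DEBV accuracy retained per generation
  "me_from_slope": 3699.8,     # (1 - 2*30/Me)^2 = e^slope
  "me_from_intercept": 3730.0, # fixed point of Me = N*q2*h2/theta_D
  "q2": 0.8623
}
```

With `Me` in hand, predict the GEBV accuracy of next-generation candidates
(one generation on each parental path, pedigree accuracy 0.543):

```bash
$ gpacc predict --r-d-ref 0.277 --r-a-target 0.543 --h2 0.523 \
      --n 777 --m 23356 --me 3705 --k 9 -L 3.3333 --lp 1 --lm 1 --json
{
  "p_rt": 0.9679,
  "r_Dt": 0.2681,
  "r_Gt": 0.5856,
  ...
}
```

The same chain is available as library calls
(`gpacc.decline_from_coefficients`, `gpacc.predict_target_accuracy`,
`gpacc.me_index`, `gpacc.me_fisher`, …).

## What is in the package

| Module | Contents |
| --- | --- |
| `gpacc.accuracy_core` | accuracy/information conversions, Fisher and Index combination, `Me` estimators, erosion factor `p_rt`, target prediction |
| `gpacc.relationships` | pedigree `A` (tabular method), genomic `G` (two standard constructions), `Me` from var(G−A), GEBV decomposition `g_A* = A G⁻¹ g_G` |
| `gpacc.blup_engine` | single-trait animal-model BLUP for any relationship matrix, population accuracy |
| `gpacc.empirical_accuracy` | exact O(n²) leave-one-out cross-validation, own-phenotype index, LR part-whole method |
| `gpacc.simulator` | neutral drift history, marker/QTL assignment, discrete breeding generations with random or GEBV selection |
| `gpacc.workflows` | replicated validation experiments, the decline regression, `gamma` calibration |
| `gpacc.cli` | `gpacc predict / estimate-me / decline / loo / simulate / experiment / calibrate-gamma` |

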