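# sparseclogit

Lasso (L1-penalized) conditional logistic regression for individually
matched epidemiological data: 1:1 and 1:M matched case-control studies and
case-crossover designs, at registry scale.

## Why

Matched designs are analyzed conditionally on the matched set, which removes
the stratum intercepts (the matching factors' joint effect) from the
likelihood. With hundreds of candidate exposures — e.g. every dispensed
drug class in a national prescription registry — maximum conditional
likelihood overfits, and subset selection is hopeless. The Lasso penalty
shrinks the log odds ratios and sets most exactly to zero, giving a sparse,
directly interpretable exposure model.

The conditional likelihood of a stratum with case covariates `u_0` and
controls `u_1..u_M` depends only on the differences `x_i = u_0 − u_i`:

    −log L(β) = Σ_n log(1 + Σ_i exp(−x_in'β)),         β̂(λ) = argmin −log L(β) + λ‖β‖₁

On the difference scale the IRLS weight matrix is diagonal, so each Newton
step reduces to a weighted Lasso problem solved by cyclic coordinate
descent on the p×p Gram system `X'WX`, `X'Wz` — memory is O(p²) no matter
how many matched sets, and sparse exposure matrices stay sparse. The path
over a decreasing λ grid is fitted with warm starts; λ is chosen by
likelihood-based K-fold cross-validation on strata, or by BIC with the
number of strata as sample size. Confounders (age, sex, chronic disease…)
can be forced into the model unpenalized.

## Worked example

```python
import numpy as np
import sparseclogit as scl

# a 1:1 matched study: 2000 pairs, 20 candidate exposures, three real
# effects (log odds ratios +0.6, -0.6, +0.6), exposure prevalence 20%
beta_true = np.zeros(20); beta_true[:3] = [0.6, -0.6, 0.6]
sim = scl.simulate_matched(scl.SimulationDesign(
    n_strata=2000, n_controls=1, n_predictors=20,
    beta_true=beta_true, exposure_prevalence=0.2, seed=7))

model = scl.ConditionalLogitLasso(sim.data)
sel = model.select(method="cv", n_lambdas=30, folds=10, seed=7)
print(sel.summary())
```

```
Model selection (CV)
==============================================
strata:          2000
grid size:       30
selected lambda: 7.13182
selected df:     14

variable      coef  odds_ratio  penalized
      x1  0.569345    1.767109       True
      x2 -0.467002    0.626879       True
      x3  0.553280    1.738947       True
      x4  0.144352    1.155291       True
      x5 -0.053904    0.947523       True
      x7 -0.144535    0.865425       True
      x8  0.078417    1.081574       True
     x10 -0.030994    0.969481       True
     x11 -0.055359    0.946146       True
     x13  0.011168    1.011230       True
     x15  0.025524    1.025852       True
     x16 -0.040715    0.960103       True
     x17  0.086383    1.090223       True
     x20  0.099479    1.104595       True
```

The three true effects head the table with the expected Lasso shrinkage
toward zero (true odds ratios e^±0.6 ≈ 1.82 / 0.55); a tail of small
spurious coefficients rides along, as plain CV-maximizing selection tends
to allow — BIC (`method="bic"`) prunes harder. `sel.path.plot()` draws the coefficient trace against λ, and
`model.fit(lam)` / `model.fit_path()` expose single fits and the raw path.

The same workflow runs from the shell:

```bash
sparseclogit simulate --n-strata 2000 --n-predictors 20 --out study
sparseclogit fit --input study.csv --select cv --folds 10 --seed 7 --out results/
```

which writes `path.csv`, `selection.json`, `odds_ratios.csv` and a
reproducibility log under `results/`.

## Layout

- `sparseclogit.data` — long-format/MTX ingestion, validation, difference
  matrix, concordant-strata and rare-exposure filters
- `sparseclogit.likelihood` — conditional likelihood, gradient, IRLS weights
- `sparseclogit.solver` — IRLS + coordinate descent at fixed λ
- `sparseclogit.path` — λ_max, grids, warm-started paths
- `sparseclogit.selection` — CV / BIC selection, odds-ratio tables
- `sparseclogit.simulate` — matched and case-crossover generators
- `sparseclogit.model` — `ConditionalLogitLasso` front-end with results
  objects
- `sparseclogit.cli` — `sparseclogit fit` / `sparseclogit simulate`

See `docs/methods.md` for the model, algorithm and design choices.
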