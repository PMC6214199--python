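# survscreen

Variable screening and selection for **ultra-high-dimensional right-censored
survival data**, aimed at prognostic modelling with germline SNP data: when
p (hundreds of thousands of variables) vastly exceeds n (a few hundred
patients), which combination of screening and selection recovers the handful
of truly prognostic variables, and how well does the resulting model
discriminate and calibrate on new patients?

The package provides, as a coherent pipeline:

* **Screening** to reduce p to a manageable subset
  * *aggressive SIS* — split the sample in two random halves; within each
    half rank every variable by its marginal Cox utility
    `u_k = max_{β} ℓ_k(β)` (the maximized univariate log partial
    likelihood); keep the top `s = ⌊n / log n⌋` per half and return the
    intersection `I₁ ∩ I₂`;
  * *ISIS* — iterate: screen conditionally on the currently selected set
    (its fitted linear predictor frozen as an offset), apply a selector to
    the union, stop at a fixed point or after 5 iterations;
  * *PSIS* — keep variables whose standardized marginal MPLE statistic
    `I_k(β̂_k)^{1/2} |β̂_k|` exceeds `Φ⁻¹(1 − q_m/2)`, controlling the
    marginal false-positive rate `q_m`.
* **Selection** on the screened set: Cox **LASSO** and **adaptive LASSO**
  (glmnet-style paths, penalty chosen by 10-fold cross-validated partial-
  likelihood deviance, ALASSO weights `1/|β̃_k|`), and **random survival
  forest** selection by minimal-depth thresholding against the
  topology-conditional null distribution of a noise variable's minimal depth.
* **A SNP survival simulator**: genotypes 0/1/2 i.i.d. under Hardy–Weinberg
  equilibrium with MAF q, Weibull proportional-hazards failure times with
  cumulative hazard `H(t|x) = t^τ exp(τ x'β)`, six informative variables
  with fixed "weak"/"strong" coefficient vectors, and uniform censoring on
  `[0, θ_c]` with `θ_c` calibrated exactly (closed-form root-finding) to a
  target censoring rate.
* **Evaluation**: Harrell's c-index, Brier-score `R²_BS(t*) = 1 −
  BS_model/BS_null` with IPCW weights, calibration slope and quartile
  tables, and Harrell-style bootstrap optimism correction.
* **QC/IO** for real-data-style analyses: tab-delimited genotype/outcome
  files, call-rate / HWE / MAF filters, mean imputation, train/test splits.

## Worked example

```python
import numpy as np
from survscreen import ScenarioConfig, MethodSpec, gen_dataset, run_method

cfg = ScenarioConfig(n=300, p=5000, signal="strong", test_n=2000, seed=11)
sim = gen_dataset(cfg, include_test=True)
rec = run_method(sim, None, MethodSpec.parse("ISIS-LASSO"), seed=3)
print({k: rec[k] for k in ("model_size", "n_informative",
                           "c_test", "r2_train", "cal_slope")})
```

prints (up to float formatting)

```
{'model_size': 7, 'n_informative': 6, 'c_test': 0.900, 'r2_train': 0.809,
 'cal_slope': 0.857}
```

— the pipeline screened 5 000
variables down to 7, of which all 6 truly informative ones were kept; the
refit proportional-hazards model reaches a test-set c-index of 0.90
(discrimination), explains ~81 % of the null model's Brier score at the
2-year horizon on the training data, and its prognostic index has a
calibration slope of 0.86 on the independent test set (values below 1
indicate some overfitting; averaged over replicates the slope sits near
0.95).

The same pipelines are scriptable from the shell:

```sh
survscreen simulate --config scenario.json --out data/ --test
survscreen select --genotypes data/genotypes.tsv --outcome data/outcome.tsv \
    --method ISIS-LASSO --seed 3 --out model.json
survscreen evaluate --genotypes data/genotypes_test.tsv \
    --outcome data/outcome_test.tsv --model model.json \
    --train-genotypes data/genotypes.tsv --train-outcome data/outcome.tsv \
    --out report.json
survscreen benchmark --config grid.json --seed 1 --workers 4 --out results/
```

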