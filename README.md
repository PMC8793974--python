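# wsvm — weighted support vector machine for binary clinical classification

`wsvm` implements the **weighted SVM (w-SVM)**: a binary classifier for
mixed tabular clinical data (continuous covariates plus integer-coded
factors) that pre-scales every predictor by how strongly it is associated
with the dichotomous outcome before training a radial-basis-function SVM.
It was designed for angiographic heart-disease prediction on the UCI
Cleveland table (13 predictors, outcome ±1 = disease present/absent), and
ships the full evaluation protocol around the classifier: stratified
Monte-Carlo cross-validation (MCCV) over several train:test splitting
ratios, seven confusion-matrix performance indices, 10-fold
cross-validated hyperparameter tuning, and a paired comparison harness
against standard baselines (unweighted SVM, random forest, naive Bayes).

## The method

For predictor $X_j$ and labels $y_i \in \{-1, +1\}$, the point-biserial
correlation is

$$r_{x_j Y} = \frac{\bar X_{+1} - \bar X_{-1}}{S_X}\sqrt{\frac{p_{+1}\,p_{-1}\,n}{n-1}},$$

with $\bar X_{\pm1}$ the class means, $p_{\pm1}$ the class proportions and
$S_X$ the $(n{-}1)$-denominator sample SD — algebraically identical to the
Pearson correlation of $x$ against $y$ coded 0/1. The feature weights are
the normalized absolute correlations

$$\omega_j = \frac{|r_{x_j Y}|}{\sum_{k=1}^{p} |r_{x_k Y}|},
\qquad \mathrm{tr}(\omega) = \textstyle\sum_j \omega_j = 1,$$

and the classifier trains the soft-margin RBF dual

$$\max_\alpha \sum_i \alpha_i - \tfrac12 \sum_{i,j} \alpha_i\alpha_j y_i y_j
K(z_i, z_j), \quad 0 \le \alpha_i \le C,\ \ \textstyle\sum_i \alpha_i y_i = 0,$$

on the weighted matrix $Z = X\,\mathrm{diag}(\omega)$ with
$K(u,v)=\exp(-\gamma\lVert u-v\rVert^2)$. The dual is solved by an SMO
(maximal-violating-pair) optimizer written for this package and verified
against a generic constrained-QP solve. Weighting shrinks noise
directions of the kernel geometry, which is where the method earns its
keep when only a few predictors carry signal.

Performance is reported through Acc, MER, Se, Sp, P+, P− and the Jaccard
index JI = TP/(TP+FP+FN), averaged over MCCV iterations.

## Worked example

Ten features, one of which (`S`, effect size δ = 2) carries all the
signal; 300 samples, 50 MCCV iterations at an 80:20 split:

```python
from wsvm import (SyntheticSpec, generate_synthetic, compute_weight_vector,
                  weight_table, mccv, PipelineConfig)

effects = {"S": 2.0, **{f"N{i}": 0.0 for i in range(9)}}
ds = generate_synthetic(SyntheticSpec(n=300, class_prob=0.5,
                                      continuous_effects=effects, seed=7))
print(weight_table(compute_weight_vector(ds)).head(3).to_string(index=False))
cfg = PipelineConfig(tune_mode="fixed", C=1.0, gamma=0.5)
rep = mccv(ds, ratio=0.80, n_iter=50, master_seed=123, config=cfg)
print({k: round(v, 2) for k, v in rep.mean_report.as_percent().items()})
```

prints

```
variable  correlation   weight  rank
       S     0.756421 0.664655     1
      N0    -0.107584 0.094533     2
      N1    -0.028787 0.025295     8
{'acc': 85.9, 'mer': 14.1, 'se': 81.36, 'sp': 89.88, 'p_plus': 87.73, 'p_minus': 84.95, 'ji': 73.06}
```

The weighting step puts ~66% of the total weight on the signal feature
(rank 1), and the resulting 14.1% mean misclassification rate sits near
the Bayes floor for this effect size (≈15.9% for a single δ = 2 feature);
the same 50 shared splits give the unweighted RBF SVM a mean MER of
16.7%.

The same pipeline is scriptable from the shell; outputs embed the config
hash and master seed for provenance:

```bash
wsvm evaluate --config examples/synthetic.yaml   # MCCV index table (CSV+JSON)
wsvm weights  --config examples/synthetic.yaml   # correlation/weight/rank table
wsvm compare  --config examples/synthetic.yaml   # paired mean-MER vs SVM/RF/NB
wsvm synth    --config examples/synthetic.yaml   # write the synthetic CSV
```

To run on the real Cleveland table, fetch it once with
`python scripts/fetch_cleveland.py` (the library itself never downloads
anything) and pass `--data data/processed.cleveland.data`; cleaning drops
the 6 incomplete records of the 303, leaving n = 297 with a 137/160
(46.1%/53.9%) class split.

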