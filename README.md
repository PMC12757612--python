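# fsnblr

Fourier-series nonparametric binary logistic regression, with full
likelihood-based inference.

## The problem

Binary outcomes in regional and socioeconomic statistics — for example,
whether a district is classified as underdeveloped — often depend on
continuous covariates (infrastructure coverage, fiscal capacity, enrollment
rates) through relationships that are far from linear on the logit scale,
and sometimes visibly oscillatory when outcomes are plotted against grouped
covariate values. Standard binary logistic regression (BLR) forces a linear
logit and can miss these patterns. This package implements a
cosine-series extension, **FSNBLR** (Fourier Series Nonparametric Binary
Logistic Regression), for analysts who want that extra flexibility while
keeping the familiar maximum-likelihood inferential toolkit: an overall
likelihood-ratio test, per-parameter Wald tests, and information-criterion
model selection.

## The model

For a binary response $y_i \sim \mathrm{Bernoulli}(\pi_i)$ and $p$
continuous predictors $x_{1i},\dots,x_{pi}$,

$$
\mathrm{logit}(\pi_i) \;=\; a_0 \;+\; \sum_{j=1}^{p}\Big( b_j x_{ji}
  \;+\; \sum_{k=1}^{K_j} a_{kj}\,\cos(k\,x_{ji}) \Big),
$$

where $K_j \ge 0$ is the number of cosine harmonics ("oscillation
parameters") for predictor $j$. Setting every $K_j = 0$ recovers plain BLR,
so the classical model is a strict special case. The parameter vector
$\theta = (a_0, b_1, a_{11},\dots)$ is estimated by Newton–Raphson maximum
likelihood with analytic score $g(\theta) = X^\top(y-\pi)$ and Hessian
$H(\theta) = -X^\top W X$, $W = \mathrm{diag}(\pi_i(1-\pi_i))$, iterating
$\theta^{(t+1)} = \theta^{(t)} - H^{-1}g$ until
$\lVert\theta^{(t+1)}-\theta^{(t)}\rVert_\infty < 10^{-6}$.

Inference follows the standard likelihood theory:

- **Simultaneous test** — $G^2 = 2[L(\hat\theta_\Omega) -
  L(\hat\theta_\omega)]$ against the intercept-only null, asymptotically
  $\chi^2$ with $p + \sum_j K_j$ degrees of freedom (equal to $p(K{+}1)$
  when all $K_j = K$).
- **Partial tests** — Wald $Z = \hat\theta_r / \sqrt{\widehat{\mathrm{Var}}
  (\hat\theta_r)}$, with variances from the diagonal of
  $-[H(\hat\theta)]^{-1}$, referred to the standard normal.
- **Order selection** — exhaustive AIC minimization over
  $K \in \{1..K_{\max}\}^p$ ($K_{\max}=3$ by default), with a greedy mode
  for large $p$.
- **Model comparison** — deviance, accuracy/sensitivity/specificity at a
  0.5 cutoff, rank-based AUC, and Press's Q.

A seeded synthetic-data module generates datasets from known cosine-series
truths (including a preset emulating a 232-district, six-predictor regional
study with a 55/232 positive class), so every statistical property is
testable without access to restricted data.

## Worked example

Simulate data from a known truth with $K = (2, 1)$ and cosine coefficients
$(1.0, 0.8)$ and $(0.9)$, then fit, test and compare:

```sh
$ fsnblr simulate strong_cosine --seed 7 --n 1000 --out demo.csv
wrote demo.csv (n=1000, p=2, positives=473) and demo.truth.json

$ fsnblr fit demo.csv -k 2,1
converged in 6 iterations; loglik=-472.6478 AIC=957.2956
               (intercept)  -0.000862
                    b_1:x1   0.368053
                  a_1,1:x1   0.972605
                  a_2,1:x1   0.760915
                    b_2:x2  -0.372647
                  a_1,2:x2   0.885708

$ fsnblr test demo.csv -k 2,1 | head -4
LRT: G2=438.0813 df=5 p=1.83e-92 critical=11.0705 -> reject H0
 Parameters  Estimations  Std. Error    z value     Pr(>|z|)          Decision
(intercept)    -0.000862    0.202045  -0.004265 9.965970e-01 fail to reject H0
     b_1:x1     0.368053    0.030705  11.986705 4.171740e-33         reject H0

$ fsnblr compare demo.csv -k 2,1
           deviance          aic  accuracy  sensitivity  specificity       auc  press_q  ...
BLR     1104.957374  1110.957374     0.727     0.743833     0.708245  0.791171  206.116  ...
FSNBLR   945.295620   957.295620     0.771     0.795066     0.744186  0.852494  293.764  ...
```

The fitted coefficients sit close to the generating truth (0.4, 1.0, 0.8,
−0.4, 0.9 with a zero intercept); the simultaneous test overwhelmingly
rejects the no-effect null ($G^2 = 438$ on 5 df); and the cosine model
beats the linear-logit baseline on every comparison column — deviance drops
by about 160 and AUC rises from 0.79 to 0.85 — because the generating truth
really does oscillate. `fsnblr pipeline` chains all stages (VIF screen,
BLR baseline, AIC selection, LRT/Wald tables, significant-predictor refit,
comparison) and writes JSON + TSV reports.

The same operations are available as a library:

```python
from fsnblr import fit_newton, lrt_simultaneous, fit_intercept_only, scenario

data, truth = scenario("strong_cosine", seed=7, n=1000)
fit = fit_newton(data, truth["K_true"])
print(lrt_simultaneous(fit, fit_intercept_only(data)))
```

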