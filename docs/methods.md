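# Methods

This note records the statistical model the package implements, the
numerical decisions behind the implementation, what the synthetic-data
generator does and does not emulate, and the known limitations. It is the
reference for "why is it done this way" questions.

## Model

The response is Bernoulli, $y_i \sim B(1, \pi(x_i))$, with

$$
\mathrm{logit}\,\pi(x_i) = a_0 + \sum_{j=1}^p \Big( b_j x_{ji} +
\sum_{k=1}^{K_j} a_{kj} \cos(k\,x_{ji}) \Big).
$$

Two modelling choices deserve comment:

- **A single intercept.** The textbook presentation of the cosine-series
  logit carries a half-constant $\tfrac12 a_{0j}$ per predictor. Those $p$
  constants are perfectly collinear with each other (each contributes a
  column of ones), so the model keeps exactly one intercept $a_0$.
  Anything else makes the Hessian singular by construction, and published
  coefficient tables for this model family likewise report a single
  intercept.
- **Raw cosine arguments by default.** The cosine acts on the raw
  predictor value, $\cos(k x)$, because that is what published coefficient
  sets for this model assume; published worked examples evaluate
  $\cos(50)$, $\cos(100)$ etc. directly in data units. For a predictor
  spanning hundreds of units this makes $\cos(kx)$ oscillate very fast
  relative to the data spacing, which is statistically legitimate (the
  basis is still bounded and smooth in the coefficients) but hard to
  interpret as a smooth trend. An optional `rescale_cosine` flag min–max
  maps each predictor to $[0, \pi]$ *inside the cosine only* (the linear
  term keeps raw units); it is off by default and the two modes are not
  comparable coefficient-for-coefficient. Per-predictor harmonic counts
  $K_j \ge 0$ are allowed, with $K_j = 0$ meaning the predictor enters
  linearly only; all $K_j = 0$ is exactly classical logistic regression,
  which is how the BLR baseline is fitted.

## Estimation

Newton–Raphson on the log-likelihood
$L(\theta) = \sum_i [y_i \eta_i - \ln(1 + e^{\eta_i})]$ with analytic score
and observed Hessian. Numerical decisions:

- **Start at $\theta = 0$** (all probabilities 0.5). The likelihood is
  concave, so the start only affects the path, not the optimum; a fixed
  start makes every fit deterministic and reproducible.
- **Convergence** is declared when the max-abs parameter change falls
  below `epsilon` ($10^{-6}$) *and* the score's max-abs component is below
  `grad_tol` ($10^{-6}$). The second condition makes "converged" mean
  first-order optimality even when predictors have large raw scales (where
  a tiny parameter step does not by itself guarantee a flat score).
- **Step-halving.** A full Newton step that would lower the
  log-likelihood is halved, up to 30 times; accepted steps therefore never
  decrease the log-likelihood (up to a $10^{-10}$ relative floor for
  floating-point noise). If no improving step exists the fit returns with
  `converged=False` and a message — never silently.
- **Transient ridge.** If the Hessian solve fails mid-iteration, a
  trace-scaled diagonal boost (`ridge`, default $10^{-8}$) is added for
  that step only. The final covariance $-[H(\hat\theta)]^{-1}$ is always
  computed from the unregularized Hessian; if that matrix is singular the
  covariance is reported unavailable rather than silently regularized.
- **Overflow policy.** The linear predictor is clipped at $\pm 700$ inside
  exponentials only, and probabilities are kept in
  $[10^{-16}, 1-10^{-16}]$, so likelihoods stay finite for quasi-separable
  data during iteration.
- **Separation.** Diverging coefficients with log-likelihood approaching
  zero (the signature of complete separation, where no MLE exists) are
  flagged via `separation_suspected`; the heuristic fires when
  $\lVert\theta\rVert_\infty$ exceeds 50 while the log-likelihood is above
  $-10^{-4}$, or when $\lVert\theta\rVert_\infty$ exceeds $10^8$ outright.
- `max_iter` defaults to 100; rank-deficient designs are rejected up front
  with the offending columns named (QR with column pivoting).

## Inference

- **Simultaneous LRT.** $G^2 = 2[L(\hat\theta_\Omega) -
  L(\hat\theta_\omega)]$ where the null is the intercept-only model with
  its intercept *re-estimated* by maximum likelihood (the standard LRT;
  the alternative reading, fixing the null intercept at the full-model
  value, is not a likelihood ratio). Degrees of freedom equal the number
  of constrained parameters, $p + \sum_j K_j$, which reduces to the
  common-order formula $p(K+1)$ when every $K_j = K$.
- **Wald tests.** $Z = \hat\theta_r / \mathrm{SE}$, SE from the diagonal
  of the inverse observed information, two-sided normal p-values. The
  intercept is tested identically to the slopes. No multiple-testing
  correction is applied — decisions are marginal per parameter, which is
  conventional in this model family but inflates the family-wise error
  over 16 simultaneous rows; treat borderline rejections accordingly.
- **Predictor retention** after partial testing is hierarchical: a
  predictor is kept iff its *linear* coefficient $b_j$ is significant, and
  a kept predictor retains all its cosine harmonics regardless of their
  individual p-values. This matches the refit workflow used in published
  applications, where non-significant harmonics of significant predictors
  stay in the reduced model.
- Default significance level $\alpha = 0.05$, configurable everywhere.

## Order selection

AIC $= -2L + 2m$ with $m = 1 + p + \sum_j K_j$ (the intercept counts; the
standard definition). The default search fits every combination in
$\{1..K_{\max}\}^p$ exhaustively — at $p = 6$, $K_{\max} = 3$ that is 729
fits, a few seconds of work — with a guard at 20,000 combinations and a
greedy coordinate-ascent mode beyond that. Unconverged combinations are
recorded and excluded from the argmin. Exact AIC ties break toward the
smaller total harmonic count, then lexicographically.

A property worth knowing: AIC's penalty of 2 per parameter accepts a
superfluous harmonic whenever its deviance gain exceeds 2, which under the
truth happens with asymptotic probability $P(\chi^2_1 > 2) \approx 0.157$
per candidate term. With several superset models in the grid the
probability that the exact generating combination wins is therefore
bounded around 2/3 even at large $n$ — the selected model tends to include
the truth rather than equal it. The package reports the full grid so users
can see near-ties; selection consistency would require a BIC-type penalty,
which is out of scope.

## Classification metrics

Deviance is $-2L$ (for ungrouped binary data the saturated log-likelihood
is zero). Classification uses a 0.5 cutoff with the boundary classified as
1 (a fixed rule for determinism). Sensitivity/specificity are the recalls
of the two true classes; published tables in this model family compute
"sensitivity" on the majority (negative/"developed") class, so
`sensitivity_class` defaults to 0 and is explicit in the API. AUC is the
Mann–Whitney rank statistic with ties counted one half. Press's Q is
$(N - nK)^2 / (N(K-1))$ for $n$ correct of $N$ in $K$ groups, referred to
$\chi^2_1$. Empty-class recalls are reported as missing, never as zero.
All metrics are in-sample (apparent); no cross-validation is attempted.

## Synthetic data

The generator draws predictors independently per column — uniform over a
configured $[\mathrm{low}, \mathrm{high}]$ by default, or truncated normal
matching a stated mean/variance — and responses as Bernoulli with
probabilities from a known cosine-series truth. Everything is
deterministic given the seed.

Preset scenarios fix the simulation conditions used by the test suite:

| preset | n | p | truth | purpose |
|---|---|---|---|---|
| `paper_shape` | 232 | 6 | $K=(3,2,1,1,1,1)$, published coefficient magnitudes, intercept calibrated to prevalence 55/232 | structural emulation of the regional study |
| `null_model` | 500 | 2 | all coefficients zero | test size / null distributions |
| `blr_only` | 200 | 3 | linear logit only | oracle comparison with classical logistic fits |
| `strong_cosine` | 1000 | 2 | $K=(2,1)$, cosine amplitudes 1.0/0.8/0.9 | recovery, coverage, selection studies |
| `one_null_predictor` | 2000 | 3 | third predictor has no effect | predictor-screening behaviour |

Intercept calibration bisects on $a_0$ until the mean of $\pi_i$ over the
realized design hits the target prevalence within 0.01; bisection is exact
here because the mean probability is strictly increasing in $a_0$.

What the generator does **not** emulate: dependence between predictors
(the real study's predictors pass a VIF screen, so independence is a
reasonable default; a correlated mode exists only for stress testing),
spatial dependence between districts, measurement error, and the real
data's joint distribution. In particular, uniform marginals combined with
the published coefficient magnitudes produce *more separable* data than
the real study — in-sample AUCs on `paper_shape` draws run in the
mid-90s, versus low-70s reported for the real data — so passing tests
demonstrate correctness of the machinery and its asymptotic properties,
not that the real study's numbers are recovered. The real dataset is not
redistributable, and no attempt is made to reproduce its fitted tables.

## Simulation sizes used in the checks

The acceptance checks use: 1000 replicates at $n=500$ for the LRT size and
null-distribution study; 500 replicates at $n=1000$ for 95 % Wald-interval
coverage; 100 replicates each at $n \in \{200, 1000, 5000\}$ for RMSE
consistency; 100 replicates at $n=3000$ for order-selection recovery; 20
datasets at $n=200$ for the classical-logistic oracle comparison; and 100
randomized instances for the finite-difference calculus oracles. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands (e.g. ±0.007 on a 0.05 rejection rate at 1000 replicates).

## Known limitations

- Cosine bases on raw units make fitted curves wiggle at the data's
  resolution for wide-ranged predictors; use `rescale_cosine` when a
  smooth low-frequency trend is the goal.
- Wald inference relies on the usual asymptotics; with $n/m$ small or
  near-separable data the intervals can under-cover. The LRT null
  re-estimates only the intercept, so it tests "any effect at all", not
  individual nested comparisons.
- AIC selection over-includes harmonics by design (see above).
- No sine terms, interactions, multinomial/ordinal responses, penalized or
  Bayesian estimation, or confidence intervals for predicted
  probabilities.
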