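"""Newton-Raphson maximum-likelihood fitting.

The update is ``theta <- theta - H(theta)^-1 g(theta)`` with analytic score
and Hessian, starting from ``theta = 0`` (every probability 0.5, a
well-conditioned start), so fits are deterministic.  Iteration stops when the
max-abs parameter change falls below ``epsilon`` and the score satisfies
first-order optimality.  A full Newton step that would lower the
log-likelihood is halved (up to ``max_halvings`` times); if no improving step
exists the fit is returned flagged as unconverged, never silently.  The
coefficient covariance is ``-H(theta_hat)^-1``, always computed from the
unregularized Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_core import (
    ConvergenceOptions,
    Dataset,
    DesignMatrix,
    OscillationOrders,
    ParameterVector,
    build_design,
    gradient,
    hessian,
    log_likelihood,
)

__all__ = [
    "FitResult",
    "fit_newton",
    "fit_intercept_only",
    "covariance",
    "RankDeficientError",
    "SingularCovarianceError",
]


class RankDeficientError(ValueError):
    """Design matrix does not have full column rank."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Hessian at the optimum is singular; no covariance available."""


@dataclass
class FitResult:
    """A fitted model: estimates, likelihood, covariance and diagnostics.

    ``trace`` holds the max-abs parameter change per accepted iteration and
    ``loglik_trace`` the log-likelihood after each accepted step (it is
    non-decreasing by construction).  ``cov`` is ``-H(theta_hat)^-1`` when
    available, else ``None``.
    """

    theta_hat: ParameterVector
    loglik: float
    design: DesignMatrix
    y: np.ndarray
    n_iter: int
    converged: bool
    trace: list[float]
    loglik_trace: list[float]
    cov: np.ndarray | None
    model_kind: str
    names: tuple[str, ...] = ()
    message: str = ""
    separation_suspected: bool = False

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def m(self) -> int:
        return self.design.m

    @property
    def param_labels(self) -> tuple[str, ...]:
        return self.design.labels


def _check_rank(design: DesignMatrix) -> None:
    # QR with column pivoting localizes the offending columns.
    cols = design.columns
    _, R, piv = scipy.linalg.qr(cols, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(cols.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = piv[diag <= tol] if diag.size else np.array([], dtype=int)
    if bad.size:
        labels = [design.labels[j] for j in sorted(bad.tolist())]
        raise RankDeficientError(
            f"design matrix is rank deficient; dependent columns: {labels}"
        )


def _solve_step(H: np.ndarray, g: np.ndarray, ridge: float) -> np.ndarray:
    A = -H
    try:
        c, low = scipy.linalg.cho_factor(A)
        return scipy.linalg.cho_solve((c, low), g)
    except scipy.linalg.LinAlgError:
        # transient ridge, trace-scaled; the final covariance never uses it
        boost = ridge * max(np.trace(A) / A.shape[0], 1.0)
        return scipy.linalg.solve(A + boost * np.eye(A.shape[0]), g, assume_a="sym")


def _model_kind(K: OscillationOrders) -> str:
    if K.p == 0:
        return "intercept_only"
    return "blr" if K.total == 0 else "fsnblr"


def _fit_on_design(y: np.ndarray, design: DesignMatrix, options: ConvergenceOptions,
                   names: tuple[str, ...], theta0: np.ndarray | None = None) -> FitResult:
    if y.min() == y.max():
        raise ValueError("fitting requires both response classes to be present")
    _check_rank(design)

    theta = np.zeros(design.m) if theta0 is None else np.asarray(theta0, float).copy()
    ll = log_likelihood(y, design, theta)
    trace: list[float] = []
    ll_trace: list[float] = [ll]
    converged = False
    separation = False
    message = ""
    n_iter = 0

    for n_iter in range(1, options.max_iter + 1):
        g = gradient(y, design, theta)
        H = hessian(y, design, theta)
        step = _solve_step(H, g, options.ridge)

        alpha = 1.0
        accepted = False
        for _ in range(options.max_halvings + 1):
            cand = theta + alpha * step
            cand_ll = log_likelihood(y, design, cand)
            if cand_ll >= ll - 1e-10 * (1.0 + abs(ll)):
                accepted = True
                break
            if not options.step_halving:
                break
            alpha *= 0.5
        if not accepted:
            message = "no improving Newton step found (step-halving exhausted)"
            break

        change = float(np.max(np.abs(cand - theta)))
        theta, ll = cand, cand_ll
        trace.append(change)
        ll_trace.append(ll)

        if np.max(np.abs(theta)) > 1e8 or (ll > -1e-4 and np.max(np.abs(theta)) > 50.0):
            separation = True
            message = "complete separation suspected (diverging coefficients, loglik -> 0)"
            break

        if change < options.epsilon:
            if float(np.max(np.abs(gradient(y, design, theta)))) < options.grad_tol:
                converged = True
                break
            # parameter change is tiny but the score is not yet flat: keep going
    else:
        message = f"did not converge within max_iter={options.max_iter}"

    cov = None
    if converged:
        A = -hessian(y, design, theta)
        try:
            cov = scipy.linalg.inv(A)
            cov = 0.5 * (cov + cov.T)
        except scipy.linalg.LinAlgError:
            cov = None
            message = "singular Hessian at the optimum; covariance unavailable"

    return FitResult(
        theta_hat=ParameterVector.unflatten(theta, design.orders),
        loglik=ll,
        design=design,
        y=np.asarray(y, dtype=float),
        n_iter=n_iter,
        converged=converged,
        trace=trace,
        loglik_trace=ll_trace,
        cov=cov,
        model_kind=_model_kind(design.orders),
        names=names,
        message=message,
        separation_suspected=separation,
    )


def fit_newton(data: Dataset, K, options: ConvergenceOptions | None = None,
               rescale_cosine: bool = False,
               theta0: ParameterVector | np.ndarray | None = None) -> FitResult:
    """Fit the FSNBLR model (or plain BLR when all ``K_j = 0``).

    Parameters
    ----------
    data : Dataset with both classes present
    K : OscillationOrders (or sequence of ints), one entry per predictor
    options : ConvergenceOptions; defaults apply when omitted
    theta0 : optional warm start (defaults to the zero vector)
    """
    options = options or ConvergenceOptions()
    design = build_design(data.X, K, names=data.names, rescale_cosine=rescale_cosine)
    if theta0 is not None and isinstance(theta0, ParameterVector):
        theta0 = theta0.flatten()
    return _fit_on_design(data.y, design, options, data.names, theta0)


def fit_intercept_only(data: Dataset, options: ConvergenceOptions | None = None) -> FitResult:
    """Fit the null model with only an intercept (MLE: logit of the mean)."""
    options = options or ConvergenceOptions()
    design = DesignMatrix(
        np.ones((data.n, 1)), ("(intercept)",), OscillationOrders(()), ()
    )
    return _fit_on_design(data.y, design, options, ())


def covariance(fit: FitResult) -> np.ndarray:
    """Coefficient covariance ``-H(theta_hat)^-1`` of a converged fit."""
    if not fit.converged:
        raise ValueError("covariance requires a converged fit")
    if fit.cov is None:
        raise SingularCovarianceError(
            "Hessian at the optimum is singular; covariance unavailable"
        )
    return fit.cov
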