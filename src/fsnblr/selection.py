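"""Oscillation-order selection, the significant-predictor refit, and VIF.

The harmonic counts are chosen by minimizing AIC = -2 loglik + 2 m, where m
counts every flat parameter including the intercept.  The default search is
exhaustive over ``{1..Kmax}^p`` (at p = 6, Kmax = 3 that is 729 fits, well
within reach); a greedy coordinate-ascent mode is provided for larger p.
Unconverged combinations are recorded but excluded from the argmin.  Exact
AIC ties break toward the smaller total harmonic count, then lexicographic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, fit_intercept_only, fit_newton
from .inference import significant_predictors, wald_partial
from .model_core import ConvergenceOptions, Dataset, OscillationOrders

__all__ = [
    "GridEntry",
    "SelectionResult",
    "aic",
    "grid_search",
    "refit_significant",
    "vif",
]

_MAX_COMBINATIONS = 20_000


@dataclass(frozen=True)
class GridEntry:
    orders: OscillationOrders
    aic: float
    converged: bool


@dataclass(frozen=True)
class SelectionResult:
    grid: tuple[GridEntry, ...]
    best: GridEntry
    Kmax: int
    mode: str

    @property
    def best_orders(self) -> OscillationOrders:
        return self.best.orders


def aic(fit: FitResult) -> float:
    """AIC = -2 loglik + 2 m with m the flat parameter count."""
    if not fit.converged:
        raise ValueError("AIC requires a converged fit")
    return -2.0 * fit.loglik + 2.0 * fit.m


def _entry_key(e: GridEntry):
    return (e.aic, sum(e.orders.K), e.orders.K)


def _evaluate(data: Dataset, K: tuple[int, ...],
              options: ConvergenceOptions, rescale_cosine: bool) -> GridEntry:
    orders = OscillationOrders(K)
    try:
        fit = fit_newton(data, orders, options, rescale_cosine=rescale_cosine)
    except (ValueError, np.linalg.LinAlgError):
        return GridEntry(orders, np.inf, False)
    if not fit.converged:
        return GridEntry(orders, np.inf, False)
    return GridEntry(orders, aic(fit), True)


def grid_search(data: Dataset, Kmax: int = 3,
                options: ConvergenceOptions | None = None,
                mode: str = "exhaustive",
                rescale_cosine: bool = False) -> SelectionResult:
    """Search harmonic-count combinations ``{1..Kmax}^p`` for minimum AIC."""
    if Kmax < 1:
        raise ValueError("Kmax must be at least 1")
    if mode not in ("exhaustive", "greedy"):
        raise ValueError(f"unknown search mode: {mode!r}")
    options = options or ConvergenceOptions()
    p = data.p

    entries: list[GridEntry] = []
    if mode == "exhaustive":
        n_comb = Kmax ** p
        if n_comb > _MAX_COMBINATIONS:
            raise ValueError(
                f"exhaustive search over {n_comb} combinations exceeds the "
                f"{_MAX_COMBINATIONS} guard; use mode='greedy' or lower Kmax"
            )
        for K in itertools.product(range(1, Kmax + 1), repeat=p):
            entries.append(_evaluate(data, K, options, rescale_cosine))
    else:
        current = tuple([1] * p)
        seen: dict[tuple[int, ...], GridEntry] = {}
        seen[current] = _evaluate(data, current, options, rescale_cosine)
        while True:
            candidates = []
            for j in range(p):
                if current[j] < Kmax:
                    K = current[:j] + (current[j] + 1,) + current[j + 1:]
                    if K not in seen:
                        seen[K] = _evaluate(data, K, options, rescale_cosine)
                    candidates.append(seen[K])
            improving = [e for e in candidates
                         if e.converged and e.aic < seen[current].aic]
            if not improving:
                break
            best_step = min(improving, key=_entry_key)
            current = best_step.orders.K
        entries = list(seen.values())

    converged = [e for e in entries if e.converged]
    if not converged:
        raise RuntimeError("every combination in the search space failed to fit")
    best = min(converged, key=_entry_key)
    return SelectionResult(tuple(entries), best, Kmax, mode)


def refit_significant(data: Dataset, full_fit: FitResult, alpha: float = 0.05,
                      Kmax: int = 3, options: ConvergenceOptions | None = None,
                      rescale_cosine: bool = False) -> FitResult:
    """Drop predictors with non-significant linear terms, re-select, refit.

    Runs the per-parameter Wald tests on ``full_fit``, keeps predictors whose
    linear coefficient is significant at ``alpha`` (with all their
    harmonics), re-runs the AIC grid search on the reduced predictor set and
    fits the winning combination.  With no significant predictor the
    intercept-only model is returned with a warning.
    """
    options = options or ConvergenceOptions()
    wald = wald_partial(full_fit, alpha=alpha)
    keep = significant_predictors(wald, alpha=alpha)
    if not keep:
        warnings.warn(
            "no predictor has a significant linear coefficient; "
            "returning the intercept-only model",
            stacklevel=2,
        )
        return fit_intercept_only(data, options)
    reduced = data.subset(sorted(keep, key=data.names.index))
    sel = grid_search(reduced, Kmax=Kmax, options=options,
                      rescale_cosine=rescale_cosine)
    return fit_newton(reduced, sel.best_orders, options,
                      rescale_cosine=rescale_cosine)


def vif(X: np.ndarray, names=None) -> pd.Series:
    """Variance inflation factors, ``VIF_j = 1 / (1 - R2_j)``.

    ``R2_j`` comes from the ordinary least-squares regression of predictor j
    on the remaining predictors plus an intercept.  Exactly collinear
    predictors get ``inf``.  Values >= 10 are the conventional
    multicollinearity flag.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    n, p = X.shape
    if n <= p:
        raise ValueError("VIF needs more observations than predictors")
    names = list(names) if names else [f"x{j + 1}" for j in range(p)]
    out = np.empty(p)
    for j in range(p):
        target = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        if ss_tot == 0.0:
            out[j] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names, name="VIF")
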