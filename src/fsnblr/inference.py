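"""Likelihood-ratio and Wald tests for fitted models.

The simultaneous test compares the full fit against the intercept-only null
(both intercepts estimated by maximum likelihood):

    G2 = 2 [ L(theta_full) - L(theta_null) ]  ~  chi2(df),
    df = number of non-intercept parameters = p + sum(K_j)

which reduces to the common-order form ``p (K + 1)`` when every predictor
uses the same K.  Partial tests are Wald z statistics, ``z = estimate / SE``
with the SE taken from the diagonal of ``-H(theta_hat)^-1``, referred to the
standard normal (two-sided).  No multiple-testing correction is applied:
per-parameter decisions are marginal, which is a deliberate caveat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimation import FitResult, covariance

__all__ = [
    "LRTResult",
    "WaldResult",
    "lrt_simultaneous",
    "wald_partial",
    "significant_predictors",
    "wald_table",
]


@dataclass(frozen=True)
class LRTResult:
    G2: float
    df: int
    p_value: float
    alpha: float
    critical_value: float
    reject: bool


@dataclass(frozen=True)
class WaldResult:
    """One per flat parameter (the intercept is tested like any slope)."""

    label: str
    kind: str            # "intercept" | "linear" | "cosine"
    predictor: str | None
    harmonic: int | None
    estimate: float
    se: float
    z: float
    p_value: float
    reject: bool


_LINEAR = re.compile(r"^b_(\d+):(.*)$")
_COSINE = re.compile(r"^a_(\d+),(\d+):(.*)$")


def _parse_label(label: str) -> tuple[str, str | None, int | None]:
    if label == "(intercept)":
        return "intercept", None, None
    m = _LINEAR.match(label)
    if m:
        return "linear", m.group(2), None
    m = _COSINE.match(label)
    if m:
        return "cosine", m.group(3), int(m.group(1))
    raise ValueError(f"unrecognized parameter label: {label!r}")


def lrt_simultaneous(fit_full: FitResult, fit_null: FitResult,
                     alpha: float = 0.05) -> LRTResult:
    """Simultaneous likelihood-ratio test of all non-intercept parameters."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if fit_null.m != 1:
        raise ValueError("fit_null must be the intercept-only model")
    if fit_full.n != fit_null.n or not np.array_equal(fit_full.y, fit_null.y):
        raise ValueError("full and null fits must use the same response data")
    df = fit_full.m - 1
    if df < 1:
        raise ValueError("full model must nest the intercept-only null strictly")
    G2 = 2.0 * (fit_full.loglik - fit_null.loglik)
    if G2 < -1e-8:
        raise ValueError(
            f"null log-likelihood exceeds the full model's (G2={G2:.3g}); "
            "this signals an optimizer failure"
        )
    G2 = max(G2, 0.0)
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    p = float(stats.chi2.sf(G2, df))
    return LRTResult(G2=G2, df=df, p_value=p, alpha=alpha,
                     critical_value=critical, reject=bool(G2 > critical))


def wald_partial(fit: FitResult, alpha: float = 0.05) -> list[WaldResult]:
    """Per-parameter Wald z tests from the inverse observed information."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    cov = covariance(fit)
    var = np.diag(cov)
    flat = fit.theta_hat.flatten()
    out: list[WaldResult] = []
    for pos, label in enumerate(fit.param_labels):
        v = var[pos]
        if v <= 0:
            raise ValueError(
                f"non-positive variance for parameter {label!r} (var={v:.3g})"
            )
        kind, predictor, harmonic = _parse_label(label)
        se = float(np.sqrt(v))
        est = float(flat[pos])
        z = est / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(WaldResult(
            label=label, kind=kind, predictor=predictor, harmonic=harmonic,
            estimate=est, se=se, z=z, p_value=p, reject=bool(p < alpha),
        ))
    return out


def significant_predictors(wald: list[WaldResult], alpha: float = 0.05) -> set[str]:
    """Predictors whose *linear* coefficient rejects H0 at level alpha.

    Selection is at predictor level via the linear slope b_j; the cosine
    harmonics of a retained predictor are kept wholesale (hierarchical
    retention), so a predictor enters or leaves with all of its terms.
    """
    if not wald:
        raise ValueError("empty Wald result list")
    return {
        w.predictor for w in wald
        if w.kind == "linear" and w.predictor is not None and w.p_value < alpha
    }


def wald_table(wald: list[WaldResult]):
    """Render Wald results as a DataFrame with the conventional columns."""
    import pandas as pd

    return pd.DataFrame({
        "Parameters": [w.label for w in wald],
        "Estimations": [w.estimate for w in wald],
        "Std. Error": [w.se for w in wald],
        "z value": [w.z for w in wald],
        "Pr(>|z|)": [w.p_value for w in wald],
        "Decision": ["reject H0" if w.reject else "fail to reject H0" for w in wald],
    })
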