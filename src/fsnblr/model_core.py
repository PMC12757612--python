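"""Model objects and likelihood calculus for Fourier-series logistic regression.

A binary response ``y_i ~ Bernoulli(pi_i)`` is linked to ``p`` continuous
predictors through a linear predictor that augments each covariate's linear
term with a truncated cosine series::

    eta_i = a0 + sum_j [ b_j * x_ji + sum_{k=1}^{K_j} a_kj * cos(k * x_ji) ]
    pi_i  = exp(eta_i) / (1 + exp(eta_i))

``K_j`` is the number of cosine harmonics ("oscillation parameters") for
predictor ``j``; ``K_j = 0`` for every predictor recovers plain binary
logistic regression.  A single intercept ``a0`` is used: carrying one
half-constant per predictor would make the design perfectly collinear, so the
per-predictor constants are collapsed into one identifiable intercept.

This module provides the data containers, the design-matrix construction and
the log-likelihood together with its analytic gradient and Hessian, which the
estimation layer consumes for Newton-Raphson fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Dataset",
    "OscillationOrders",
    "ParameterVector",
    "DesignMatrix",
    "ConvergenceOptions",
    "build_design",
    "linear_predictor",
    "predict_prob",
    "log_likelihood",
    "gradient",
    "hessian",
]

# eta is clipped at +/-700 inside exponentials only; probabilities are kept
# strictly inside (0, 1) so logs never overflow for quasi-separable data.
ETA_CLIP = 700.0
_PROB_EPS = 1e-16


@dataclass(frozen=True)
class Dataset:
    """A binary response with continuous predictors.

    Parameters
    ----------
    y : array of 0/1, length n
    X : (n, p) float matrix, no missing values
    names : p predictor labels (defaults to ``x1..xp``)
    """

    y: np.ndarray
    X: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.ndim != 1 or X.ndim != 2:
            raise ValueError("y must be 1-D and X 2-D")
        if y.shape[0] != X.shape[0]:
            raise ValueError(
                f"y has {y.shape[0]} rows but X has {X.shape[0]}"
            )
        if y.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("need n >= 1 observations and p >= 1 predictors")
        if not np.all(np.isin(y, (0.0, 1.0))):
            bad = np.where(~np.isin(y, (0.0, 1.0)))[0]
            raise ValueError(f"y must be binary 0/1; offending rows: {bad[:10].tolist()}")
        if not np.all(np.isfinite(X)):
            bad = np.where(~np.all(np.isfinite(X), axis=1))[0]
            raise ValueError(f"X contains non-finite values; offending rows: {bad[:10].tolist()}")
        names = tuple(self.names) or tuple(f"x{j + 1}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValueError("names length must match the number of predictors")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, keep: Sequence[str]) -> "Dataset":
        """Restrict to the named predictors, preserving column order."""
        keep_set = set(keep)
        idx = [j for j, nm in enumerate(self.names) if nm in keep_set]
        if not idx:
            raise ValueError("subset would drop every predictor")
        return Dataset(self.y, self.X[:, idx], tuple(self.names[j] for j in idx))


@dataclass(frozen=True)
class OscillationOrders:
    """Per-predictor cosine-harmonic counts ``K_1..K_p`` (all >= 0)."""

    K: tuple[int, ...]

    def __post_init__(self) -> None:
        K = tuple(int(k) for k in np.atleast_1d(np.asarray(self.K)).tolist())
        if any(k < 0 for k in K):
            raise ValueError("oscillation orders must be non-negative")
        object.__setattr__(self, "K", K)

    @property
    def p(self) -> int:
        return len(self.K)

    @property
    def total(self) -> int:
        return sum(self.K)

    @property
    def n_params(self) -> int:
        """Flat parameter count m = 1 + p + sum(K)."""
        return 1 + self.p + self.total


def _orders(K) -> OscillationOrders:
    return K if isinstance(K, OscillationOrders) else OscillationOrders(tuple(K))


class ParameterVector:
    """The model coefficients with a stable flat layout.

    Flat order mirrors the design matrix: ``[a0, b_1, a_{1,1}..a_{K1,1},
    b_2, a_{1,2}.., ..., b_p, ...]``.  ``index_map`` maps component labels
    (``"a0"``, ``"b1"``, ``"a2,1"`` ...) to positions in the flat vector.
    """

    def __init__(self, a0: float, b: Sequence[float], a: Sequence[Sequence[float]]):
        self.a0 = float(a0)
        self.b = np.asarray(b, dtype=float).reshape(-1)
        self.a = [np.asarray(aj, dtype=float).reshape(-1) for aj in a]
        if len(self.a) != self.b.shape[0]:
            raise ValueError("need one harmonic-coefficient block per predictor")

    @property
    def orders(self) -> OscillationOrders:
        return OscillationOrders(tuple(aj.shape[0] for aj in self.a))

    @property
    def p(self) -> int:
        return self.b.shape[0]

    @property
    def m(self) -> int:
        return 1 + self.p + sum(aj.shape[0] for aj in self.a)

    @property
    def index_map(self) -> dict[str, int]:
        mapping = {"a0": 0}
        pos = 1
        for j, aj in enumerate(self.a, start=1):
            mapping[f"b{j}"] = pos
            pos += 1
            for k in range(1, aj.shape[0] + 1):
                mapping[f"a{k},{j}"] = pos
                pos += 1
        return mapping

    def flatten(self) -> np.ndarray:
        out = np.empty(self.m)
        out[0] = self.a0
        pos = 1
        for j in range(self.p):
            out[pos] = self.b[j]
            pos += 1
            kj = self.a[j].shape[0]
            out[pos : pos + kj] = self.a[j]
            pos += kj
        return out

    @classmethod
    def unflatten(cls, flat: np.ndarray, K) -> "ParameterVector":
        K = _orders(K)
        flat = np.asarray(flat, dtype=float).reshape(-1)
        if flat.shape[0] != K.n_params:
            raise ValueError(
                f"flat vector has length {flat.shape[0]}, expected {K.n_params}"
            )
        a0 = flat[0]
        b, a = [], []
        pos = 1
        for kj in K.K:
            b.append(flat[pos])
            pos += 1
            a.append(flat[pos : pos + kj])
            pos += kj
        return cls(a0, b, a)

    @classmethod
    def zeros(cls, K) -> "ParameterVector":
        K = _orders(K)
        return cls.unflatten(np.zeros(K.n_params), K)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParameterVector(a0={self.a0:.4g}, K={self.orders.K})"


@dataclass(frozen=True)
class DesignMatrix:
    """The regressor matrix ``[1 | x_j | cos(k x_j) ...]`` with labels.

    ``cosine_scale`` records, per predictor, the affine map applied to the
    cosine argument (``(offset, rate)`` so the argument is
    ``rate * (x - offset)``); identity when no rescaling was requested.
    """

    columns: np.ndarray
    labels: tuple[str, ...]
    orders: OscillationOrders
    cosine_scale: tuple[tuple[float, float], ...] = ()

    @property
    def n(self) -> int:
        return self.columns.shape[0]

    @property
    def m(self) -> int:
        return self.columns.shape[1]


def build_design(X: np.ndarray, K, names: Sequence[str] | None = None,
                 rescale_cosine: bool = False) -> DesignMatrix:
    """Construct the FSNBLR design matrix.

    Columns are ``[1 | x_1 | cos(1*x_1)..cos(K_1*x_1) | ... | x_p | ...]``.
    With ``rescale_cosine`` each predictor is min-max mapped to ``[0, pi]``
    *inside the cosine only* (the linear term keeps raw units); by default
    the cosine acts on raw values, which is what published coefficient sets
    for this model assume.
    """
    K = _orders(K)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != K.p:
        raise ValueError(f"X has {X.shape[1]} predictors but K has {K.p} entries")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    names = tuple(names) if names else tuple(f"x{j + 1}" for j in range(K.p))

    n = X.shape[0]
    cols = [np.ones(n)]
    labels = ["(intercept)"]
    scales: list[tuple[float, float]] = []
    for j in range(K.p):
        xj = X[:, j]
        cols.append(xj)
        labels.append(f"b_{j + 1}:{names[j]}")
        if rescale_cosine:
            lo, hi = float(xj.min()), float(xj.max())
            rate = np.pi / (hi - lo) if hi > lo else 0.0
            scales.append((lo, rate))
            arg = rate * (xj - lo)
        else:
            scales.append((0.0, 1.0))
            arg = xj
        for k in range(1, K.K[j] + 1):
            cols.append(np.cos(k * arg))
            labels.append(f"a_{k},{j + 1}:{names[j]}")
    return DesignMatrix(np.column_stack(cols), tuple(labels), K, tuple(scales))


@dataclass(frozen=True)
class ConvergenceOptions:
    """Newton-Raphson controls.

    ``epsilon`` is the max-abs parameter-change stopping tolerance;
    ``grad_tol`` additionally requires first-order optimality so a declared
    optimum really is one.  ``ridge`` scales a transient diagonal boost used
    only when the Hessian solve fails mid-iteration.
    """

    epsilon: float = 1e-6
    max_iter: int = 100
    ridge: float = 1e-8
    step_halving: bool = True
    grad_tol: float = 1e-6
    max_halvings: int = 30

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


def _flat_theta(theta, design: DesignMatrix) -> np.ndarray:
    flat = theta.flatten() if isinstance(theta, ParameterVector) else np.asarray(theta, dtype=float).reshape(-1)
    if flat.shape[0] != design.m:
        raise ValueError(
            f"theta has {flat.shape[0]} components but design has {design.m} columns"
        )
    return flat


def linear_predictor(design: DesignMatrix, theta) -> np.ndarray:
    """eta = design @ theta (unclipped)."""
    return design.columns @ _flat_theta(theta, design)


def predict_prob(design: DesignMatrix, theta) -> np.ndarray:
    """Success probabilities ``pi = expit(eta)``, kept strictly in (0, 1)."""
    eta = np.clip(linear_predictor(design, theta), -ETA_CLIP, ETA_CLIP)
    return np.clip(expit(eta), _PROB_EPS, 1.0 - _PROB_EPS)


def _check_y(y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.shape[0] != design.n:
        raise ValueError(f"y has {y.shape[0]} rows but design has {design.n}")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    return y


def log_likelihood(y: np.ndarray, design: DesignMatrix, theta) -> float:
    """Bernoulli log-likelihood ``sum_i [y_i eta_i - ln(1 + exp(eta_i))]``."""
    y = _check_y(y, design)
    eta = np.clip(linear_predictor(design, theta), -ETA_CLIP, ETA_CLIP)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def gradient(y: np.ndarray, design: DesignMatrix, theta) -> np.ndarray:
    """Score vector ``design.T @ (y - pi)``."""
    y = _check_y(y, design)
    pi = predict_prob(design, theta)
    return design.columns.T @ (y - pi)


def hessian(y: np.ndarray, design: DesignMatrix, theta) -> np.ndarray:
    """Observed Hessian ``-design.T @ diag(pi (1-pi)) @ design``.

    Returned exactly symmetric (explicitly symmetrized) and negative
    semidefinite.
    """
    _check_y(y, design)
    pi = predict_prob(design, theta)
    w = pi * (1.0 - pi)
    B = design.columns * np.sqrt(w)[:, None]
    A = B.T @ B
    A = 0.5 * (A + A.T)
    return -A
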