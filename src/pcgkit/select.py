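"""Regularized neighborhood component analysis (NCA) feature weighting and
the fixed 15-feature reduction preset.

NCA learns one non-negative weight per feature by maximizing a stochastic
(softmax-neighbor) leave-one-out classification objective with an L2
penalty. The free parameters u_k enter the distance squared, which keeps
the effective weights w_k = u_k^2 non-negative without constraints:

    d_ij = sum_k u_k^2 (x_ik - x_jk)^2,

the soft neighbor assignment p_ij = softmax_j(-d_ij), and the objective

    F(u) = (1/n) sum_i sum_{j in class(i)} p_ij  -  lambda sum_k u_k^2.

The L2 penalty acts on the parameters u, so for lambda large enough the
all-zero weight vector is a genuine optimum and irrelevant features are
driven exactly to zero. Reported weights are w_k = u_k^2.

Default lambda is 1/n. Optimization is L-BFGS with the analytic gradient;
the default all-ones initialization makes the fit deterministic and exactly
equivariant under feature permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .features import FEATURE_NAMES, FeatureVector

#: The reduced feature preset: kurtosis, peak frequency, and all 13 MFCCs.
REDUCED_FEATURE_NAMES = ("kurtosis", "f_max") + tuple(f"mfcc_{i}" for i in range(1, 14))


@dataclass
class FeatureWeights:
    names: tuple
    weights: np.ndarray
    lam: float
    objective_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.weights.size != len(self.names):
            raise ValueError("one weight per feature required")


def nca_objective(u: np.ndarray, X: np.ndarray, y: np.ndarray,
                  lam: float) -> tuple:
    """Regularized NCA leave-one-out objective and its analytic gradient
    with respect to the square-root parameters ``u`` (weights = u**2).

    Returns ``(F, dF/du)``; both are for the maximization problem.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    u = np.asarray(u, float)
    # squared per-feature differences, (n, n, p)
    diff = X[:, None, :] - X[None, :, :]
    D = diff ** 2
    d = D @ (u ** 2)  # (n, n) weighted distances
    np.fill_diagonal(d, np.inf)
    # softmax over j != i, stabilized per row
    dmin = np.min(d, axis=1, keepdims=True)
    E = np.exp(-(d - dmin))
    E[~np.isfinite(E)] = 0.0
    np.fill_diagonal(E, 0.0)
    row = E.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    P = E / row
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    p_i = (P * same).sum(axis=1)
    F = p_i.mean() - lam * np.sum(u ** 2)

    A = np.einsum("ij,ijk->ik", P, D)
    B = np.einsum("ij,ijk->ik", P * same, D)
    grad_u = 2.0 * u * (p_i[:, None] * A - B).sum(axis=0) / n - 2.0 * lam * u
    return float(F), grad_u


def nca_fit(X, y, lam: float | None = None, max_iter: int = 200,
            tol: float = 1e-6, seed: int = 0,
            init: str = "ones") -> FeatureWeights:
    """Fit NCA feature weights on a standardized feature matrix.

    Parameters
    ----------
    X : (n, p) array, standardized (z-scores per feature).
    y : (n,) labels, at least two classes.
    lam : L2 regularization strength; default 1/n.
    init : "ones" (deterministic, default) or "random" (seeded).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("NCA requires at least two classes")
    sd = X.std(axis=0)
    if np.any(sd > 10.0) or np.any((sd > 0) & (sd < 0.1)):
        warnings.warn("feature columns deviate strongly from unit scale; "
                      "standardize before NCA")
    n, p = X.shape
    lam = 1.0 / n if lam is None else float(lam)
    if init == "random":
        rng = np.random.default_rng(seed)
        u0 = 1.0 + 0.01 * rng.standard_normal(p)
    else:
        u0 = np.ones(p)
    trace: list = []

    def neg(uv):
        F, g = nca_objective(uv, X, y, lam)
        return -F, -g

    res = minimize(neg, u0, jac=True, method="L-BFGS-B",
                   callback=lambda uv: trace.append(nca_objective(uv, X, y, lam)[0]),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
    u = res.x
    names = tuple(FEATURE_NAMES[:p]) if p <= len(FEATURE_NAMES) else tuple(
        f"x{i}" for i in range(p))
    return FeatureWeights(names, u ** 2, lam, trace)


def threshold_selection(weights: FeatureWeights, rel_threshold: float = 0.1) -> list:
    """Feature names with weight >= rel_threshold * max weight."""
    wmax = np.max(weights.weights)
    if wmax == 0:
        warnings.warn("all NCA weights are zero; empty selection")
        return []
    keep = weights.weights >= rel_threshold * wmax
    return [n for n, k in zip(weights.names, keep) if k]


def reduce_features(vectors, selection=REDUCED_FEATURE_NAMES):
    """Subset feature columns by name, preserving canonical order.

    Accepts a single :class:`FeatureVector`, a list of them, or a pandas
    DataFrame with feature-named columns.
    """
    selection = list(selection)
    if not selection:
        raise ValueError("empty feature selection")

    def _ordered(names):
        unknown = [s for s in selection if s not in names]
        if unknown:
            raise KeyError(f"unknown feature names: {unknown}")
        return [nm for nm in names if nm in selection]

    if isinstance(vectors, FeatureVector):
        keep = _ordered(vectors.names)
        idx = [vectors.names.index(nm) for nm in keep]
        return FeatureVector(vectors.values[idx], tuple(keep))
    if isinstance(vectors, (list, tuple)):
        return [reduce_features(v, selection) for v in vectors]
    # assume DataFrame-like
    cols = [c for c in vectors.columns if c in FEATURE_NAMES]
    keep = _ordered(cols)
    other = [c for c in vectors.columns if c not in FEATURE_NAMES]
    return vectors[other + keep]
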