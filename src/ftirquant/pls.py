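"""PLS1 regression, cross-validation and calibration metrics.

The regression engine is PLS1 with NIPALS deflation on mean-centered X
and y (no variance scaling — derivative spectra carry meaningful relative
magnitudes).  The regression coefficient vector b is exposed in centered
coordinates so that a prediction is ``(x - x_mean) @ b + y_mean``; the
wavelength-selection algorithms consume b directly.

Metrics follow the usual chemometric definitions: RMSE is
``sqrt(mean((y_real - y_pre)^2))`` (RMSECV / RMSEC / RMSEP depending on
which predictions enter), and R^2 defaults to ``1 - SSE/SST`` with a
squared-Pearson alternative selectable by config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .datatypes import SpectraSet

__all__ = [
    "PLSModel",
    "CVResult",
    "EvaluationReport",
    "rmse",
    "r_squared",
    "fit_pls",
    "coefficient_path",
    "cross_validate",
    "evaluate",
]

CVScheme = Literal["loo"] | int  # "loo" or the k of k-fold


def rmse(y_real: Sequence[float], y_pre: Sequence[float]) -> float:
    """Root-mean-square error in the units of y (% w/w here)."""
    y_real = np.asarray(y_real, dtype=float)
    y_pre = np.asarray(y_pre, dtype=float)
    if y_real.shape != y_pre.shape:
        raise ValueError(f"length mismatch: {y_real.shape} vs {y_pre.shape}")
    if y_real.size == 0:
        raise ValueError("rmse of empty sequences is undefined")
    return float(np.sqrt(np.mean((y_real - y_pre) ** 2)))


def r_squared(
    y_real: Sequence[float],
    y_pre: Sequence[float],
    definition: Literal["one_minus_sse_sst", "squared_pearson"] = "one_minus_sse_sst",
) -> float:
    y_real = np.asarray(y_real, dtype=float)
    y_pre = np.asarray(y_pre, dtype=float)
    if y_real.size < 2 or y_real.shape != y_pre.shape:
        raise ValueError("r_squared needs >= 2 paired values")
    sst = float(np.sum((y_real - y_real.mean()) ** 2))
    if sst == 0:
        raise ValueError("y_real is constant; R^2 undefined")
    if definition == "one_minus_sse_sst":
        return 1.0 - float(np.sum((y_real - y_pre) ** 2)) / sst
    if definition == "squared_pearson":
        return float(np.corrcoef(y_real, y_pre)[0, 1] ** 2)
    raise ValueError(f"unknown R^2 definition {definition!r}")


@dataclass
class PLSModel:
    """A fitted PLS1 model restricted to ``included_variables``."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x nLVs
    loadings: np.ndarray  # p x nLVs
    b: np.ndarray  # regression coefficients over included variables
    nlvs: int
    included_variables: np.ndarray  # indices into the full wavenumber axis

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == self.included_variables.size:
            Xv = X
        else:
            Xv = X[:, self.included_variables]
        return (Xv - self.x_mean) @ self.b + self.y_mean


@dataclass
class CVResult:
    scheme: str
    rmsecv_by_nlv: np.ndarray
    chosen_nlvs: int
    r2: float  # cross-validated R^2 at chosen_nlvs

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_by_nlv[self.chosen_nlvs - 1])


@dataclass
class EvaluationReport:
    rmsec: float
    rmsep: float
    r2_cal: float
    r2_test: float
    pairs_calibration: tuple[np.ndarray, np.ndarray]  # (actual, predicted)
    pairs_test: tuple[np.ndarray, np.ndarray]


def _pls1_decompose(Xc: np.ndarray, yc: np.ndarray, nlvs: int):
    """NIPALS deflation for a single response; returns W, P, q.

    If the residual matrix runs out of rank before ``nlvs`` components the
    decomposition stops early (fewer columns come back).
    """
    n, p = Xc.shape
    W = np.empty((p, nlvs))
    P = np.empty((p, nlvs))
    q = np.empty(nlvs)
    X = Xc.copy()
    y = yc.copy()
    k = 0
    for _ in range(nlvs):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-13:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-13:
            break
        P[:, k] = X.T @ t / tt
        q[k] = float(y @ t) / tt
        W[:, k] = w
        X -= np.outer(t, P[:, k])
        y -= q[k] * t
        k += 1
    return W[:, :k], P[:, :k], q[:k]


def coefficient_path(X: np.ndarray, y: np.ndarray, max_nlvs: int) -> tuple[np.ndarray, float, np.ndarray]:
    """Regression coefficients for every 1..max_nlvs in one pass.

    Returns ``(B, y_mean, x_mean)`` where column k-1 of the p x max_nlvs
    matrix B is the coefficient vector of the k-component model.  When X
    runs out of rank, later columns repeat the last attainable model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _pls1_decompose(X - x_mean, y - y_mean, max_nlvs)
    p_vars = X.shape[1]
    B = np.zeros((p_vars, max_nlvs))
    k_avail = W.shape[1]
    for k in range(1, k_avail + 1):
        R = np.linalg.solve(P[:, :k].T @ W[:, :k], np.eye(k))
        B[:, k - 1] = W[:, :k] @ (R @ q[:k])
    for k in range(k_avail, max_nlvs):  # rank exhausted: carry the last model
        B[:, k] = B[:, k_avail - 1] if k_avail else 0.0
    return B, y_mean, x_mean


def fit_pls(
    X: np.ndarray,
    y: Sequence[float],
    nlvs: int,
    included_variables: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``nlvs`` latent variables.

    ``included_variables`` restricts the model to a wavenumber index set
    (the interface the selection algorithms use); X is then indexed
    before fitting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if included_variables is None:
        included_variables = np.arange(X.shape[1])
    else:
        included_variables = np.asarray(included_variables, dtype=int)
        X = X[:, included_variables]
    n, p = X.shape
    if not 1 <= nlvs <= min(n - 1, p):
        raise ValueError(f"nlvs={nlvs} out of range for {n} samples x {p} variables")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _pls1_decompose(X - x_mean, y - y_mean, nlvs)
    k = W.shape[1]
    if k == 0:
        raise ValueError("X has no covariance with y; cannot fit any component")
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        b=b,
        nlvs=k,
        included_variables=included_variables,
    )


def _stratified_fold_assignment(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous-block folds after a seeded stratified shuffle.

    Samples are grouped by y value, shuffled within groups, interleaved
    round-robin across groups, and the resulting order is cut into k
    near-equal contiguous blocks — each fold then spans the y range.
    """
    order: list[int] = []
    groups = [np.flatnonzero(y == v) for v in np.unique(y)]
    shuffled = [rng.permutation(g) for g in groups]
    longest = max(len(g) for g in shuffled)
    for i in range(longest):
        for g in shuffled:
            if i < len(g):
                order.append(int(g[i]))
    folds = np.empty(y.size, dtype=int)
    bounds = np.linspace(0, y.size, k + 1).astype(int)
    for f in range(k):
        folds[order[bounds[f] : bounds[f + 1]]] = f
    return folds


def cross_validate(
    X: np.ndarray,
    y: Sequence[float],
    max_nlvs: int,
    scheme: CVScheme = "loo",
    seed: int = 0,
) -> CVResult:
    """RMSECV as a function of the number of latent variables.

    Held-out predictions are assembled over all folds for every
    1..max_nlvs, scored by RMSE, and the component count minimizing
    RMSECV is chosen (ties break toward fewer latent variables).
    LOO is deterministic; k-fold folds come from a seeded stratified
    shuffle followed by contiguous blocks.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if scheme == "loo":
        k = n
        folds = np.arange(n)
        name = "leave_one_out"
    else:
        k = int(scheme)
        if not 2 <= k <= n:
            raise ValueError(f"k-fold k={k} infeasible for {n} samples")
        folds = _stratified_fold_assignment(y, k, np.random.default_rng(seed))
        name = f"{k}-fold"
    smallest_train = min(int(np.sum(folds != f)) for f in range(k))
    if max_nlvs > min(smallest_train - 1, p):
        raise ValueError(
            f"max_nlvs={max_nlvs} infeasible: smallest training fold has "
            f"{smallest_train} samples and {p} variables"
        )
    preds = np.empty((n, max_nlvs))
    for f in range(k):
        test = folds == f
        B, y_mean, x_mean = coefficient_path(X[~test], y[~test], max_nlvs)
        preds[test] = (X[test] - x_mean) @ B + y_mean
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmin(rmsecv)) + 1
    r2cv = 1.0 - float(np.sum((y - preds[:, chosen - 1]) ** 2)) / float(
        np.sum((y - y.mean()) ** 2)
    )
    return CVResult(scheme=name, rmsecv_by_nlv=rmsecv, chosen_nlvs=chosen, r2=r2cv)


def evaluate(model: PLSModel, preprocessor, calibration: SpectraSet, test: SpectraSet) -> EvaluationReport:
    """Score a fitted model on calibration (RMSEC) and test (RMSEP) sets.

    ``preprocessor`` is the pretreatment chain fitted on calibration
    spectra; both sets pass through it before prediction.
    """
    if test.n_samples == 0:
        raise ValueError("empty test set")
    Xc = preprocessor.transform(calibration.absorbance)
    Xt = preprocessor.transform(test.absorbance)
    yc_hat = model.predict(Xc)
    yt_hat = model.predict(Xt)
    return EvaluationReport(
        rmsec=rmse(calibration.labels, yc_hat),
        rmsep=rmse(test.labels, yt_hat),
        r2_cal=r_squared(calibration.labels, yc_hat),
        r2_test=r_squared(test.labels, yt_hat),
        pairs_calibration=(calibration.labels.copy(), yc_hat),
        pairs_test=(test.labels.copy(), yt_hat),
    )
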