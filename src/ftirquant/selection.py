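"""Wavelength selection: moving-window PLS, MC-UVE and interval random frog.

All three methods score candidate variable sets by the cross-validated
RMSE of a PLS model restricted to those variables, and all three operate
on the regression coefficient vector b one way or another:

* **MW-PLS** scans every contiguous window of each requested width and
  keeps the window with the lowest RMSECV.
* **MC-UVE** refits PLS on many Monte-Carlo subsamples of the calibration
  set and computes a per-wavenumber stability ``S_j = mean(b_j)/std(b_j)``
  over the runs; low-|S| (uninformative) variables are cut.
* **interval random frog (iRF)** runs a stochastic reversible-jump-style
  search over subsets of fixed-width spectral intervals; each interval's
  selection probability is the fraction of iterations whose accepted
  subset contains it, and the final variable set is the RMSECV-minimizing
  union of the top-probability intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pls import CVScheme, coefficient_path, cross_validate, fit_pls

__all__ = [
    "WindowResult",
    "MCUVEConfig",
    "StabilityProfile",
    "IRFConfig",
    "IntervalProbabilities",
    "mw_pls",
    "mc_uve",
    "uve_cutoff",
    "enumerate_intervals",
    "interval_random_frog",
    "select_intervals_by_probability",
]


def _cap_nlvs(requested: int, n_samples: int, n_vars: int, scheme: CVScheme) -> int:
    if scheme == "loo":
        smallest_train = n_samples - 1
    else:
        smallest_train = n_samples - int(np.ceil(n_samples / int(scheme)))
    return max(1, min(requested, smallest_train - 1, n_vars))


# ------------------------------------------------------------------ MW-PLS


@dataclass
class WindowResult:
    """RMSECV landscape of a moving-window scan."""

    widths: np.ndarray  # per-window width
    starts: np.ndarray  # per-window start index
    rmsecv_per_window: np.ndarray
    nlvs_per_window: np.ndarray
    best_window: tuple[int, int]  # [start, stop) into the axis
    best_rmsecv: float
    best_nlvs: int

    @property
    def selected_variables(self) -> np.ndarray:
        return np.arange(*self.best_window)


def mw_pls(
    X: np.ndarray,
    y: Sequence[float],
    widths: Sequence[int],
    scheme: CVScheme = 5,
    max_nlvs: int = 10,
    stride: int = 1,
    seed: int = 0,
) -> WindowResult:
    """Exhaustive moving-window PLS scan.

    For every width and every window start (windows fully inside the
    axis) a PLS model restricted to the window is cross-validated; the
    window with the lowest RMSECV wins, ties breaking toward the narrower
    width and then the lower start index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    for w in widths:
        if w < 2 or w > p:
            raise ValueError(f"window width {w} out of range [2, {p}]")
    rec_w, rec_s, rec_r, rec_l = [], [], [], []
    best = None  # (rmsecv, width, start, nlvs)
    for w in widths:
        nlv = _cap_nlvs(max_nlvs, n, w, scheme)
        for s in range(0, p - w + 1, stride):
            cv = cross_validate(X[:, s : s + w], y, nlv, scheme, seed=seed)
            rec_w.append(w)
            rec_s.append(s)
            rec_r.append(cv.rmsecv)
            rec_l.append(cv.chosen_nlvs)
            key = (cv.rmsecv, w, s)
            if best is None or key < (best[0], best[1], best[2]):
                best = (cv.rmsecv, w, s, cv.chosen_nlvs)
    assert best is not None
    return WindowResult(
        widths=np.asarray(rec_w),
        starts=np.asarray(rec_s),
        rmsecv_per_window=np.asarray(rec_r),
        nlvs_per_window=np.asarray(rec_l),
        best_window=(best[2], best[2] + best[1]),
        best_rmsecv=best[0],
        best_nlvs=best[3],
    )


# ------------------------------------------------------------------ MC-UVE


@dataclass(frozen=True)
class MCUVEConfig:
    M: int = 500  # Monte-Carlo runs
    sampling_fraction: float = 0.8
    nlvs: int = 10
    cutoff_rule: str = "noise_augmented"  # or "quantile_scan"
    scheme: CVScheme = 5  # CV used when a cutoff rule needs model scores
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("MC-UVE needs at least 2 Monte-Carlo runs")
        if not 0.0 < self.sampling_fraction < 1.0:
            raise ValueError("sampling_fraction must lie in (0, 1)")
        if self.cutoff_rule not in ("noise_augmented", "quantile_scan"):
            raise ValueError(f"unknown cutoff rule {self.cutoff_rule!r}")


@dataclass
class StabilityProfile:
    """Per-wavenumber MC-UVE stability with the applied cut-off."""

    s: np.ndarray  # S_j = mean(b_j)/std(b_j); +-inf where std was zero
    cutoff: float
    selected: np.ndarray  # indices with |S| >= cutoff
    flagged: np.ndarray  # boolean: zero-std sentinels
    noise_s: np.ndarray | None = None  # stabilities of augmentation channels


def _stability_from_runs(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """S_j = mean/std (sample sd) per column of the M x p coefficient matrix."""
    mean = B.mean(axis=0)
    std = B.std(axis=0, ddof=1)
    flagged = std == 0
    s = np.empty(B.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        s[~flagged] = mean[~flagged] / std[~flagged]
    s[flagged] = np.where(mean[flagged] >= 0, np.inf, -np.inf)
    return s, flagged


def _mc_coefficient_runs(
    X: np.ndarray, y: np.ndarray, cfg: MCUVEConfig, rng: np.random.Generator
) -> np.ndarray:
    n, p = X.shape
    n_sub = int(round(cfg.sampling_fraction * n))
    if n_sub < cfg.nlvs + 1:
        raise ValueError(
            f"subsample of {n_sub} cannot support {cfg.nlvs} latent variables"
        )
    nlv = min(cfg.nlvs, n_sub - 1, p)
    B = np.empty((cfg.M, p))
    for m in range(cfg.M):
        idx = rng.choice(n, size=n_sub, replace=False)
        path, _, _ = coefficient_path(X[idx], y[idx], nlv)
        B[m] = path[:, nlv - 1]
    return B


def uve_cutoff(
    s: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    rule: str,
    seed: int = 0,
    noise_s: np.ndarray | None = None,
    nlvs: int = 10,
    scheme: CVScheme = 5,
) -> float:
    """Stability threshold under one of the two cut-off rules.

    ``noise_augmented``: the largest |S| among artificial noise channels
    (the null distribution of an uninformative variable).
    ``quantile_scan``: scan |S| quantiles {50, 60, 70, 80, 90, 95}% plus
    the keep-everything baseline (cutoff 0) and keep the cutoff whose
    surviving variable set minimizes RMSECV — by construction the chosen
    set is never worse than no elimination under the scanning CV.
    """
    abs_s = np.abs(np.asarray(s, dtype=float))
    if rule == "noise_augmented":
        if noise_s is None:
            raise ValueError("noise_augmented rule needs the noise-channel stabilities")
        finite = np.abs(noise_s[np.isfinite(noise_s)])
        return float(finite.max()) if finite.size else float("inf")
    if rule != "quantile_scan":
        raise ValueError(f"unknown cutoff rule {rule!r}")
    finite = abs_s[np.isfinite(abs_s)]
    best_cut, best_rmsecv = 0.0, np.inf
    n = X.shape[0]
    for cut in (0.0, *(float(np.percentile(finite, qt)) for qt in (50, 60, 70, 80, 90, 95))):
        keep = np.flatnonzero(abs_s >= cut)
        if keep.size == 0:
            continue
        nlv = _cap_nlvs(nlvs, n, keep.size, scheme)
        cv = cross_validate(X[:, keep], y, nlv, scheme, seed=seed)
        if cv.rmsecv < best_rmsecv:
            best_rmsecv, best_cut = cv.rmsecv, cut
    return best_cut


def mc_uve(X: np.ndarray, y: Sequence[float], cfg: MCUVEConfig) -> StabilityProfile:
    """Monte-Carlo uninformative variable elimination.

    M subsampled PLS fits yield the per-wavenumber stability
    ``S_j = mean(b_j)/std(b_j)``; variables whose |S_j| falls below the
    cut-off are eliminated.  Zero-std channels get signed infinite S and
    are flagged rather than dropped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    p = X.shape[1]
    noise_s = None
    if cfg.cutoff_rule == "noise_augmented":
        # tiny-amplitude random channels: a null sample of uninformative b_j
        noise = rng.standard_normal((X.shape[0], p)) * (1e-10 * max(X.std(), 1e-30))
        B = _mc_coefficient_runs(np.hstack([X, noise]), y, cfg, rng)
        s_all, flagged_all = _stability_from_runs(B)
        s, flagged = s_all[:p], flagged_all[:p]
        noise_s = s_all[p:]
    else:
        B = _mc_coefficient_runs(X, y, cfg, rng)
        s, flagged = _stability_from_runs(B)
    cutoff = uve_cutoff(
        s, X, y, cfg.cutoff_rule, seed=cfg.seed, noise_s=noise_s,
        nlvs=cfg.nlvs, scheme=cfg.scheme,
    )
    selected = np.flatnonzero(np.abs(s) >= cutoff)
    return StabilityProfile(s=s, cutoff=cutoff, selected=selected, flagged=flagged, noise_s=noise_s)


# --------------------------------------------------------------------- iRF


@dataclass(frozen=True)
class IRFConfig:
    interval_width: int = 20
    N: int = 1000  # search iterations
    Q0: int = 10  # initial interval count
    proposal_sd_factor: float = 0.3
    downhill_accept_prob: float = 0.1
    nlvs_cap: int = 10
    scheme: CVScheme = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_width < 2:
            raise ValueError("interval_width must be >= 2")
        if self.N < 10:
            raise ValueError("iRF needs at least 10 iterations")
        if not 0.0 < self.downhill_accept_prob < 1.0:
            raise ValueError("downhill_accept_prob must lie in (0, 1)")
        if self.proposal_sd_factor <= 0:
            raise ValueError("proposal_sd_factor must be positive")


@dataclass
class IntervalProbabilities:
    """Per-interval iRF selection probabilities N_j/N."""

    intervals: list[tuple[int, int]]  # [start, stop) index ranges
    n_j: np.ndarray  # integer acceptance counts
    n_iterations: int
    truncated: np.ndarray  # boolean: edge intervals narrower than the width

    @property
    def probability(self) -> np.ndarray:
        return self.n_j / self.n_iterations

    @property
    def ranked(self) -> np.ndarray:
        """Interval indices sorted by probability descending, ties by start."""
        starts = np.array([iv[0] for iv in self.intervals])
        return np.lexsort((starts, -self.probability))


def enumerate_intervals(p: int, width: int) -> tuple[list[tuple[int, int]], np.ndarray]:
    """One centered interval per spectral point, truncated at the edges.

    Interval j covers ``[j - width//2, j + ceil(width/2))`` clipped to the
    axis, so the interval count equals the number of points; clipped edge
    intervals are narrower than ``width`` and flagged as truncated.
    """
    if width > p:
        raise ValueError(f"interval width {width} exceeds {p} spectral points")
    half_lo = width // 2
    half_hi = width - half_lo
    intervals, truncated = [], []
    for j in range(p):
        lo, hi = max(0, j - half_lo), min(p, j + half_hi)
        intervals.append((lo, hi))
        truncated.append(hi - lo < width)
    return intervals, np.asarray(truncated)


def _interval_union(intervals: list[tuple[int, int]], members: np.ndarray) -> np.ndarray:
    mask_parts = [np.arange(*intervals[int(i)]) for i in members]
    return np.unique(np.concatenate(mask_parts))


def _subset_rmsecv(
    X: np.ndarray, y: np.ndarray, var_idx: np.ndarray, cfg: IRFConfig
) -> float:
    nlv = _cap_nlvs(cfg.nlvs_cap, X.shape[0], var_idx.size, cfg.scheme)
    return cross_validate(X[:, var_idx], y, nlv, cfg.scheme, seed=cfg.seed).rmsecv


def _rank_intervals(
    X: np.ndarray, y: np.ndarray, intervals: list[tuple[int, int]],
    members: np.ndarray, cfg: IRFConfig,
) -> np.ndarray:
    """Members sorted by PLS-coefficient importance (mean |b| per interval)."""
    union = _interval_union(intervals, members)
    nlv = _cap_nlvs(cfg.nlvs_cap, X.shape[0], union.size, cfg.scheme)
    model = fit_pls(X, y, nlv, included_variables=union)
    b_abs = np.zeros(X.shape[1])
    b_abs[union] = np.abs(model.b)
    scores = np.array([b_abs[slice(*intervals[int(i)])].mean() for i in members])
    order = np.lexsort((members, -scores))  # ties toward lower interval index
    return members[order]


def interval_random_frog(
    X: np.ndarray, y: Sequence[float], cfg: IRFConfig
) -> IntervalProbabilities:
    """Stochastic search over interval subsets.

    Starting from Q0 random intervals, each iteration proposes a subset
    whose size is drawn around the current size; the proposal keeps the
    best-ranked intervals (by PLS coefficient magnitude) from the union
    of the current subset and fresh random candidates.  A proposal with
    lower cross-validated RMSE is always accepted, a worse one with
    probability ``downhill_accept_prob * (RMSECV_current/RMSECV_candidate)``.
    N_j counts the iterations whose accepted subset contains interval j.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    intervals, truncated = enumerate_intervals(p, cfg.interval_width)
    n_int = len(intervals)
    rng = np.random.default_rng(cfg.seed)
    current = rng.choice(n_int, size=min(cfg.Q0, n_int), replace=False)
    rmsecv_cur = _subset_rmsecv(X, y, _interval_union(intervals, current), cfg)
    counts = np.zeros(n_int, dtype=np.int64)
    for _ in range(cfg.N):
        q = current.size
        q_star = int(np.clip(round(rng.normal(q, cfg.proposal_sd_factor * q)), 1, n_int))
        n_new = max(q_star - q, 1)
        outside = np.setdiff1d(np.arange(n_int), current, assume_unique=False)
        extras = rng.choice(outside, size=min(n_new, outside.size), replace=False)
        pool = np.concatenate([current, extras])
        ranked = _rank_intervals(X, y, intervals, pool, cfg)
        candidate = np.sort(ranked[:q_star])
        rmsecv_cand = _subset_rmsecv(X, y, _interval_union(intervals, candidate), cfg)
        if rmsecv_cand < rmsecv_cur or rng.random() < cfg.downhill_accept_prob * (
            rmsecv_cur / rmsecv_cand
        ):
            current, rmsecv_cur = candidate, rmsecv_cand
        counts[current] += 1
    return IntervalProbabilities(
        intervals=intervals, n_j=counts, n_iterations=cfg.N, truncated=truncated
    )


def select_intervals_by_probability(
    ip: IntervalProbabilities,
    X: np.ndarray,
    y: Sequence[float],
    scheme: CVScheme = 5,
    max_nlvs: int = 10,
    k_max: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Final iRF variable set: the RMSECV-minimizing union of top intervals.

    Intervals are ranked by selection probability (ties toward the lower
    start index); for k = 1..k_max the union of the top-k intervals is
    cross-validated and the best union wins, ties breaking to smaller k.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    prob = ip.probability
    if not np.any(prob > 0):
        raise ValueError("all interval probabilities are zero; increase iRF iterations N")
    ranked = [int(i) for i in ip.ranked if prob[int(i)] > 0]
    best_vars, best_rmsecv = None, np.inf
    for k in range(1, min(k_max, len(ranked)) + 1):
        union = _interval_union(ip.intervals, np.asarray(ranked[:k]))
        nlv = _cap_nlvs(max_nlvs, X.shape[0], union.size, scheme)
        cv = cross_validate(X[:, union], y, nlv, scheme, seed=seed)
        if cv.rmsecv < best_rmsecv:
            best_rmsecv, best_vars = cv.rmsecv, union
    assert best_vars is not None
    return best_vars
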