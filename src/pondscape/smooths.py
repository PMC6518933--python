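"""Penalized-spline smooths and the habitat-number vs habitat-area contest.

For every accumulation run we fit an additive model
richness ~ s(number of sites) + s(cumulative area), each smooth a cubic
B-spline basis (k functions) with a second-difference coefficient penalty,
smoothing parameters chosen by GCV. A predictor's importance is the
drop-one loss in explained deviance (full model minus the model without
that smooth, each with its own GCV-selected smoothing); the predictor with
the larger importance wins the run. Within a run site count and cumulative
area are strongly collinear, which is exactly why the drop-one contrast is
used: only variation unique to a predictor counts for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io import DataError
from .rarefaction import AccumulationRun, _bspline_knots, _greville

log = logging.getLogger(__name__)

TIE_EPS = 1e-10
IMPORTANCE_FLOOR = -1e-8


@dataclass
class SmoothFit:
    """A single penalized cubic regression spline fit."""

    k: int
    lam: float
    fitted: np.ndarray
    edf: float
    dev_expl: float


@dataclass
class RunComparison:
    run_index: int
    importance_sites: float
    importance_area: float
    winner: Literal["sites", "area", "tie"]
    dev_expl_full: float


def _second_diff_penalty(greville: np.ndarray) -> np.ndarray:
    """Second-divided-difference penalty on spline coefficients.

    Differences are taken with respect to the Greville abscissae so that the
    null space is exactly the linear functions of x (a linear f has
    coefficients linear in the Greville sites, not in the index).
    """
    k = len(greville)
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        h1 = max(greville[i + 1] - greville[i], 1e-12)
        h2 = max(greville[i + 2] - greville[i + 1], 1e-12)
        w = 2.0 / (h1 + h2)
        D[i, i] = w / h1
        D[i, i + 1] = -w * (1.0 / h1 + 1.0 / h2)
        D[i, i + 2] = w / h2
    # normalise so lambda grids are comparable across x scales
    D /= max(np.abs(D).max(), 1e-12)
    return D.T @ D


def _basis_and_penalty(
    x: np.ndarray, k: int, x_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    t = _bspline_knots(np.asarray(x, float), k, x_range)
    from scipy.interpolate import BSpline

    B = BSpline.design_matrix(np.clip(x, *x_range), t, 3, extrapolate=True).toarray()
    return B, _second_diff_penalty(_greville(t))


def _effective_k(x: np.ndarray, k: int) -> int:
    n_distinct = len(np.unique(x))
    return k if n_distinct >= k else max(n_distinct - 1, 3)


def _penalized_solve(
    B: np.ndarray, y: np.ndarray, P: np.ndarray, lam: float
) -> tuple[np.ndarray, float, float]:
    """Solve min ||y - B th||^2 + lam th' P th; return (theta, rss, edf)."""
    BtB = B.T @ B
    ridge = 1e-9 * (np.trace(BtB) / len(BtB) + 1.0)
    A = BtB + lam * P + ridge * np.eye(len(BtB))
    # pinv: the two smooths of an additive fit share an unpenalized linear
    # null space, so A can be singular when the predictors are collinear
    Ainv = np.linalg.pinv(A, hermitian=True)
    theta = Ainv @ (B.T @ y)
    resid = y - B @ theta
    edf = float(np.trace(Ainv @ BtB))
    return theta, float(resid @ resid), edf


def _gcv_fit(
    B: np.ndarray, y: np.ndarray, P: np.ndarray, lambdas: np.ndarray
) -> tuple[np.ndarray, float, float, float]:
    """GCV-select lambda on a log grid; return (theta, lam, rss, edf)."""
    n = len(y)
    best = None
    for lam in lambdas:
        theta, rss, edf = _penalized_solve(B, y, P, lam)
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, theta, float(lam), rss, edf)
    return best[1], best[2], best[3], best[4]


LAMBDA_GRID = np.logspace(-5, 9, 29)


def fit_penalized_spline(
    x: Sequence[float],
    y: Sequence[float],
    k: int = 10,
    lam: float | Literal["auto"] = "auto",
) -> SmoothFit:
    """Penalized cubic regression spline of y on x (Gaussian likelihood).

    The second-difference penalty leaves linear trends unpenalized, so
    lam -> infinity shrinks the fit to the least-squares line. k is reduced
    when x has too few distinct values.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise DataError("need at least 4 points")
    k = _effective_k(x, k)
    B, P = _basis_and_penalty(x, k, (float(x.min()), float(x.max())))
    if lam == "auto":
        theta, lam_sel, rss, edf = _gcv_fit(B, y, P, LAMBDA_GRID)
    else:
        theta, rss, edf = _penalized_solve(B, y, P, float(lam))
        lam_sel = float(lam)
    tss = float(((y - y.mean()) ** 2).sum())
    dev_expl = 0.0 if tss == 0 else float(np.clip(1 - rss / tss, 0.0, 1.0))
    return SmoothFit(k, lam_sel, B @ theta, edf, dev_expl)


def _additive_fit(
    terms: list[tuple[np.ndarray, np.ndarray]], y: np.ndarray, grid: np.ndarray
) -> tuple[float, float]:
    """Additive model with centred smooth bases + intercept; per-term lambda
    by GCV over the grid (joint grid for two terms). ``terms`` pairs each
    basis with its penalty. Returns (dev_expl, edf)."""
    n = len(y)
    bases = [b for b, _ in terms]
    centred = [b - b.mean(axis=0, keepdims=True) for b in bases]
    X = np.hstack([np.ones((n, 1))] + centred)
    pens = [p for _, p in terms]

    def block_penalty(lams):
        blocks = [np.zeros((1, 1))] + [lam * p for lam, p in zip(lams, pens)]
        size = sum(b.shape[0] for b in blocks)
        P = np.zeros((size, size))
        o = 0
        for b in blocks:
            P[o : o + len(b), o : o + len(b)] = b
            o += len(b)
        return P

    combos = (
        [(l,) for l in grid]
        if len(bases) == 1
        else [(l1, l2) for l1 in grid for l2 in grid]
    )
    best = None
    for lams in combos:
        theta, rss, edf = _penalized_solve(X, y, block_penalty(lams), 1.0)
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, rss, edf)
    _, rss, edf = best
    tss = float(((y - y.mean()) ** 2).sum())
    dev_expl = 0.0 if tss == 0 else float(np.clip(1 - rss / tss, 0.0, 1.0))
    return dev_expl, edf


# coarser grid than the univariate fit: the two-term search is quadratic in it
ADDITIVE_LAMBDA_GRID = np.logspace(-4, 8, 9)


def compare_predictors(
    run: AccumulationRun, k: int = 10, run_index: int = 0
) -> RunComparison:
    """Drop-one explained-deviance contest between site count and area."""
    if run.area_cum is None:
        raise DataError("run has no cumulative areas")
    y = np.asarray(run.richness_cum, float)
    n = len(y)
    if n < 8:
        raise DataError("run too short (need >= 8 sites)")
    x_sites = np.arange(1, n + 1, dtype=float)
    x_area = np.asarray(run.area_cum, float)
    k_s = _effective_k(x_sites, k)
    k_a = _effective_k(x_area, k)
    term_s = _basis_and_penalty(x_sites, k_s, (x_sites.min(), x_sites.max()))
    term_a = _basis_and_penalty(x_area, k_a, (x_area.min(), x_area.max()))

    dev_full, _ = _additive_fit([term_s, term_a], y, ADDITIVE_LAMBDA_GRID)
    dev_no_area, _ = _additive_fit([term_s], y, ADDITIVE_LAMBDA_GRID)
    dev_no_sites, _ = _additive_fit([term_a], y, ADDITIVE_LAMBDA_GRID)

    imp_sites = dev_full - dev_no_sites
    imp_area = dev_full - dev_no_area
    for name, v in (("sites", imp_sites), ("area", imp_area)):
        if v < IMPORTANCE_FLOOR:
            # expected occasionally: lambda is refit per model, so drop-one
            # deviance is only >= 0 up to GCV selection noise
            log.debug("importance_%s below numerical floor: %.3g", name, v)
    imp_sites = max(imp_sites, 0.0)
    imp_area = max(imp_area, 0.0)
    if abs(imp_sites - imp_area) < TIE_EPS:
        winner = "tie"
    else:
        winner = "sites" if imp_sites > imp_area else "area"
    return RunComparison(run_index, imp_sites, imp_area, winner, dev_full)


def compare_runs(
    runs: Sequence[AccumulationRun], k: int = 10
) -> list[RunComparison]:
    return [compare_predictors(r, k=k, run_index=i) for i, r in enumerate(runs)]


@dataclass
class PredictorContest:
    pct_sites_better: float
    n_sites: int
    n_area: int
    n_tie: int


def proportion_sites_better(comparisons: Sequence[RunComparison]) -> PredictorContest:
    """Percent of decided runs in which site count beats cumulative area."""
    if not comparisons:
        raise DataError("no comparisons")
    n_sites = sum(c.winner == "sites" for c in comparisons)
    n_area = sum(c.winner == "area" for c in comparisons)
    n_tie = sum(c.winner == "tie" for c in comparisons)
    decided = n_sites + n_area
    pct = 100.0 * n_sites / decided if decided else float("nan")
    return PredictorContest(pct, n_sites, n_area, n_tie)
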