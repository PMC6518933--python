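"""Sample-based rarefaction: accumulation runs, envelopes, expected loss.

The sampling-only null for species loss under habitat removal: how many
species would a random subset of m habitats (or a given cumulative area)
be expected to hold? Resampling is without replacement — each run is a
uniform random permutation of the sites and richness accumulates along its
prefixes. The site-count axis uses exact per-k means and empirical
2.5/97.5 percentiles; the continuous area axis uses quantile regression
(pinball loss) on a cubic B-spline basis at tau = 0.025 / 0.5 / 0.975.
A closed-form hypergeometric expectation serves as the oracle for the
site-count axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import gammaln

from .io import DataError, OccurrenceMatrix


@dataclass
class AccumulationRun:
    """One random site ordering with cumulative richness (and area)."""

    ordering: np.ndarray  # permutation of site indices
    richness_cum: np.ndarray  # cumulative distinct-species counts
    area_cum: np.ndarray | None  # cumulative area (ha), or None if no areas


@dataclass
class Envelope:
    """Central curve with 2.5th/97.5th percentile bounds on a grid."""

    axis: Literal["sites", "area"]
    grid: np.ndarray
    central: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_runs: int

    def at(self, x: float) -> tuple[float, float, float]:
        """(central, lo, hi) interpolated at ``x`` (no extrapolation)."""
        if not (self.grid[0] <= x <= self.grid[-1]):
            raise DataError(
                f"{x} outside envelope grid [{self.grid[0]}, {self.grid[-1]}]"
            )
        return (
            float(np.interp(x, self.grid, self.central)),
            float(np.interp(x, self.grid, self.lo)),
            float(np.interp(x, self.grid, self.hi)),
        )


def accumulation_runs(
    occ: OccurrenceMatrix,
    areas: Sequence[float] | pd.Series | None = None,
    n_runs: int = 2000,
    seed: int = 0,
) -> list[AccumulationRun]:
    """Independent uniform permutation runs over the sites of ``occ``.

    ``areas`` (ha, aligned to ``occ.site_ids``) may be a sequence or a
    Series indexed by site id; omit it if only the site-count axis is needed.
    """
    a = None
    if areas is not None:
        if isinstance(areas, pd.Series):
            missing = [s for s in occ.site_ids if s not in areas.index]
            if missing:
                raise DataError(f"missing area for sites: {missing}")
            a = areas.loc[occ.site_ids].to_numpy(float)
        else:
            a = np.asarray(areas, float)
            if len(a) != occ.n_sites:
                raise DataError("areas not aligned to occurrence sites")
        if np.isnan(a).any() or (a <= 0).any():
            raise DataError("areas must be positive and present for all sites")
    rng = np.random.default_rng(seed)
    inc = occ.incidence.astype(bool)
    runs = []
    for _ in range(n_runs):
        perm = rng.permutation(occ.n_sites)
        seen = np.maximum.accumulate(inc[perm], axis=0)
        rich = seen.sum(axis=1)
        area_cum = np.cumsum(a[perm]) if a is not None else None
        runs.append(AccumulationRun(perm, rich, area_cum))
    return runs


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def analytic_sample_rarefaction(occ: OccurrenceMatrix, m: int) -> float:
    """Exact expected richness in a uniform random subset of ``m`` sites.

    E[S_m] = sum_i [1 - C(n - n_i, m) / C(n, m)], with n_i the number of
    sites species i occupies. Evaluated with log-gamma for stability.
    """
    n = occ.n_sites
    if not 1 <= m <= n:
        raise DataError(f"m={m} out of range 1..{n}")
    ni = occ.incidence.sum(axis=0).astype(float)
    keep = ni > 0
    ni = ni[keep]
    absent = np.zeros_like(ni)
    ok = n - ni >= m  # else the subset must contain the species
    absent[ok] = np.exp(_log_choose(n - ni[ok], m) - _log_choose(np.array(n, float), m))
    return float(np.sum(1.0 - absent))


def sample_envelope(runs: Sequence[AccumulationRun]) -> Envelope:
    """Site-count envelope: per-k mean and exact empirical percentiles."""
    if len(runs) < 2:
        raise DataError("need at least 2 runs")
    R = np.stack([r.richness_cum for r in runs]).astype(float)
    lo, hi = np.quantile(R, [0.025, 0.975], axis=0)  # type-7 (linear)
    return Envelope(
        axis="sites",
        grid=np.arange(1, R.shape[1] + 1, dtype=float),
        central=R.mean(axis=0),
        lo=lo,
        hi=hi,
        n_runs=len(runs),
    )


def _bspline_knots(x: np.ndarray, df: int, x_range: tuple[float, float]) -> np.ndarray:
    """Clamped cubic knot vector giving ``df`` basis functions (interior
    knots at quantiles of x)."""
    lo, hi = x_range
    degree = 3
    n_interior = df - degree - 1
    if n_interior < 0:
        raise DataError(f"qr_df={df} too small for a cubic basis (min 4)")
    interior = (
        np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
    )
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


def _greville(t: np.ndarray, degree: int = 3) -> np.ndarray:
    """Greville abscissae: a linear f(x)=a+bx has coefficients a + b*g_i."""
    k = len(t) - degree - 1
    return np.array([t[i + 1 : i + degree + 1].mean() for i in range(k)])


def _bspline_basis(x: np.ndarray, df: int, x_range: tuple[float, float]) -> np.ndarray:
    """Clamped cubic B-spline design matrix with ``df`` basis functions."""
    t = _bspline_knots(np.asarray(x, float), df, x_range)
    xc = np.clip(x, *x_range)
    return BSpline.design_matrix(xc, t, 3, extrapolate=True).toarray()


def area_envelope(
    runs: Sequence[AccumulationRun],
    qr_df: int = 5,
    n_grid: int = 200,
    max_points: int | None = 100_000,
    seed: int = 0,
) -> Envelope:
    """Area-axis envelope by spline quantile regression on the pooled
    (cumulative area, cumulative richness) points of all runs.

    Three fits (tau = 0.025, 0.5, 0.975) each minimise the pinball loss;
    quantile crossing is resolved by sorting the three curves pointwise.
    """
    if any(r.area_cum is None for r in runs):
        raise DataError("runs lack cumulative areas")
    x = np.concatenate([r.area_cum for r in runs])
    y = np.concatenate([r.richness_cum for r in runs]).astype(float)
    if x.min() == x.max():
        raise DataError("degenerate area range")
    if max_points is not None and len(x) > max_points:
        idx = np.random.default_rng(seed).choice(len(x), max_points, replace=False)
        x, y = x[idx], y[idx]
    x_range = (float(x.min()), float(x.max()))
    grid = np.linspace(*x_range, n_grid)
    if np.ptp(y) == 0:  # all richness identical: constant curves, no fit needed
        const = np.full(n_grid, y[0])
        return Envelope("area", grid, const, const.copy(), const.copy(), len(runs))

    B = _bspline_basis(x, qr_df, x_range)
    Bg = _bspline_basis(grid, qr_df, x_range)
    from statsmodels.regression.quantile_regression import QuantReg

    curves = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QuantReg convergence chatter on flat data
        for tau in (0.025, 0.5, 0.975):
            res = QuantReg(y, B).fit(q=tau)
            curves[tau] = Bg @ res.params
    stacked = np.sort(np.stack([curves[0.025], curves[0.5], curves[0.975]]), axis=0)
    return Envelope("area", grid, stacked[1], stacked[0], stacked[2], len(runs))


@dataclass
class ExpectedLoss:
    """Expected species loss under the sampling-only null."""

    expected: float
    rounded: int
    ci: tuple[float, float]
    gamma: int
    analytic: float | None = None  # closed-form cross-check (sites axis only)


def expected_loss_sites(
    occ_ref: OccurrenceMatrix,
    m_target: int,
    n_runs: int = 2000,
    seed: int = 0,
) -> ExpectedLoss:
    """Expected loss when the reference epoch is rarefied to ``m_target`` sites."""
    if not 1 <= m_target <= occ_ref.n_sites:
        raise DataError(f"m_target={m_target} out of range")
    runs = accumulation_runs(occ_ref, None, n_runs=n_runs, seed=seed)
    env = sample_envelope(runs)
    gamma = occ_ref.gamma
    if m_target == occ_ref.n_sites:
        # every permutation ends at gamma: the loss is exactly zero
        return ExpectedLoss(0.0, 0, (0.0, 0.0), gamma, 0.0)
    k = m_target - 1
    expected = gamma - env.central[k]
    ci = (gamma - env.hi[k], gamma - env.lo[k])
    analytic = gamma - analytic_sample_rarefaction(occ_ref, m_target)
    return ExpectedLoss(float(expected), int(round(expected)), ci, gamma, float(analytic))


def expected_loss_area(
    occ_ref: OccurrenceMatrix,
    areas: pd.Series | Sequence[float],
    a_target: float,
    n_runs: int = 2000,
    qr_df: int = 5,
    seed: int = 0,
) -> ExpectedLoss:
    """Expected loss when the reference epoch is rarefied to ``a_target`` ha."""
    runs = accumulation_runs(occ_ref, areas, n_runs=n_runs, seed=seed)
    env = area_envelope(runs, qr_df=qr_df, seed=seed)
    gamma = occ_ref.gamma
    central, lo, hi = env.at(a_target)
    expected = gamma - central
    return ExpectedLoss(float(expected), int(round(expected)), (gamma - hi, gamma - lo), gamma)
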