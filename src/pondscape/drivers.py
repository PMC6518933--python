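"""Trait and landscape driver models with commonality (variance) partitioning.

Two analyses:

* regional: a binomial GLM of a species' regional extinction on
  sqrt(occupancy in epoch 1), log(body size) and salinity preference, with
  the adjusted pseudo-R^2 partitioned into pure and shared fractions over
  the three traits;
* local: a Gaussian partition of the change in per-pond richness at the
  ponds sampled in both epochs onto the changes in closeness centrality,
  conductivity and log-area, plus one multiple linear regression for
  slope t-tests.

The three-predictor commonality algebra: with R(S) the adjusted
(pseudo-)R^2 of the model on predictor subset S,

    pure_A      = R(ABC) - R(BC)
    shared_AB   = R(AC) + R(BC) - R(C) - R(ABC)
    shared_ABC  = R(ABC) + R(A) + R(B) + R(C) - R(AB) - R(AC) - R(BC)

(and symmetrically); the seven fractions sum to R(ABC) identically.
Individual fractions may be negative under the adjusted-R^2 convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import DataError

MAX_COND_NUMBER = 1e10
SEPARATION_SLOPE = 15.0  # |slope| on standardized predictors beyond which
                         # we flag quasi-separation


@dataclass
class GlmFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    null_deviance: float
    deviance: float
    n: int
    p: int  # number of slopes (excluding intercept)
    converged: bool
    family: Literal["binomial", "gaussian"]


def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, float)
    if not np.isfinite(arr).all():
        raise DataError("non-finite predictor values")
    Xc = sm.add_constant(arr, has_constant="add")
    if np.linalg.cond(Xc) > MAX_COND_NUMBER:
        raise DataError("predictor matrix is (near-)collinear")


def fit_binomial_glm(y, X: pd.DataFrame) -> GlmFit:
    """Logistic regression via IRLS (statsmodels GLM, binomial family).

    Flags quasi-separation: any standardized slope with |value| > 15 sets
    ``converged=False``.
    """
    y = np.asarray(y, float)
    X = pd.DataFrame(X)
    if len(y) != len(X):
        raise DataError("y and X lengths differ")
    if len(y) <= X.shape[1] + 1:
        raise DataError("need n > p + 1 observations")
    if len(np.unique(y)) < 2:
        raise DataError("response is constant")
    _check_design(X)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xc, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-8)
            converged = bool(res.converged)
        except Exception:
            # IRLS blow-up under perfect separation: refit with heavy damping
            res = model.fit(maxiter=25, tol=1e-4)
            converged = False
    sds = X.std(ddof=0)
    std_slopes = res.params.drop("const") * sds.to_numpy()
    if (np.abs(std_slopes) > SEPARATION_SLOPE).any():
        warnings.warn("possible (quasi-)separation: extreme standardized slope",
                      stacklevel=2)
        converged = False
    return GlmFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        n=len(y),
        p=X.shape[1],
        converged=converged,
        family="binomial",
    )


def fit_gaussian_lm(y, X: pd.DataFrame):
    """OLS with t-test p-values (statsmodels)."""
    y = np.asarray(y, float)
    X = pd.DataFrame(X)
    if len(y) <= X.shape[1] + 1:
        raise DataError("need n > p + 1 observations")
    _check_design(X)
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def extinction_model(traits: pd.DataFrame) -> GlmFit:
    """Binomial GLM of regional extinction on transformed species traits.

    Predictors: sqrt(occupancy_1957), log(body_size), preference (mS/cm).
    """
    need = ["occupancy_1957", "body_size", "preference", "extinct_2010"]
    missing = [c for c in need if c not in traits.columns]
    if missing:
        raise DataError(f"trait table missing columns: {missing}")
    if traits[need].isna().any().any():
        raise DataError("trait table has missing values")
    X = pd.DataFrame(
        {
            "sqrt_occupancy": np.sqrt(traits["occupancy_1957"]),
            "log_body_size": np.log(traits["body_size"]),
            "preference": traits["preference"],
        },
        index=traits.index,
    )
    return fit_binomial_glm(traits["extinct_2010"].astype(float), X)


def adjusted_pseudo_r2(fit: GlmFit) -> float:
    """Deviance pseudo-R^2 with the Ezekiel small-sample adjustment."""
    if fit.n <= fit.p + 1:
        raise DataError("n too small for adjustment")
    r2 = 1.0 - fit.deviance / fit.null_deviance
    return float(1.0 - (1.0 - r2) * (fit.n - 1) / (fit.n - fit.p - 1))


def _variance_r2(fit: GlmFit, y, X) -> float:
    """Variance-function-based pseudo-R^2 (corr(y, fitted)^2), adjusted."""
    Xc = sm.add_constant(pd.DataFrame(X), has_constant="add")
    eta = np.asarray(Xc, float) @ fit.params.to_numpy()
    mu = 1.0 / (1.0 + np.exp(-eta))
    r2 = float(np.corrcoef(np.asarray(y, float), mu)[0, 1] ** 2)
    return float(1.0 - (1.0 - r2) * (fit.n - 1) / (fit.n - fit.p - 1))


@dataclass
class Partition3:
    """Pure and shared explained-variance fractions for three predictors."""

    labels: tuple[str, str, str]
    fractions: dict[str, float]  # keys "A","B","C","AB","AC","BC","ABC"
    residual: float
    total_adj_r2: float

    def pure(self, label: str) -> float:
        return self.fractions["ABC"[self.labels.index(label)]]

    def largest_pure(self) -> str:
        key = max("ABC", key=lambda s: self.fractions[s])
        return self.labels["ABC".index(key)]


def _subset_r2(y, X: pd.DataFrame, cols: tuple[str, ...],
               family: str, r2_variant: str) -> float:
    sub = X[list(cols)]
    if family == "gaussian":
        res = fit_gaussian_lm(y, sub)
        return float(res.rsquared_adj)  # Ezekiel adjustment
    fit = fit_binomial_glm(y, sub)
    if r2_variant == "variance":
        return _variance_r2(fit, y, sub)
    return adjusted_pseudo_r2(fit)


def commonality_partition(
    y,
    X: pd.DataFrame,
    family: Literal["binomial", "gaussian"] = "gaussian",
    r2_variant: Literal["deviance", "variance"] = "deviance",
) -> Partition3:
    """All pure and shared adjusted-R^2 fractions for three named predictors.

    Fits the seven non-empty predictor subsets and applies the standard
    three-set commonality algebra. ``r2_variant`` selects the binomial
    pseudo-R^2 (deviance-based default; "variance" = squared correlation
    of response with fitted probabilities).
    """
    X = pd.DataFrame(X)
    if X.shape[1] != 3:
        raise DataError("commonality_partition needs exactly 3 predictors")
    A, B, C = X.columns
    R: dict[frozenset, float] = {}
    for size in (1, 2, 3):
        for cols in combinations(X.columns, size):
            try:
                R[frozenset(cols)] = _subset_r2(y, X, cols, family, r2_variant)
            except DataError as e:
                raise DataError(f"subset {cols} fit failed: {e}") from e

    def r(*cols):
        return R[frozenset(cols)]

    frac = {
        "A": r(A, B, C) - r(B, C),
        "B": r(A, B, C) - r(A, C),
        "C": r(A, B, C) - r(A, B),
        "AB": r(A, C) + r(B, C) - r(C) - r(A, B, C),
        "AC": r(A, B) + r(B, C) - r(B) - r(A, B, C),
        "BC": r(A, B) + r(A, C) - r(A) - r(A, B, C),
        "ABC": r(A, B, C) + r(A) + r(B) + r(C) - r(A, B) - r(A, C) - r(B, C),
    }
    total = r(A, B, C)
    if abs(sum(frac.values()) - total) > 1e-10:
        raise AssertionError("commonality fractions do not sum to total R^2")
    return Partition3((A, B, C), frac, 1.0 - total, total)


@dataclass
class LocalDrivers:
    partition: Partition3
    slopes: pd.Series
    pvalues: pd.Series
    adj_r2: float


def local_drivers_analysis(records: pd.DataFrame) -> LocalDrivers:
    """Partition the change in local richness onto connectivity, salinity
    and area change at ponds sampled in both epochs.

    ``records`` needs columns d_richness, d_closeness, d_conductivity,
    d_log_area (one row per shared pond, >= 8 rows).
    """
    need = ["d_richness", "d_closeness", "d_conductivity", "d_log_area"]
    missing = [c for c in need if c not in records.columns]
    if missing:
        raise DataError(f"records missing columns: {missing}")
    if len(records) < 8:
        raise DataError("need at least 8 shared ponds")
    y = records["d_richness"].to_numpy(float)
    X = records[["d_closeness", "d_conductivity", "d_log_area"]]
    part = commonality_partition(y, X, family="gaussian")
    res = fit_gaussian_lm(y, X)
    return LocalDrivers(
        partition=part,
        slopes=res.params.drop("const"),
        pvalues=res.pvalues.drop("const"),
        adj_r2=float(res.rsquared_adj),
    )
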