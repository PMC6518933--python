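"""Synthetic two-epoch pond metacommunities.

Emulates a landscape of shallow saline ponds (soda pans): ~116 ponds in a
~270 km^2 region, right-skewed areas, lognormal conductivities, a species
pool with many rare / few common occupancies and Gaussian salinity niches
on log-conductivity, heavy habitat loss (30 survivors), and a relaxation
(extinction-debt) phase in which each surviving incidence is lost with a
probability that grows with the pond's loss of network connectivity, its
shrinkage and its change in salinity. No recolonisation: regional richness
can only decrease through relaxation.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .io import DataError, OccurrenceMatrix, PondTable
from .network import build_network, delta_closeness

COND_FLOOR = 0.05  # mS/cm; conductivity never drifts to or below zero


@dataclass
class LandscapeParams:
    """Pond landscape geometry and habitat distributions.

    Defaults give ~116 ponds on a 27 x 10 km rectangle (270 km^2), areas
    lognormal(2.0, 1.2) ha (median ~7.4 ha, right-skewed), conductivities
    lognormal(0.8, 0.6) mS/cm (mean ~2.7 mS/cm).
    """

    n_ponds: int = 116
    extent_x: float = 27_000.0
    extent_y: float = 10_000.0
    area_logmean: float = 2.0
    area_logsd: float = 1.2
    cond_logmean: float = 0.8
    cond_logsd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ponds < 2:
            raise DataError("n_ponds must be >= 2")
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise DataError("extents must be positive")
        if self.area_logsd < 0 or self.cond_logsd < 0:
            raise DataError("log-sds must be non-negative")


@dataclass
class PoolParams:
    """Regional species pool: prevalence distribution and salinity niches.

    Prevalence (baseline occupancy probability) is Beta(0.35, 1.6): most
    species rare, a few widespread. Niche optima are uniform on a
    log-conductivity interval; niche width is Gaussian sd on the log scale
    (``math.inf`` = no salinity structure).
    """

    n_species: int = 60
    prevalence_a: float = 0.35
    prevalence_b: float = 1.6
    niche_sd_log: float = 1.0
    niche_optima_range: tuple[float, float] = (math.log(0.5), math.log(8.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise DataError("n_species must be >= 1")
        if self.prevalence_a <= 0 or self.prevalence_b <= 0:
            raise DataError("prevalence Beta parameters must be positive")
        if self.niche_sd_log <= 0:
            raise DataError("niche_sd_log must be positive (math.inf allowed)")


@dataclass
class RelaxationParams:
    """Per-incidence local-extinction model for the relaxation phase.

    q_j = logistic(b0 + b_conn * dclose_j + b_area * dlogarea_j
                   + b_cond * |dcond_j|)

    b0 is the baseline logit; b_conn is per km of closeness increase
    (isolation), b_area per unit of log-area change, b_cond per mS/cm of
    absolute conductivity change. ``no_extinction`` forces q = 0.
    """

    b0: float = -2.0
    b_conn: float = 0.8
    b_area: float = -0.3
    b_cond: float = 0.15
    cond_drift_mean: float = 0.77
    cond_drift_sd: float = 2.0
    no_extinction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("b_conn", "b_area", "b_cond", "cond_drift_mean", "cond_drift_sd"):
            if not math.isfinite(getattr(self, name)):
                raise DataError(f"{name} must be finite")


def generate_landscape(params: LandscapeParams) -> PondTable:
    """Draw a pond landscape; everything extant and sampled in epoch 1."""
    rng = np.random.default_rng(params.seed)
    n = params.n_ponds
    df = pd.DataFrame(
        {
            "x": rng.uniform(0.0, params.extent_x, n),
            "y": rng.uniform(0.0, params.extent_y, n),
            "area_1957": np.exp(rng.normal(params.area_logmean, params.area_logsd, n)),
            "area_2010": np.nan,
            "cond_1957": np.exp(rng.normal(params.cond_logmean, params.cond_logsd, n)),
            "cond_2010": np.nan,
            "extant_1957": True,
            "extant_2010": False,
            "sampled_1957": True,
            "sampled_2010": False,
        },
        index=pd.Index([f"P{i + 1:03d}" for i in range(n)], name="pond_id"),
    )
    return PondTable(df)


def _occupancy_probs(cond: np.ndarray, prev: np.ndarray, optima: np.ndarray,
                     niche_sd_log: float) -> np.ndarray:
    """p_ij = prev_i * exp(-(ln c_j - mu_i)^2 / (2 sd^2)); (sites x species)."""
    if math.isinf(niche_sd_log):
        return np.broadcast_to(prev, (len(cond), len(prev))).copy()
    z = (np.log(cond)[:, None] - optima[None, :]) / niche_sd_log
    return prev[None, :] * np.exp(-0.5 * z**2)


def simulate_occurrence(ponds: PondTable, pool: PoolParams, epoch: str) -> OccurrenceMatrix:
    """Sample a site x species incidence matrix for the ponds extant in ``epoch``.

    Occupancy is an independent Bernoulli per (species, site) with a
    Gaussian niche on log-conductivity scaled by the species' prevalence.
    Species never observed anywhere are dropped from the matrix.
    """
    rng = np.random.default_rng(pool.seed)
    prev = rng.beta(pool.prevalence_a, pool.prevalence_b, pool.n_species)
    lo, hi = pool.niche_optima_range
    optima = rng.uniform(lo, hi, pool.n_species)

    sub = ponds.extant(epoch)
    cond = sub[f"cond_{epoch}"].to_numpy(float)
    if np.isnan(cond).any():
        bad = sub.index[np.isnan(cond)][0]
        raise DataError(f"pond {bad!r} lacks conductivity in epoch {epoch}")
    p = _occupancy_probs(cond, prev, optima, pool.niche_sd_log)
    inc = (rng.random(p.shape) < p).astype(np.int8)
    occ = OccurrenceMatrix(
        epoch,
        list(sub.index),
        [f"S{i + 1:03d}" for i in range(pool.n_species)],
        inc,
    )
    return occ.drop_empty_species()


def apply_habitat_loss(
    ponds: PondTable,
    keep: int | float,
    mode: Literal["random", "clustered"] = "random",
    seed: int = 0,
) -> PondTable:
    """Mark exactly ``keep`` epoch-1 ponds as extant in epoch 2.

    ``keep`` may be a count or a fraction of the epoch-1 ponds. ``random``
    picks a uniform subset; ``clustered`` makes survival odds fall off
    logistically with distance from a random focal point (weighted sampling
    without replacement, exact count preserved).
    """
    rng = np.random.default_rng(seed)
    extant1 = ponds.df.index[ponds.df["extant_1957"]]
    n = len(extant1)
    if isinstance(keep, float) and 0 < keep <= 1:
        keep = round(keep * n)
    keep = int(keep)
    if not 0 < keep <= n:
        raise DataError(f"keep={keep} out of range (1..{n})")

    if mode == "random":
        survivors = rng.choice(extant1, size=keep, replace=False)
    elif mode == "clustered":
        coords = ponds.coords(extant1)
        focal = coords[rng.integers(n)]
        d = np.hypot(*(coords - focal).T)
        scale = max(np.median(d), 1e-9)
        logit = (np.median(d) - d) / (0.25 * scale)
        # Gumbel-max trick: weighted sampling without replacement at exact count
        score = logit + rng.gumbel(size=n)
        survivors = extant1[np.argsort(score)[::-1][:keep]]
    else:
        raise DataError(f"unknown loss mode {mode!r}")

    df = ponds.df.copy()
    df["extant_2010"] = False
    df.loc[survivors, "extant_2010"] = True
    df["sampled_2010"] = False
    return PondTable(df)


def simulate_relaxation(
    occ: OccurrenceMatrix,
    delta: pd.DataFrame,
    params: RelaxationParams,
) -> OccurrenceMatrix:
    """Relaxation after habitat loss: each incidence at a surviving site
    flips to absent independently with a logistic probability in the site's
    connectivity, area and salinity changes.

    ``delta`` is indexed by surviving site id with columns ``d_closeness_km``,
    ``d_log_area`` and ``d_conductivity``; sites of ``occ`` not in ``delta``
    are treated as lost and removed. No colonisation: the output incidence
    is a subset of the input.
    """
    survivors = [s for s in occ.site_ids if s in delta.index]
    missing = [s for s in delta.index if s not in occ.site_ids]
    if missing:
        raise DataError(f"delta rows for unknown sites: {missing}")
    sub = occ.restrict_sites(survivors, drop_empty=False)
    d = delta.loc[survivors]
    if params.no_extinction:
        q = np.zeros(len(survivors))
    else:
        eta = (
            params.b0
            + params.b_conn * d["d_closeness_km"].to_numpy(float)
            + params.b_area * d["d_log_area"].to_numpy(float)
            + params.b_cond * np.abs(d["d_conductivity"].to_numpy(float))
        )
        q = 1.0 / (1.0 + np.exp(-eta))
    if np.isnan(q).any():
        raise DataError("missing delta values for a surviving site")
    rng = np.random.default_rng(params.seed)
    lost = rng.random(sub.incidence.shape) < q[:, None]
    inc = np.where(lost, 0, sub.incidence).astype(np.int8)
    out = OccurrenceMatrix("2010", survivors, list(sub.species_ids), inc)
    return out.drop_empty_species()


@dataclass
class CaseStudy:
    """End-to-end synthetic fixture mirroring the study's dimensions."""

    ponds: PondTable
    occ_1957: OccurrenceMatrix  # the 53 sampled epoch-1 sites
    occ_2010: OccurrenceMatrix  # the 30 surviving sites
    body_sizes: pd.Series
    delta: pd.DataFrame  # per-survivor changes used by the relaxation
    occ_1957_full: OccurrenceMatrix  # all 116 epoch-1 sites (pre-subsampling)


def generate_case_study(
    seed: int = 0,
    landscape: LandscapeParams | None = None,
    pool: PoolParams | None = None,
    relaxation: RelaxationParams | None = None,
    n_keep: int = 30,
    n_sampled: int = 53,
    n_overlap: int = 24,
    area_shrink_logmean: float = -0.3,
    area_shrink_logsd: float = 0.3,
) -> CaseStudy:
    """Full two-epoch fixture: 116 ponds, 53 sampled in epoch 1, 30 survivors
    of which 24 are among the sampled set.

    Sub-seeds for each stage are split deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    landscape = replace(landscape or LandscapeParams(), seed=subseeds[0])
    pool = replace(pool or PoolParams(), seed=subseeds[1])
    relaxation = replace(relaxation or RelaxationParams(), seed=subseeds[2])

    ponds = generate_landscape(landscape)
    occ_full = simulate_occurrence(ponds, pool, "1957")
    ponds = apply_habitat_loss(ponds, keep=n_keep, mode="random", seed=subseeds[3])

    rng = np.random.default_rng(subseeds[4])
    survivors = list(ponds.df.index[ponds.df["extant_2010"]])
    others = [p for p in ponds.df.index if p not in set(survivors)]
    if n_overlap > min(n_keep, n_sampled) or n_sampled - n_overlap > len(others):
        raise DataError("infeasible sampled/overlap counts")
    sampled = list(rng.choice(survivors, n_overlap, replace=False)) + list(
        rng.choice(others, n_sampled - n_overlap, replace=False)
    )
    sampled = [p for p in ponds.df.index if p in set(sampled)]  # stable order

    df = ponds.df.copy()
    df["sampled_1957"] = False
    df.loc[sampled, "sampled_1957"] = True
    # surviving ponds shrink and become more saline on average
    shrink = np.exp(rng.normal(area_shrink_logmean, area_shrink_logsd, len(survivors)))
    df.loc[survivors, "area_2010"] = df.loc[survivors, "area_1957"] * shrink
    drift = rng.normal(relaxation.cond_drift_mean, relaxation.cond_drift_sd, len(survivors))
    df.loc[survivors, "cond_2010"] = np.maximum(
        df.loc[survivors, "cond_1957"] + drift, COND_FLOOR
    )
    df.loc[survivors, "sampled_2010"] = True
    ponds = PondTable(df)

    net_1957 = build_network(ponds, "1957")
    net_2010 = build_network(ponds, "2010")
    delta = pd.DataFrame(
        {
            "d_closeness_km": delta_closeness(net_1957, net_2010, survivors),
            "d_log_area": np.log(df.loc[survivors, "area_2010"])
            - np.log(df.loc[survivors, "area_1957"]),
            "d_conductivity": df.loc[survivors, "cond_2010"]
            - df.loc[survivors, "cond_1957"],
        }
    )
    occ_2010 = simulate_relaxation(occ_full, delta, relaxation)
    occ_1957 = occ_full.restrict_sites(sampled, drop_empty=True)

    rng_bs = np.random.default_rng(subseeds[5])
    all_species = sorted(set(occ_full.species_ids))
    body_sizes = pd.Series(
        np.exp(rng_bs.normal(-0.7, 0.8, len(all_species))),
        index=pd.Index(all_species, name="species_id"),
        name="body_size_mm",
    )
    return CaseStudy(ponds, occ_1957, occ_2010, body_sizes, delta, occ_full)
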