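"""Synthetic landscape generator: distributions, loss, relaxation, fixture."""

import math

import numpy as np
import pandas as pd
import pytest

from pondscape import landscape as L
from pondscape.io import DataError


class TestGenerateLandscape:
    def test_degenerate_sd_all_areas_equal(self):
        p = L.LandscapeParams(n_ponds=2, area_logsd=0.0, cond_logsd=0.0, seed=1)
        ponds = L.generate_landscape(p)
        np.testing.assert_allclose(ponds.df["area_1957"], math.exp(p.area_logmean))

    def test_deterministic_given_seed(self):
        a = L.generate_landscape(L.LandscapeParams(seed=5))
        b = L.generate_landscape(L.LandscapeParams(seed=5))
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_area_mean_matches_lognormal_moment(self):
        p = L.LandscapeParams(n_ponds=100_000, area_logmean=1.0, area_logsd=0.7, seed=2)
        areas = L.generate_landscape(p).df["area_1957"]
        mu = math.exp(1.0 + 0.7**2 / 2)
        sd = mu * math.sqrt(math.exp(0.7**2) - 1)
        se = sd / math.sqrt(p.n_ponds)
        assert abs(areas.mean() - mu) < 3 * se

    def test_validation(self):
        with pytest.raises(DataError):
            L.LandscapeParams(n_ponds=1)
        with pytest.raises(DataError):
            L.LandscapeParams(extent_x=-1)


class TestSimulateOccurrence:
    def test_flat_niche_limit_probability_is_prevalence(self):
        cond = np.array([0.5, 2.0, 8.0])
        prev = np.array([0.3, 0.9])
        optima = np.array([0.0, 1.0])
        p = L._occupancy_probs(cond, prev, optima, math.inf)
        np.testing.assert_allclose(p, np.broadcast_to(prev, (3, 2)))

    def test_at_optimum_with_full_prevalence_probability_one(self):
        p = L._occupancy_probs(np.array([2.0]), np.array([1.0]),
                               np.array([math.log(2.0)]), 0.5)
        assert p[0, 0] == pytest.approx(1.0)

    def test_realised_occupancy_matches_expectation(self):
        # many ponds: per-species realised occupancy ~ mean_j p_ij (binomial)
        lp = L.LandscapeParams(n_ponds=5000, seed=3)
        pool = L.PoolParams(n_species=20, seed=4)
        ponds = L.generate_landscape(lp)
        occ = L.simulate_occurrence(ponds, pool, "1957")
        rng = np.random.default_rng(pool.seed)
        prev = rng.beta(pool.prevalence_a, pool.prevalence_b, pool.n_species)
        lo, hi = pool.niche_optima_range
        optima = rng.uniform(lo, hi, pool.n_species)
        p = L._occupancy_probs(
            ponds.df["cond_1957"].to_numpy(), prev, optima, pool.niche_sd_log
        )
        realised = pd.Series(0.0, index=[f"S{i+1:03d}" for i in range(20)])
        realised[occ.species_ids] = occ.incidence.mean(axis=0)
        expect = p.mean(axis=0)
        se = np.sqrt((p * (1 - p)).sum(axis=0)) / lp.n_ponds
        assert (np.abs(realised.to_numpy() - expect) < 3 * se + 1e-12).all()


class TestHabitatLoss:
    def test_keep_all_is_identity(self):
        ponds = L.generate_landscape(L.LandscapeParams(n_ponds=20, seed=1))
        out = L.apply_habitat_loss(ponds, keep=20, seed=2)
        assert (out.df["extant_2010"] == out.df["extant_1957"]).all()

    @pytest.mark.parametrize("mode", ["random", "clustered"])
    def test_exact_survivor_count(self, mode):
        ponds = L.generate_landscape(L.LandscapeParams(n_ponds=116, seed=1))
        out = L.apply_habitat_loss(ponds, keep=30, mode=mode, seed=2)
        assert out.df["extant_2010"].sum() == 30

    def test_keep_too_large_errors(self):
        ponds = L.generate_landscape(L.LandscapeParams(n_ponds=5, seed=1))
        with pytest.raises(DataError):
            L.apply_habitat_loss(ponds, keep=6)

    def test_random_mode_is_uniform(self):
        ponds = L.generate_landscape(L.LandscapeParams(n_ponds=12, seed=1))
        n_rep, keep = 4000, 5
        freq = np.zeros(12)
        for rep in range(n_rep):
            out = L.apply_habitat_loss(ponds, keep=keep, seed=rep)
            freq += out.df["extant_2010"].to_numpy()
        freq /= n_rep
        p = keep / 12
        se = math.sqrt(p * (1 - p) / n_rep)
        assert (np.abs(freq - p) < 3.5 * se).all()


def _toy_occ_and_delta(n_sites=40, n_species=25, seed=0):
    rng = np.random.default_rng(seed)
    inc = (rng.random((n_sites, n_species)) < 0.5).astype(np.int8)
    inc[0] = 1  # no empty column
    from conftest import make_occ

    occ = make_occ(inc)
    delta = pd.DataFrame(
        {
            "d_closeness_km": rng.normal(0, 1, n_sites),
            "d_log_area": rng.normal(0, 0.3, n_sites),
            "d_conductivity": rng.normal(0, 1, n_sites),
        },
        index=occ.site_ids,
    )
    return occ, delta


class TestRelaxation:
    def test_no_extinction_flag_is_identity(self):
        occ, delta = _toy_occ_and_delta()
        out = L.simulate_relaxation(
            occ, delta, L.RelaxationParams(no_extinction=True, seed=1)
        )
        np.testing.assert_array_equal(out.incidence, occ.incidence)

    def test_fair_coin_at_zero_logit(self):
        occ, delta = _toy_occ_and_delta()
        delta[:] = 0.0
        total = occ.incidence.sum()
        kept = []
        for seed in range(60):
            out = L.simulate_relaxation(occ, delta, L.RelaxationParams(
                b0=0.0, b_conn=0.0, b_area=0.0, b_cond=0.0, seed=seed))
            kept.append(out.incidence.sum())
        mean_kept = np.mean(kept)
        se = math.sqrt(total * 0.25 / 60)
        assert abs(mean_kept - total / 2) < 3 * se

    def test_richness_loss_concentrates_where_isolation_grew(self):
        # with b_conn > 0, sites in the top tercile of d_closeness lose more
        occ, delta = _toy_occ_and_delta(seed=3)
        params = dict(b0=-1.0, b_conn=2.0, b_area=0.0, b_cond=0.0)
        order = np.argsort(delta["d_closeness_km"].to_numpy())
        lo_t, hi_t = order[:13], order[-13:]
        d_lo, d_hi = [], []
        for seed in range(100):
            out = L.simulate_relaxation(occ, delta, L.RelaxationParams(**params, seed=seed))
            alpha = pd.Series(0, index=occ.site_ids)
            alpha[out.site_ids] = pd.Series(out.alpha, index=out.site_ids)
            d = alpha.to_numpy() - occ.alpha
            d_lo.append(d[lo_t].mean())
            d_hi.append(d[hi_t].mean())
        assert np.mean(d_hi) < np.mean(d_lo)

    def test_never_adds_incidences(self):
        occ, delta = _toy_occ_and_delta(seed=9)
        out = L.simulate_relaxation(occ, delta, L.RelaxationParams(seed=2))
        sub = occ.restrict_sites(out.site_ids, drop_empty=False)
        pos = {s: j for j, s in enumerate(sub.species_ids)}
        cols = [pos[s] for s in out.species_ids]
        assert (out.incidence <= sub.incidence[:, cols]).all()


class TestCaseStudy:
    def test_study_dimensions(self):
        case = L.generate_case_study(seed=11)
        assert case.occ_1957.n_sites == 53
        assert case.occ_2010.n_sites == 30
        overlap = set(case.occ_1957.site_ids) & set(case.occ_2010.site_ids)
        assert len(overlap) >= 24

    def test_bit_identical_given_seed(self):
        a = L.generate_case_study(seed=4)
        b = L.generate_case_study(seed=4)
        pd.testing.assert_frame_equal(a.ponds.df, b.ponds.df)
        np.testing.assert_array_equal(a.occ_1957.incidence, b.occ_1957.incidence)
        np.testing.assert_array_equal(a.occ_2010.incidence, b.occ_2010.incidence)
        pd.testing.assert_series_equal(a.body_sizes, b.body_sizes)

    def test_distinct_seeds_distinct_output(self):
        a = L.generate_case_study(seed=4)
        b = L.generate_case_study(seed=5)
        assert not a.ponds.df.equals(b.ponds.df)

    def test_relaxation_only_removes_regional_species(self):
        case = L.generate_case_study(seed=6)
        assert case.occ_2010.species_present <= case.occ_1957_full.species_present
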