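"""GLM fits, adjusted pseudo-R2, and commonality partitioning."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from pondscape import drivers as DR
from pondscape.io import DataError


def nelder_mead_logistic(y, X):
    """Derivative-free binomial likelihood maximiser (independent oracle)."""
    Xc = np.column_stack([np.ones(len(y)), np.asarray(X, float)])

    def nll(beta):
        eta = Xc @ beta
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    res = minimize(nll, np.zeros(Xc.shape[1]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000})
    return res.x


def simulate_logistic(n, p, seed, beta=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(0, 1, (n, p)), columns=[f"x{j}" for j in range(p)])
    beta = np.zeros(p + 1) if beta is None else np.asarray(beta, float)
    eta = beta[0] + X.to_numpy() @ beta[1:]
    y = (rng.random(n) < expit(eta)).astype(float)
    if len(np.unique(y)) < 2:  # rare at these sizes; reroll deterministically
        return simulate_logistic(n, p, seed + 1000, beta)
    return y, X


class TestBinomialGlm:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0, 0, 0, 0] * 4)  # mean 0.25
        fit = DR.fit_binomial_glm(y, pd.DataFrame(index=range(16)))
        assert fit.params["const"] == pytest.approx(logit(0.25), abs=1e-8)
        assert DR.adjusted_pseudo_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_errors(self):
        with pytest.raises(DataError, match="constant"):
            DR.fit_binomial_glm(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_collinear_design_errors(self):
        y, X = simulate_logistic(40, 1, seed=1)
        X["x1"] = 2.0 * X["x0"]
        with pytest.raises(DataError, match="collinear"):
            DR.fit_binomial_glm(y, X)

    def test_null_slopes_near_zero(self):
        y, X = simulate_logistic(4000, 3, seed=2)
        fit = DR.fit_binomial_glm(y, X)
        assert np.abs(fit.params.drop("const")).max() < 0.12
        assert fit.deviance <= fit.null_deviance

    @pytest.mark.parametrize("seed", range(10))
    def test_irls_matches_derivative_free_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(25, 60))
        p = int(rng.integers(1, 3))
        beta = rng.normal(0, 0.8, p + 1)
        y, X = simulate_logistic(n, p, seed=seed + 100, beta=beta)
        fit = DR.fit_binomial_glm(y, X)
        oracle = nelder_mead_logistic(y, X)
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-4)

    def test_separation_flagged(self):
        # extinction is a deterministic threshold on the predictor
        x = np.linspace(0, 1, 30)
        y = (x < 0.4).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            fit = DR.fit_binomial_glm(y, pd.DataFrame({"x": x}))
        assert not fit.converged


class TestExtinctionModel:
    def make_traits(self, seed=0, n=40, b_occ=-4.0):
        rng = np.random.default_rng(seed)
        occ = rng.uniform(0.02, 1.0, n)
        traits = pd.DataFrame(
            {
                "occupancy_1957": occ,
                "body_size": np.exp(rng.normal(-0.7, 0.8, n)),
                "preference": np.exp(rng.normal(0.8, 0.6, n)),
            },
            index=pd.Index([f"S{i}" for i in range(n)], name="species_id"),
        )
        eta = 1.0 + b_occ * np.sqrt(occ)
        traits["extinct_2010"] = rng.random(n) < expit(eta)
        if traits["extinct_2010"].nunique() < 2:
            return self.make_traits(seed + 1, n, b_occ)
        return traits

    def test_rarity_slope_negative(self):
        traits = self.make_traits(seed=3)
        fit = DR.extinction_model(traits)
        assert fit.params["sqrt_occupancy"] < 0
        assert fit.p == 3

    def test_constant_extinction_errors(self):
        traits = self.make_traits(seed=3)
        traits["extinct_2010"] = True
        with pytest.raises(DataError):
            DR.extinction_model(traits)


class TestAdjustedPseudoR2:
    def test_improves_toward_one_as_fit_saturates(self):
        y, X = simulate_logistic(200, 1, seed=5, beta=[0.0, 6.0])
        fit = DR.fit_binomial_glm(y, X)
        assert DR.adjusted_pseudo_r2(fit) > 0.5

    def test_hand_computed_toy(self):
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1], float)  # not separable in x
        X = pd.DataFrame({"x": [0.1, 0.4, 0.9, 0.2, 0.8, 0.7, 0.95, 0.3]})
        fit = DR.fit_binomial_glm(y, X)
        r2 = 1 - fit.deviance / fit.null_deviance
        expect = 1 - (1 - r2) * 7 / 6
        assert DR.adjusted_pseudo_r2(fit) == pytest.approx(expect, abs=1e-12)


def orthogonal_design(n, seed):
    rng = np.random.default_rng(seed)
    M = rng.normal(0, 1, (n, 3))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    return pd.DataFrame(Q * np.sqrt(n), columns=["A", "B", "C"])


class TestCommonalityPartition:
    def test_orthogonal_predictors_no_sharing(self):
        X = orthogonal_design(400, seed=6)
        rng = np.random.default_rng(7)
        y = 1.0 * X["A"] + 0.5 * X["B"] + rng.normal(0, 1, 400)
        part = DR.commonality_partition(y, X, family="gaussian")
        for key in ("AB", "AC", "BC", "ABC"):
            assert abs(part.fractions[key]) < 0.02
        assert part.pure("A") > part.pure("B") > 0

    def test_single_driver_gets_everything(self):
        X = orthogonal_design(300, seed=8)
        y = 2.0 * X["A"].to_numpy()
        part = DR.commonality_partition(y, X, family="gaussian")
        assert part.pure("A") == pytest.approx(part.total_adj_r2, abs=0.02)
        assert abs(part.pure("B")) < 0.02

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_sum_identity(self, family):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(0, 1, (80, 3)), columns=list("ABC"))
        if family == "gaussian":
            y = X.sum(axis=1).to_numpy() + rng.normal(0, 1, 80)
        else:
            y = (rng.random(80) < expit(X["A"])).astype(float)
        part = DR.commonality_partition(y, X, family=family)
        assert abs(sum(part.fractions.values()) - part.total_adj_r2) < 1e-10
        assert part.residual == pytest.approx(1 - part.total_adj_r2)

    def test_symmetric_under_relabelling(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(0, 1, (60, 3)), columns=list("ABC"))
        y = X["A"].to_numpy() - X["C"].to_numpy() + rng.normal(0, 0.5, 60)
        p1 = DR.commonality_partition(y, X, family="gaussian")
        p2 = DR.commonality_partition(y, X[["C", "A", "B"]], family="gaussian")
        assert p1.pure("A") == pytest.approx(p2.pure("A"), abs=1e-12)
        assert p1.fractions["ABC"] == pytest.approx(p2.fractions["ABC"], abs=1e-12)


VARPART_R = """
suppressMessages(library(vegan))
d <- read.csv(commandArgs(TRUE)[1])
p <- varpart(d$y, ~A, ~B, ~C, data = d)
f <- p$part$indfract$Adj.R.square
cat(f[1], f[2], f[3], p$part$fract$Adj.R.square[7], sep = ",")
"""


def test_gaussian_partition_matches_vegan_varpart(tmp_path):
    rng = np.random.default_rng(11)
    X = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("ABC"))
    X["B"] += 0.5 * X["A"]  # induce shared structure
    y = X["A"].to_numpy() + 0.5 * X["B"].to_numpy() + rng.normal(0, 1, 50)
    part = DR.commonality_partition(y, X, family="gaussian")

    df = X.copy()
    df["y"] = y
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "vp.R"
    script.write_text(VARPART_R)
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv)],
        capture_output=True, text=True, check=True,
    )
    pure_a, pure_b, pure_c, total = map(float, out.stdout.strip().split(","))
    assert part.pure("A") == pytest.approx(pure_a, abs=1e-6)
    assert part.pure("B") == pytest.approx(pure_b, abs=1e-6)
    assert part.pure("C") == pytest.approx(pure_c, abs=1e-6)
    assert part.total_adj_r2 == pytest.approx(total, abs=1e-6)


class TestLocalDrivers:
    def make_records(self, n=24, sigma=1.0, b=-2.0, seed=12):
        rng = np.random.default_rng(seed)
        rec = pd.DataFrame(
            {
                "d_closeness": rng.normal(0, 1, n),
                "d_conductivity": rng.normal(0, 2, n),
                "d_log_area": rng.normal(-0.3, 0.3, n),
            },
            index=pd.Index([f"P{i}" for i in range(n)], name="pond_id"),
        )
        rec["d_richness"] = b * rec["d_closeness"] + rng.normal(0, sigma, n)
        return rec

    def test_constructed_signal_recovered(self):
        res = DR.local_drivers_analysis(self.make_records(sigma=0.05))
        assert res.partition.largest_pure() == "d_closeness"
        assert res.partition.pure("d_closeness") > 0.9
        assert res.pvalues["d_closeness"] < 1e-6
        assert res.slopes["d_closeness"] == pytest.approx(-2.0, abs=0.1)

    def test_null_fractions_small(self):
        res = DR.local_drivers_analysis(self.make_records(n=200, b=0.0, seed=13))
        for name in ("d_closeness", "d_conductivity", "d_log_area"):
            assert abs(res.partition.pure(name)) < 0.05

    def test_too_few_records_errors(self):
        with pytest.raises(DataError):
            DR.local_drivers_analysis(self.make_records(n=7))
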