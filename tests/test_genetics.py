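"""Animal-model REML, LS means and derived genetic parameters."""

import numpy as np
import pandas as pd
import pytest

from colosig import genetics
from colosig.simdata import SimConfig, gene_drop, simulate_pedigree


def simulate_halfsib_records(ped, daughters, s2a, s2e, seed):
    rng = np.random.default_rng(seed)
    bv = gene_drop(ped, [[s2a]], rng)["bv_IgG"].to_numpy()
    y = bv + rng.normal(0, np.sqrt(s2e), len(ped)) + 100.0
    rec = pd.DataFrame({"animal": ped.animals, "y": y})
    return rec[rec["animal"].isin(daughters)].reset_index(drop=True)


class TestDeriveRatios:
    def test_heritability_arithmetic(self):
        out = genetics.derive_ratios([[15.0]], [[85.0]])
        assert out["h2"][0] == pytest.approx(0.15)

    def test_zero_genetic_covariance(self):
        out = genetics.derive_ratios(
            [[10.0, 0.0], [0.0, 5.0]], [[20.0, 3.0], [3.0, 10.0]]
        )
        assert out["r_a"] == 0.0

    def test_hand_computed_genetic_correlation(self):
        G0 = [[57.3, 40.0], [40.0, 34.0]]
        out = genetics.derive_ratios(G0, np.eye(2))
        assert out["r_a"] == pytest.approx(40.0 / np.sqrt(57.3 * 34.0), abs=1e-12)
        assert out["r_a"] == pytest.approx(0.906, abs=1e-3)


class TestLsMeans:
    def test_balanced_two_by_two(self):
        # balanced design: LS means equal raw marginal means
        df = pd.DataFrame(
            {
                "a": ["x", "x", "y", "y"] * 10,
                "b": ["p", "q", "p", "q"] * 10,
                "y": np.tile([1.0, 2.0, 3.0, 4.0], 10),
            }
        )
        lsm, anova = genetics.fit_univariate_lsmeans(df, "y", ("a", "b"))
        means_a = dict(zip(lsm["a"]["level"], lsm["a"]["lsmean"]))
        assert means_a["x"] == pytest.approx(1.5)
        assert means_a["y"] == pytest.approx(3.5)

    def test_simulated_parity_shift_recovered(self):
        rng = np.random.default_rng(0)
        n = 400
        parity = rng.choice(["1", "2", "3"], size=n)
        herd = rng.choice(["A", "B"], size=n)
        shift = np.where(parity == "3", 20.0, 0.0)
        y = 90 + shift + rng.normal(0, 10, n)
        df = pd.DataFrame({"parity": parity, "herd": herd, "y": y})
        lsm, anova = genetics.fit_univariate_lsmeans(df, "y", ("parity", "herd"))
        m = dict(zip(lsm["parity"]["level"], lsm["parity"]["lsmean"]))
        se = lsm["parity"]["se"].max()
        assert abs((m["3"] - m["1"]) - 20.0) < 4 * se
        assert anova.loc["C(parity, Sum)", "PR(>F)"] < 1e-6


class TestUnivariateREML:
    def test_matches_halfsib_anova(self, halfsib_design):
        """REML additive variance equals 4x the ANOVA sire component."""
        ped, daughters = halfsib_design
        rec = simulate_halfsib_records(ped, daughters, 40.0, 60.0, seed=2)
        vals = rec["y"].to_numpy().reshape(30, 12)
        msb = 12 * vals.mean(axis=1).var(ddof=1)
        msw = vals.var(axis=1, ddof=1).mean()
        anova_s2a = 4 * (msb - msw) / 12
        est = genetics.AnimalModelREML(
            traits=("y",), fixed_effects=(), tol_loglik=1e-11, tol_param=1e-9
        ).fit(rec, ped)
        assert est.G0_[0, 0] == pytest.approx(anova_s2a, abs=1e-4)

    def test_zero_genetic_variance_bounded_at_zero(self, halfsib_design):
        ped, daughters = halfsib_design
        rec = simulate_halfsib_records(ped, daughters, 0.0, 100.0, seed=5)
        est = genetics.AnimalModelREML(traits=("y",), fixed_effects=()).fit(rec, ped)
        assert 0.0 <= est.h2_[0] < 0.05

    def test_loglik_path_nondecreasing(self, halfsib_design):
        ped, daughters = halfsib_design
        rec = simulate_halfsib_records(ped, daughters, 40.0, 60.0, seed=3)
        est = genetics.AnimalModelREML(traits=("y",), fixed_effects=()).fit(rec, ped)
        path = est.loglik_path_
        assert np.all(np.diff(path) >= -1e-8)


@pytest.fixture(scope="module")
def bivariate_fit():
    cfg = SimConfig(seed=13, n_founders=150, n_generations=2)
    ped = simulate_pedigree(cfg)
    G0 = np.array([[40.0, 18.0], [18.0, 20.0]])
    R0 = np.array([[60.0, 25.0], [25.0, 50.0]])
    rng = np.random.default_rng(77)
    bv = gene_drop(ped, G0, rng).iloc[:, 1:].to_numpy()
    e = rng.standard_normal((len(ped), 2)) @ np.linalg.cholesky(R0).T
    herd = rng.integers(0, 4, len(ped))
    y = 50 + bv + e + 4.0 * herd[:, None]
    rec = pd.DataFrame(
        {"animal": ped.animals, "herd": herd, "t1": y[:, 0], "t2": y[:, 1]}
    )
    rec.loc[rng.random(len(ped)) < 0.25, "t2"] = np.nan  # missing one trait
    return ped, rec


class TestBivariateREML:
    def test_converges_with_missing_records(self, bivariate_fit):
        ped, rec = bivariate_fit
        est = genetics.AnimalModelREML(
            traits=("t1", "t2"), fixed_effects=("herd",)
        ).fit(rec, ped)
        assert est.converged_
        assert -1.0 <= est.r_a_ <= 1.0
        assert -1.0 <= est.r_p_ <= 1.0
        assert np.all((est.h2_ >= 0) & (est.h2_ <= 1))
        assert est.se_["r_p"] > 0

    def test_rescaling_invariance(self, bivariate_fit):
        """x100 rescaling scales variances by 1e4, leaves ratios alone."""
        ped, rec = bivariate_fit
        base = genetics.AnimalModelREML(
            traits=("t1", "t2"), fixed_effects=("herd",)
        ).fit(rec, ped)
        scaled = genetics.AnimalModelREML(
            traits=("t1", "t2"), fixed_effects=("herd",),
            rescale={"t1": 100.0, "t2": 100.0},
        ).fit(rec, ped)
        assert scaled.G0_[0, 0] == pytest.approx(1e4 * base.G0_[0, 0], rel=1e-3)
        assert scaled.h2_[0] == pytest.approx(base.h2_[0], abs=1e-4)
        assert scaled.r_a_ == pytest.approx(base.r_a_, abs=1e-4)
        assert scaled.r_p_ == pytest.approx(base.r_p_, abs=1e-4)

    def test_too_few_records_raises(self):
        ped = simulate_pedigree(SimConfig(n_founders=3, n_generations=0))
        rec = pd.DataFrame({"animal": ped.animals, "t1": np.arange(3.0)})
        with pytest.raises(genetics.RemlError):
            genetics.AnimalModelREML(traits=("t1",), fixed_effects=()).fit(rec, ped)
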