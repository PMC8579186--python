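"""Synthetic-data generator: structure, moments, determinism."""

import numpy as np
import pytest

from colosig.pedigree import build_a_matrix
from colosig.simdata import (
    SimConfig,
    SimError,
    component_signatures,
    gene_drop,
    gene_drop_replicates,
    season_of_month,
    simulate_dataset,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_spectra,
)
from tests.conftest import COARSE_WL, random_pedigree


class TestPedigreeGeneration:
    def test_founders_only(self):
        ped = simulate_pedigree(SimConfig(n_founders=10, n_generations=0))
        assert len(ped) == 10
        assert (ped.records[["sire", "dam"]] == 0).all().all()

    def test_one_generation_counts(self):
        cfg = SimConfig(
            n_founders=4, n_generations=1, dams_per_sire=1, offspring_per_dam=1
        )
        ped = simulate_pedigree(cfg)
        assert len(ped) == 6
        offspring = ped.records[ped.records["sire"] != 0]
        assert len(offspring) == 2
        assert (offspring["dam"] != 0).all()

    def test_offspring_born_after_parents(self):
        ped = simulate_pedigree(SimConfig(n_founders=20, n_generations=2, seed=3))
        gen = dict(zip(ped.records["animal"], ped.records["generation"]))
        for row in ped.records.itertuples():
            if row.sire != 0:
                assert gen[row.sire] < row.generation
                assert gen[row.dam] < row.generation

    def test_deterministic_under_seed(self):
        a = simulate_pedigree(SimConfig(seed=9)).records
        b = simulate_pedigree(SimConfig(seed=9)).records
        assert a.equals(b)

    def test_invalid_counts(self):
        with pytest.raises(SimError):
            SimConfig(n_founders=0)


class TestGeneDrop:
    def test_zero_variance_gives_zero_bvs(self):
        ped = simulate_pedigree(SimConfig(n_founders=10, n_generations=1))
        bv = gene_drop(ped, np.zeros((3, 3)), 0)
        assert np.allclose(bv.iloc[:, 1:], 0.0)

    def test_full_sib_covariance(self):
        """Empirical full-sib covariance matches A = 0.5 (tabular oracle)."""
        import pandas as pd

        from colosig.pedigree import Pedigree

        ped = Pedigree(
            pd.DataFrame(
                {"animal": [1, 2, 3, 4], "sire": [0, 0, 1, 1], "dam": [0, 0, 2, 2]}
            )
        )
        A = build_a_matrix(ped)
        assert A[2, 3] == 0.5
        draws = gene_drop_replicates(ped, 1.0, 40_000, rng=0)
        emp = np.cov(draws[:, 2], draws[:, 3])[0, 1]
        assert emp == pytest.approx(0.5, abs=0.02)

    def test_parent_offspring_covariance(self):
        import pandas as pd

        from colosig.pedigree import Pedigree

        ped = Pedigree(
            pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})
        )
        draws = gene_drop_replicates(ped, 2.0, 40_000, rng=1)
        emp = np.cov(draws[:, 0], draws[:, 2])[0, 1]
        assert emp == pytest.approx(0.5 * 2.0, abs=0.04)

    def test_non_psd_rejected(self):
        ped = simulate_pedigree(SimConfig(n_founders=4, n_generations=0))
        with pytest.raises(SimError):
            gene_drop(ped, [[1.0, 2.0], [2.0, 1.0]], 0)


class TestPhenotypes:
    def test_deterministic_structure_without_noise(self):
        """Zero residual + zero fixed effects: phenotype = mean + BV."""
        zeros = dict(
            herd_effects=np.zeros((9, 3)),
            parity_effects=np.zeros((5, 3)),
            season_effects=np.zeros((4, 3)),
        )
        cfg = SimConfig(
            seed=4, n_founders=30, n_generations=1,
            R0_true=np.zeros((3, 3)), **zeros,
        )
        ped = simulate_pedigree(cfg)
        bv = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
        ph = simulate_phenotypes(ped, bv, cfg)
        expected = cfg.base_means[0] + bv["bv_IgG"].to_numpy()
        floored = ph["IgG_floored"].to_numpy()
        assert np.allclose(ph["IgG"].to_numpy()[~floored], expected[~floored])

    def test_igg_moments_near_targets(self):
        """Grand IgG mean and SD land within 3% of 91.77 / 36.47 at n~700."""
        cfg = SimConfig(seed=11)
        ped = simulate_pedigree(cfg)
        bv = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
        ph = simulate_phenotypes(ped, bv, cfg)
        assert len(ph) > 600
        assert ph["IgG"].mean() == pytest.approx(91.77, rel=0.03)
        assert ph["IgG"].std() == pytest.approx(36.47, rel=0.03)

    def test_season_mapping(self):
        assert season_of_month(12) == "winter"
        assert season_of_month(2) == "winter"
        assert season_of_month(5) == "spring"
        assert season_of_month(8) == "summer"
        assert season_of_month(11) == "autumn"

    def test_midparent_offspring_regression_recovers_h2(self):
        """Realised heritability matches G/(G+R) = 0.15 at large n."""
        cfg = SimConfig(seed=2, n_founders=600, n_generations=1)
        ped = simulate_pedigree(cfg)
        g = float(cfg.G0_true[0, 0])
        r = float(cfg.R0_true[0, 0])
        rng = cfg.rng("oracle")
        bv = gene_drop(ped, [[g]], rng)["bv_IgG"].to_numpy()
        y = bv + rng.normal(0, np.sqrt(r), len(ped))
        rec = ped.records
        idx = ped._index
        kids = rec[rec["sire"] != 0]
        mid = 0.5 * (
            y[[idx[s] for s in kids["sire"]]] + y[[idx[d] for d in kids["dam"]]]
        )
        child = y[[idx[a] for a in kids["animal"]]]
        slope = np.polyfit(mid, child, 1)[0]
        # E[slope] = h2; SE ~ sqrt((1 - h2^2/2)/n)/sd ratio, n ~ 600
        assert slope == pytest.approx(g / (g + r), abs=0.08)


class TestSpectra:
    def test_noiseless_single_component(self):
        cfg = SimConfig(
            seed=0, n_founders=4, n_generations=0,
            wavelengths=COARSE_WL, noise_sd=0.0,
        )
        ped = simulate_pedigree(cfg)
        bv = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
        ph = simulate_phenotypes(ped, bv, cfg)
        sig = {"IgG": np.exp(-(((COARSE_WL - 1500) / 100) ** 2))}
        sp = simulate_spectra(ph, cfg, signatures=sig, scatter=False)
        X = sp.drop(columns=["animal"]).to_numpy()
        expected = np.outer(ph["IgG"], sig["IgG"])
        assert np.allclose(X, expected)

    def test_regression_recovers_concentrations(self, clean_dataset):
        """OLS of IgG on low-noise unscattered spectra has R2 > 0.99."""
        X, y = clean_dataset["X"], clean_dataset["y"]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(X)), X]), y, rcond=None
        )
        fitted = np.column_stack([np.ones(len(X)), X]) @ coef
        ss_res = np.sum((y - fitted) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_standard_grid_width(self):
        cfg = SimConfig(seed=0, n_founders=2, n_generations=0)
        ped = simulate_pedigree(cfg)
        bv = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
        ph = simulate_phenotypes(ped, bv, cfg)
        sp = simulate_spectra(ph, cfg)
        assert sp.shape[1] == 4201  # animal id + 4200 wavelengths
        assert np.isfinite(sp.drop(columns=["animal"]).to_numpy()).all()

    def test_grid_mismatch_rejected(self):
        cfg = SimConfig(seed=0, n_founders=2, n_generations=0, wavelengths=COARSE_WL)
        ped = simulate_pedigree(cfg)
        bv = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
        ph = simulate_phenotypes(ped, bv, cfg)
        with pytest.raises(SimError, match="grid"):
            simulate_spectra(ph, cfg, signatures={"IgG": np.ones(10)})


class TestDatasetAssembly:
    def test_reproducible_and_consistent(self):
        cfg = SimConfig(seed=21, n_founders=20, n_generations=1, wavelengths=COARSE_WL)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        for key in a:
            assert a[key].equals(b[key])
        assert list(a["phenotypes"]["animal"]) == list(a["spectra"]["animal"])

    def test_signatures_cover_components(self):
        sigs = component_signatures(COARSE_WL)
        assert set(sigs) >= {"IgG", "IgA", "IgM", "water", "fat"}
        for s in sigs.values():
            assert len(s) == len(COARSE_WL) and (s >= 0).all()
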