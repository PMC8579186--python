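"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from colosig.pedigree import Pedigree
from colosig.simdata import (
    SimConfig,
    gene_drop,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_spectra,
)

#: coarse wavelength grid (840 points) for tests where spectral width
#: is irrelevant; the full 4200-point grid is exercised separately
COARSE_WL = np.arange(400.0, 2500.0, 2.5)


@pytest.fixture(scope="session")
def clean_dataset():
    """Small no-scatter dataset: 120 animals, coarse grid."""
    cfg = SimConfig(seed=0, n_founders=60, n_generations=1, wavelengths=COARSE_WL)
    ped = simulate_pedigree(cfg)
    bvs = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
    phen = simulate_phenotypes(ped, bvs, cfg)
    spectra = simulate_spectra(phen, cfg, scatter=False)
    X = spectra.drop(columns=["animal"]).to_numpy()
    return dict(pedigree=ped, phenotypes=phen, X=X, y=phen["IgG"].to_numpy())


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Exactly clean dataset: no scatter, zero spectral noise."""
    cfg = SimConfig(
        seed=0, n_founders=60, n_generations=1, wavelengths=COARSE_WL, noise_sd=0.0
    )
    ped = simulate_pedigree(cfg)
    bvs = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
    phen = simulate_phenotypes(ped, bvs, cfg)
    spectra = simulate_spectra(phen, cfg, scatter=False)
    X = spectra.drop(columns=["animal"]).to_numpy()
    return dict(pedigree=ped, phenotypes=phen, X=X, y=phen["IgG"].to_numpy())


@pytest.fixture(scope="session")
def scattered_dataset():
    """Dataset with full multiplicative/additive scatter, coarse grid."""
    cfg = SimConfig(seed=1, n_founders=120, n_generations=1, wavelengths=COARSE_WL)
    ped = simulate_pedigree(cfg)
    bvs = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
    phen = simulate_phenotypes(ped, bvs, cfg)
    spectra = simulate_spectra(phen, cfg)
    X = spectra.drop(columns=["animal"]).to_numpy()
    return dict(pedigree=ped, phenotypes=phen, X=X, y=phen["IgG"].to_numpy())


@pytest.fixture(scope="session")
def halfsib_design():
    """Balanced paternal half-sib design: 30 sires x 12 daughters."""
    rows, sires = [], []
    aid = 1
    for _ in range(30):
        rows.append((aid, 0, 0))
        sires.append(aid)
        aid += 1
    daughters = []
    for s in sires:
        for _ in range(12):
            rows.append((aid, s, 0))
            daughters.append(aid)
            aid += 1
    ped = Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
    return ped, np.asarray(daughters)


def random_pedigree(n: int, seed: int) -> Pedigree:
    """Random overlapping pedigree of ``n`` animals (founder prob 0.3)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n + 1):
        if i <= 2 or rng.random() < 0.3:
            rows.append((i, 0, 0))
        else:
            s, d = rng.choice(np.arange(1, i), size=2, replace=False)
            rows.append((i, int(s), int(d)))
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
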