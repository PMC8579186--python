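"""Synthetic colostrum dataset generator.

Produces, under one seed, every input the downstream pipeline consumes:

* a Holstein-like multi-generation pedigree,
* true breeding values by gene drop consistent with ``var(a) = A G0``,
* immunoglobulin phenotypes (IgG, IgA, IgM, g/L) with herd, parity and
  calving-season fixed effects,
* NIR spectra as noisy linear mixtures of smooth component signatures
  with multiplicative/additive scatter (so scatter corrections and
  derivatives are non-trivial),
* RID plates whose ring diameters follow a chosen standard-curve model
  with multiplicative CV noise.

Default moments target the field data the pipeline emulates: IgG mean
91.77 g/L and SD 36.47 (IgA 4.80/3.03, IgM 5.07/2.44), heritabilities
0.15/0.13/0.24, nine herds, parity classes 1-4 and 5+ (pooling parities
5-8) with proportions 28.9/29.7/18.4/12.1/10.9%, and seasons derived
from the calving month (winter = Dec-Feb, spring = Mar-May, summer =
Jun-Aug, autumn = Sep-Nov).  The fixed-effect level shifts are chosen
first and the genetic/residual variances are then solved so that the
marginal mean and SD hit their targets — see ``docs/methods.md``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from colosig import rid as rid_mod
from colosig.pedigree import Pedigree, build_a_matrix
from colosig.preprocess import STANDARD_WAVELENGTHS

TRAITS = ("IgG", "IgA", "IgM")

#: target marginal moments (g/L) and heritabilities
TRAIT_MEANS = np.array([91.77, 4.80, 5.07])
TRAIT_SDS = np.array([36.47, 3.03, 2.44])
TRAIT_H2 = np.array([0.15, 0.13, 0.24])

#: genetic correlations among the three reference analytes
GENETIC_CORR = {("IgG", "IgA"): 0.220, ("IgG", "IgM"): 0.401, ("IgA", "IgM"): 0.144}
#: phenotypic correlations among the three reference analytes
PHENOTYPIC_CORR = {("IgG", "IgA"): 0.554, ("IgG", "IgM"): 0.603, ("IgA", "IgM"): 0.520}

#: parity-class proportions for classes 1, 2, 3, 4, 5+ (5+ pools 5-8)
PARITY_PROPORTIONS = np.array([0.289, 0.297, 0.184, 0.121, 0.109])
PARITY_CLASSES = ("1", "2", "3", "4", "5-8")

SEASONS = ("winter", "spring", "summer", "autumn")
_MONTH_TO_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: fixed-effect level shifts (g/L) per trait, rows = levels
PARITY_EFFECTS = np.array(
    [
        [-13.41, -1.90, -0.58],
        [-15.09, -0.72, -0.65],
        [6.22, 0.72, 0.84],
        [9.62, 0.90, 0.19],
        [12.62, 1.02, 0.21],
    ]
)
SEASON_EFFECTS = np.array(
    [
        [-5.99, -0.18, -0.32],
        [-4.07, -0.38, -0.38],
        [2.97, 0.11, 0.42],
        [7.07, 0.46, 0.28],
    ]
)
N_HERDS = 9
HERD_EFFECTS = np.column_stack(
    [
        np.linspace(-10.0, 10.0, N_HERDS),
        np.linspace(-0.8, 0.8, N_HERDS),
        np.linspace(-0.6, 0.6, N_HERDS),
    ]
)

#: floor for truncated negative concentrations (g/L)
CONCENTRATION_FLOOR = 0.1


class SimError(ValueError):
    pass


def season_of_month(month: int) -> str:
    return _MONTH_TO_SEASON[int(month)]


def _fixed_effect_moments() -> tuple[np.ndarray, np.ndarray]:
    """Mean shift and variance contributed by the fixed effects per trait.

    Parity levels are drawn with :data:`PARITY_PROPORTIONS`; herd and
    calving month (hence season) uniformly.
    """
    season_w = np.array([3, 3, 3, 3]) / 12.0  # equal months per season
    herd_w = np.full(N_HERDS, 1.0 / N_HERDS)
    mean = np.zeros(3)
    var = np.zeros(3)
    for eff, w in (
        (PARITY_EFFECTS, PARITY_PROPORTIONS),
        (SEASON_EFFECTS, season_w),
        (HERD_EFFECTS, herd_w),
    ):
        m = w @ eff
        mean += m
        var += w @ (eff**2) - m**2
    return mean, var


def default_covariances() -> tuple[np.ndarray, np.ndarray]:
    """Solve 3x3 G0 (additive) and R0 (residual) from the target moments.

    Per trait: ``sigma2_p = SD^2 - Var(fixed)``, split by the target
    heritability.  Off-diagonals come from the genetic correlations
    (G0) and from phenotypic-minus-genetic covariance (R0).
    """
    _, var_fixed = _fixed_effect_moments()
    s2p = TRAIT_SDS**2 - var_fixed
    if np.any(s2p <= 0):
        raise SimError("fixed-effect variance exceeds target phenotypic variance")
    s2a = TRAIT_H2 * s2p
    s2e = s2p - s2a
    G0 = np.diag(s2a).astype(float)
    R0 = np.diag(s2e).astype(float)
    idx = {t: i for i, t in enumerate(TRAITS)}
    for (t1, t2), rg in GENETIC_CORR.items():
        i, j = idx[t1], idx[t2]
        cov_a = rg * np.sqrt(s2a[i] * s2a[j])
        cov_p = PHENOTYPIC_CORR[(t1, t2)] * np.sqrt(s2p[i] * s2p[j])
        G0[i, j] = G0[j, i] = cov_a
        R0[i, j] = R0[j, i] = cov_p - cov_a
    for name, M in (("G0", G0), ("R0", R0)):
        if np.min(np.linalg.eigvalsh(M)) < -1e-8:
            raise SimError(f"default {name} not positive semidefinite")
    return G0, R0


def default_base_means() -> np.ndarray:
    """Intercepts such that marginal trait means hit their targets."""
    mean_fixed, _ = _fixed_effect_moments()
    return TRAIT_MEANS - mean_fixed


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Generator configuration; defaults state the emulated population."""

    n_founders: int = 192
    n_generations: int = 3
    dams_per_sire: int = 4
    offspring_per_dam: int = 2
    G0_true: np.ndarray = field(default_factory=lambda: default_covariances()[0])
    R0_true: np.ndarray = field(default_factory=lambda: default_covariances()[1])
    base_means: np.ndarray = field(default_factory=default_base_means)
    herd_effects: np.ndarray = field(default_factory=lambda: HERD_EFFECTS.copy())
    parity_effects: np.ndarray = field(default_factory=lambda: PARITY_EFFECTS.copy())
    season_effects: np.ndarray = field(default_factory=lambda: SEASON_EFFECTS.copy())
    wavelengths: np.ndarray = field(default_factory=lambda: STANDARD_WAVELENGTHS.copy())
    scatter_slope_sd: float = 0.3
    scatter_offset_sd: float = 0.1
    scatter_drift_sd: float = 0.1
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "dams_per_sire", "offspring_per_dam"):
            v = getattr(self, name)
            if name != "n_generations" and v < 1:
                raise SimError(f"{name} must be >= 1")
            if name == "n_generations" and v < 0:
                raise SimError("n_generations must be >= 0")
        for name, M in (("G0_true", self.G0_true), ("R0_true", self.R0_true)):
            M = np.asarray(M, dtype=float)
            if not np.allclose(M, M.T):
                raise SimError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-8:
                raise SimError(f"{name} must be positive semidefinite")
            setattr(self, name, M)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent child stream per generator stage.

        Uses a CRC32 of the stream name (process-stable, unlike ``hash``)
        as the spawn key so sub-generators are disjoint and reproducible.
        """
        key = zlib.crc32(stream.encode()) % (2**31)
        seq = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(seq)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation hierarchical pedigree.

    Founders (generation 0) have unknown parents and alternate sexes.
    Each later generation mates the previous generation's females in
    groups of ``dams_per_sire`` to distinct sires, ``offspring_per_dam``
    offspring each, giving paternal half-sib families nested over full-sib
    families, the classical dairy structure.
    """
    rng = cfg.rng("pedigree")
    rows = []
    next_id = 1
    males: list[int] = []
    females: list[int] = []
    for _ in range(cfg.n_founders):
        sex = "M" if next_id % 2 else "F"
        (males if sex == "M" else females).append(next_id)
        rows.append((next_id, 0, 0, 0, sex))
        next_id += 1
    for gen in range(1, cfg.n_generations + 1):
        dams = list(rng.permutation(females))
        sire_pool = list(rng.permutation(males))
        if not sire_pool or not dams:
            raise SimError("generation with no available sires or dams")
        males, females = [], []
        for block_start in range(0, len(dams), cfg.dams_per_sire):
            sire = sire_pool[(block_start // cfg.dams_per_sire) % len(sire_pool)]
            for dam in dams[block_start : block_start + cfg.dams_per_sire]:
                for _ in range(cfg.offspring_per_dam):
                    sex = "M" if rng.random() < 0.5 else "F"
                    (males if sex == "M" else females).append(next_id)
                    rows.append((next_id, sire, dam, gen, sex))
                    next_id += 1
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "sex"])
    return Pedigree(df)


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------


def gene_drop(
    pedigree: Pedigree, G0_true, rng: np.random.Generator | int = 0
) -> pd.DataFrame:
    """Drop true breeding values through the pedigree.

    Founders draw from ``MVN(0, G0)``; an offspring's vector is the
    parent average plus a Mendelian-sampling deviation with covariance
    ``d_i * G0`` where ``d_i = 1 - 0.25 (1 + F_s) - 0.25 (1 + F_d)``
    (each unknown parent drops its term), so that across replicates
    ``cov(a_i, a_j) -> A_ij * G0``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    G0 = np.atleast_2d(np.asarray(G0_true, dtype=float))
    k = G0.shape[0]
    if np.min(np.linalg.eigvalsh(G0)) < -1e-8:
        raise SimError("G0_true must be positive semidefinite")
    n = len(pedigree)
    df = pedigree.records
    idx = pedigree._index
    sires = np.array([idx.get(s, -1) for s in df["sire"]])
    dams = np.array([idx.get(d, -1) for d in df["dam"]])
    F = np.diag(build_a_matrix(pedigree)) - 1.0
    # eigendecomposition handles PSD-but-singular G0 (e.g. the zero matrix)
    w, V = np.linalg.eigh(G0)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    a = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = sires[i], dams[i]
        mean = np.zeros(k)
        d_i = 1.0
        if s >= 0:
            mean += 0.5 * a[s]
            d_i -= 0.25 * (1.0 + F[s])
        if d >= 0:
            mean += 0.5 * a[d]
            d_i -= 0.25 * (1.0 + F[d])
        a[i] = mean + np.sqrt(d_i) * (root @ z[i])
    cols = [f"bv_{t}" for t in (TRAITS[:k] if k <= 3 else range(k))]
    out = pd.DataFrame(a, columns=cols)
    out.insert(0, "animal", df["animal"].to_numpy())
    return out


def gene_drop_replicates(
    pedigree: Pedigree, sigma2_a: float, n_replicates: int, rng=0
) -> np.ndarray:
    """Vectorised scalar gene drop: ``(n_replicates, n_animals)`` draws.

    Same recursion as :func:`gene_drop` for a single trait, run for many
    independent replicates at once so the empirical covariance of
    breeding values can be compared against the relationship matrix.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if sigma2_a < 0:
        raise SimError("sigma2_a must be non-negative")
    n = len(pedigree)
    df = pedigree.records
    idx = pedigree._index
    sires = np.array([idx.get(s, -1) for s in df["sire"]])
    dams = np.array([idx.get(d, -1) for d in df["dam"]])
    F = np.diag(build_a_matrix(pedigree)) - 1.0
    a = np.zeros((n_replicates, n))
    z = rng.standard_normal((n_replicates, n))
    sd = np.sqrt(sigma2_a)
    for i in range(n):
        s, d = sires[i], dams[i]
        mean = 0.0
        d_i = 1.0
        if s >= 0:
            mean = mean + 0.5 * a[:, s]
            d_i -= 0.25 * (1.0 + F[s])
        if d >= 0:
            mean = mean + 0.5 * a[:, d]
            d_i -= 0.25 * (1.0 + F[d])
        a[:, i] = mean + np.sqrt(d_i) * sd * z[:, i]
    return a


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    pedigree: Pedigree, breeding_values: pd.DataFrame, cfg: SimConfig
) -> pd.DataFrame:
    """Ig phenotypes = base mean + fixed effects + breeding value + residual.

    Every animal receives one record (a simulation convenience: each
    animal stands for a cow with one colostrum sample).  Herd and calving
    month are uniform; parity classes follow the stated proportions;
    season is derived from the calving month.  Negative concentrations
    are floored at 0.1 g/L and flagged.
    """
    rng = cfg.rng("phenotypes")
    n = len(pedigree)
    herd = rng.integers(0, cfg.herd_effects.shape[0], size=n)
    parity = rng.choice(len(PARITY_CLASSES), size=n, p=PARITY_PROPORTIONS)
    month = rng.integers(1, 13, size=n)
    season_names = np.array([season_of_month(m) for m in month])
    season = np.array([SEASONS.index(s) for s in season_names])
    bv = breeding_values[[f"bv_{t}" for t in TRAITS]].to_numpy()
    w, V = np.linalg.eigh(cfg.R0_true)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    resid = rng.standard_normal((n, 3)) @ root.T
    y = (
        cfg.base_means[None, :]
        + cfg.herd_effects[herd]
        + cfg.parity_effects[parity]
        + cfg.season_effects[season]
        + bv
        + resid
    )
    floored = y < CONCENTRATION_FLOOR
    y = np.where(floored, CONCENTRATION_FLOOR, y)
    out = pd.DataFrame(
        {
            "animal": pedigree.records["animal"].to_numpy(),
            "herd": herd + 1,
            "parity": [PARITY_CLASSES[p] for p in parity],
            "calving_month": month,
            "season": season_names,
        }
    )
    for j, t in enumerate(TRAITS):
        out[t] = y[:, j]
        out[f"{t}_floored"] = floored[:, j]
    return out


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

_SIGNATURE_BUMPS = {
    # component -> (centre nm, width nm, amplitude) triples; smooth
    # Gaussian mixtures standing in for real absorbance signatures
    "IgG": [(1450, 120, 0.0020), (1940, 90, 0.0032), (2180, 70, 0.0024), (980, 60, 0.0010)],
    "IgA": [(1510, 100, 0.030), (2050, 80, 0.024), (1200, 90, 0.016)],
    "IgM": [(1680, 110, 0.026), (2290, 60, 0.020), (900, 80, 0.012)],
    "water": [(1440, 140, 0.30), (1930, 120, 0.45), (760, 60, 0.08)],
    "fat": [(1720, 50, 0.18), (2310, 45, 0.22), (1210, 60, 0.10)],
}


def component_signatures(wavelengths) -> dict[str, np.ndarray]:
    """Smooth synthetic absorbance signatures on the given grid."""
    wl = np.asarray(wavelengths, dtype=float)
    sigs = {}
    for name, bumps in _SIGNATURE_BUMPS.items():
        s = np.zeros_like(wl)
        for centre, width, amp in bumps:
            s += amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        sigs[name] = s
    return sigs


def simulate_spectra(
    phenotypes: pd.DataFrame,
    cfg: SimConfig,
    signatures: dict[str, np.ndarray] | None = None,
    scatter: bool = True,
) -> pd.DataFrame:
    """log(1/R) spectra as scattered noisy mixtures of the signatures.

    ``spectrum = (sum_k conc_k sig_k) * m + b * drift + c + noise`` with
    multiplicative factor ``m = exp(N(0, slope_sd))``, a quadratic drift
    term and an additive offset.  Ig concentrations come from the
    phenotype table; nuisance components (water, fat) vary around 1.
    """
    rng = cfg.rng("spectra")
    wl = np.asarray(cfg.wavelengths, dtype=float)
    sigs = component_signatures(wl) if signatures is None else signatures
    for name, s in sigs.items():
        if len(s) != len(wl):
            raise SimError(f"signature {name!r} not on the configured grid")
    n = len(phenotypes)
    conc = {t: phenotypes[t].to_numpy() for t in TRAITS if t in phenotypes}
    for nuisance in ("water", "fat"):
        if nuisance in sigs:
            conc[nuisance] = 1.0 + 0.2 * rng.standard_normal(n)
    clean = np.zeros((n, len(wl)))
    for name, c in conc.items():
        if name in sigs:
            clean += np.outer(c, sigs[name])
    if scatter:
        m = np.exp(cfg.scatter_slope_sd * rng.standard_normal(n))
        offset = cfg.scatter_offset_sd * rng.standard_normal(n)
        drift_coef = cfg.scatter_drift_sd * rng.standard_normal(n)
    else:
        m = np.ones(n)
        offset = np.zeros(n)
        drift_coef = np.zeros(n)
    tnorm = (wl - wl[0]) / (wl[-1] - wl[0])
    drift = tnorm**2
    X = clean * m[:, None] + np.outer(drift_coef, drift) + offset[:, None]
    X += cfg.noise_sd * rng.standard_normal(X.shape)
    out = pd.DataFrame(X, columns=[f"{w:.1f}" for w in wl])
    out.insert(0, "animal", phenotypes["animal"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# RID plates
# ---------------------------------------------------------------------------


def simulate_rid_plate(
    concentrations,
    curve: rid_mod.StandardCurve,
    cv_percent: float = 0.0,
    rng: np.random.Generator | int = 0,
    sample_ids=None,
    replicates: int = 1,
) -> rid_mod.RidPlate:
    """One RID plate for the given sample concentrations (g/L).

    Reference wells carry the kit sera; sample wells hold each diluted
    concentration perturbed by multiplicative CV noise and mapped to a
    ring diameter through the inverse standard curve.  ``replicates``
    plates each sample in several wells (e.g. quintuplicate for the
    precision study); plate capacity (21 sample wells) is enforced.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    conc = np.asarray(concentrations, dtype=float)
    if conc.size * replicates > rid_mod.PLATE_CAPACITY:
        raise rid_mod.RidError(
            f"{conc.size * replicates} sample wells exceed capacity "
            f"{rid_mod.PLATE_CAPACITY}"
        )
    analyte = curve.analyte
    dilution = rid_mod.DILUTION_FACTOR[analyte]
    sera = rid_mod.REFERENCE_SERA[analyte]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(conc.size)]
    rows = []
    for j, c in enumerate(sera):
        rows.append(
            dict(well_id=f"R{j + 1}", role="reference", sample_id=None,
                 known_conc=c, diameter=float(curve.diameter(c)))
        )
    well = 0
    for sid, c in zip(sample_ids, conc):
        well_conc = c / dilution
        lo, _ = curve.kit_range
        for _ in range(replicates):
            noisy = well_conc * (1.0 + cv_percent / 100.0 * rng.standard_normal())
            noisy = max(noisy, lo * 1e-3)  # keep the inverse curve defined
            rows.append(
                dict(well_id=f"W{well + 1}", role="sample", sample_id=sid,
                     known_conc=np.nan, diameter=float(curve.diameter(noisy)))
            )
            well += 1
    wells = pd.DataFrame(rows)
    for rule in rid_mod.QC_RULES:
        wells[rule] = False
    return rid_mod.RidPlate(analyte=analyte, wells=wells)


def default_standard_curve(analyte: str = "IgG", model: str = "mancini") -> rid_mod.StandardCurve:
    """A plausible per-plate curve covering the kit's diluted range."""
    sera = rid_mod.REFERENCE_SERA[analyte]
    if model == "mancini":
        # diameters ~4-10 mm across the kit span
        slope = (max(sera) - min(sera) * 0.5) / (10.0**2 - 4.0**2)
        intercept = min(sera) * 0.5 - slope * 4.0**2
    else:
        slope = (np.log10(max(sera)) - np.log10(min(sera))) / (10.0 - 4.0)
        intercept = np.log10(min(sera)) - slope * 4.0
    return rid_mod.StandardCurve(
        model, float(intercept), float(slope), analyte, rid_mod.default_kit_range(analyte)
    )


# ---------------------------------------------------------------------------
# full dataset + disk layout
# ---------------------------------------------------------------------------


def simulate_dataset(cfg: SimConfig) -> dict[str, pd.DataFrame]:
    """Pedigree, truth, phenotypes and spectra under one configuration."""
    ped = simulate_pedigree(cfg)
    bvs = gene_drop(ped, cfg.G0_true, cfg.rng("genedrop"))
    phen = simulate_phenotypes(ped, bvs, cfg)
    spectra = simulate_spectra(phen, cfg)
    return {
        "pedigree": ped.records[["animal", "sire", "dam"]],
        "truth": bvs,
        "phenotypes": phen,
        "spectra": spectra,
    }


def write_dataset(dataset: dict[str, pd.DataFrame], outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in dataset.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
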