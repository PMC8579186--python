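"""End-to-end study orchestration.

Mirrors the full analysis chain on a dataset laid out as the generator
writes it: calibration/validation split stratified by parity (28%
calibration), model development over the pretreatment grid per trait
(with reduced 80%/60% calibration subsets for IgG), prediction of the
validation set with applicability-domain filtering, bivariate animal
model REML of reference vs predicted concentrations, and deterministic
selection-response scenarios built from the estimated parameters.

Every removal and exclusion (assay QC, calibration outlier passes,
GH/NH prediction filters) is logged with its reason so the sample
accounting of a run can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from colosig import genetics, mpls, selection, simdata
from colosig.pedigree import Pedigree
from colosig.preprocess import PretreatmentSpec, default_grid

#: reduced-grid option for quick runs: one code per scatter family
SMALL_GRID = [
    PretreatmentSpec("none", (0, 0, 1, 1)),
    PretreatmentSpec("snv", (2, 5, 5, 1)),
    PretreatmentSpec("msc", (2, 5, 5, 1)),
]


@dataclass
class PipelineConfig:
    """Knobs of the full study; defaults state the emulated design."""

    seed: int = 1
    traits: tuple[str, ...] = ("IgG", "IgA", "IgM")
    split_fraction: float = 0.28
    subset_fractions: tuple[float, ...] = (1.0, 0.8, 0.6)  # IgG only
    grid: str = "full"  # "full" (25 treatments) or "small"
    max_lv: int = 16
    n_groups: int = 20
    outlier_thresholds: mpls.OutlierThresholds = field(
        default_factory=mpls.OutlierThresholds
    )
    gh_max: float = 3.5
    nh_max: float = 2.0
    predicted_records: str = "validation"  # or "all"
    rescale_x100: tuple[str, ...] = ("IgA", "IgM")
    reml_max_iter: int = 200
    progeny_group_small: int = 30
    progeny_group_large: int = 120
    daughters_for_ratio: int = 70
    intensity: float = 1.76


def load_dataset(datadir) -> dict:
    datadir = Path(datadir)
    ped = Pedigree.read_csv(datadir / "pedigree.csv")
    phen = pd.read_csv(datadir / "phenotypes.csv")
    spectra = pd.read_csv(datadir / "spectra.csv")
    return {"pedigree": ped, "phenotypes": phen, "spectra": spectra}


def run_simulate(cfg: simdata.SimConfig, outdir) -> dict:
    """Generate and write the synthetic dataset."""
    ds = simdata.simulate_dataset(cfg)
    simdata.write_dataset(ds, outdir)
    return ds


def _subset_rows(cal_rows: np.ndarray, strata: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Stratified (herd x parity) subset of the calibration rows."""
    if fraction >= 1.0:
        return cal_rows
    assign = mpls.stratified_split(strata[cal_rows], fraction=fraction, seed=rng)
    return cal_rows[assign == "calibration"]


def run_full_study(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    spectra: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the complete analysis; returns a dict of report tables.

    Keys: ``split`` (assignment), ``calibration`` (fit statistics per
    trait/subset), ``leaderboards``, ``predictions``, ``genetics``
    (REML summary per trait/subset), ``scenarios`` (selection-response
    table), ``response_ratios`` (calibration-subset study ratios) and
    ``accounting`` (n in/removed/excluded per stage).
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    phen = phenotypes.reset_index(drop=True)
    X_all = spectra.drop(columns=["animal"]).to_numpy(dtype=float)
    if not np.array_equal(spectra["animal"].to_numpy(), phen["animal"].to_numpy()):
        raise ValueError("spectra and phenotypes must be aligned on animal")

    assignment = mpls.stratified_split(
        phen["parity"].to_numpy(), cfg.split_fraction, rng
    )
    cal_rows = np.flatnonzero(assignment == "calibration")
    val_rows = np.flatnonzero(assignment == "validation")
    herd_parity = (
        phen["herd"].astype(str) + "x" + phen["parity"].astype(str)
    ).to_numpy()

    grid = default_grid() if cfg.grid == "full" else SMALL_GRID
    calib_rows_out, leaderboards, predictions, genetics_rows, accounting = (
        [], {}, {}, [], []
    )
    ratio_rows = []
    models: dict[str, mpls.CalibrationModel] = {}
    h2_ref_igg = None
    sigma_a_goal = None
    scen_inputs = {}

    for trait in cfg.traits:
        fractions = cfg.subset_fractions if trait == "IgG" else (1.0,)
        for frac in fractions:
            label = f"{trait}_{int(frac * 100)}"
            sub = _subset_rows(cal_rows, herd_parity, frac, rng)
            y = phen[trait].to_numpy(dtype=float)
            model, board = mpls.develop_model(
                X_all[sub], y[sub], grid=grid, max_lv=cfg.max_lv,
                n_groups=cfg.n_groups, seed=cfg.seed,
                thresholds=cfg.outlier_thresholds,
            )
            model.gh_max, model.nh_max = cfg.gh_max, cfg.nh_max
            models[label] = model
            leaderboards[label] = board
            retained = sub[model.retained_rows]
            cal_pred = model.predict(X_all[retained])
            cal_stats = mpls.fit_statistics(cal_pred["prediction"], y[retained])
            val_pred = model.predict(X_all[val_rows])
            val_pred.insert(0, "animal", phen.loc[val_rows, "animal"].to_numpy())
            predictions[label] = val_pred
            keep = ~val_pred["excluded"].to_numpy()
            val_stats = mpls.fit_statistics(
                val_pred.loc[keep, "prediction"], y[val_rows][keep]
            )
            calib_rows_out.append(
                dict(
                    trait=trait, subset=frac, n_calibration=len(retained),
                    mean=cal_stats.mean, sd=cal_stats.sd,
                    treatment=model.spec.label, n_lv=model.n_lv,
                    rmse_c=cal_stats.rmse, r2_c=cal_stats.r2,
                    rmse_cv=model.rmse_cv,
                    rmse_v=val_stats.rmse, r2_v=val_stats.r2,
                    relative_rmse_v=val_stats.relative_rmse,
                )
            )
            accounting.append(
                dict(
                    stage=f"calibration_{label}", n_in=len(sub),
                    n_removed=int(len(sub) - len(retained)),
                    n_excluded_prediction=int((~keep).sum()),
                )
            )

            # bivariate REML: reference vs prediction
            pred_col = f"pred_{label}"
            rec = phen[["animal", "parity", "season", "herd", trait]].copy()
            rec = rec.rename(columns={trait: f"ref_{trait}"})
            pred_map = dict(
                zip(val_pred.loc[keep, "animal"], val_pred.loc[keep, "prediction"])
            )
            if cfg.predicted_records == "all":
                cal_keep = ~cal_pred["excluded"].to_numpy()
                pred_map.update(
                    dict(
                        zip(
                            phen.loc[retained[cal_keep], "animal"],
                            cal_pred.loc[cal_keep, "prediction"],
                        )
                    )
                )
            rec[pred_col] = rec["animal"].map(pred_map)
            scale = 100.0 if trait in cfg.rescale_x100 else 1.0
            est = genetics.AnimalModelREML(
                traits=(f"ref_{trait}", pred_col),
                fixed_effects=("parity", "season", "herd"),
                rescale={f"ref_{trait}": scale, pred_col: scale},
                max_iter=cfg.reml_max_iter,
            ).fit(rec, pedigree)
            genetics_rows.append(
                dict(
                    trait=trait, subset=frac,
                    h2_ref=est.h2_[0], se_h2_ref=est.se_[f"h2_ref_{trait}"],
                    h2_pred=est.h2_[1], se_h2_pred=est.se_[f"h2_{pred_col}"],
                    r_p=est.r_p_, se_r_p=est.se_["r_p"],
                    r_a=est.r_a_, se_r_a=est.se_["r_a"],
                    n_iter=est.n_iter_,
                )
            )
            if trait == "IgG":
                ratio_rows.append(
                    dict(
                        subset=frac,
                        response_ratio=selection.correlated_response_ratio(
                            1.0, est.r_a_, cfg.daughters_for_ratio,
                            est.h2_[1], est.h2_[0],
                        ),
                    )
                )
                if frac == 1.0:
                    h2_ref_igg = float(est.h2_[0])
                    h2_pred_igg = float(est.h2_[1])
                    r_g_igg = float(est.r_a_)
                    sigma_a_goal = float(np.sqrt(est.G0_[0, 0]))
                    scen_inputs = dict(
                        h2_ref=h2_ref_igg, h2_pred=h2_pred_igg, r_g=r_g_igg
                    )

    # scenario engine from the estimated IgG parameters (base + I-III)
    scenario_table = None
    if h2_ref_igg is not None:
        n1, n2 = cfg.progeny_group_small, cfg.progeny_group_large
        scenarios = {
            "base": dict(
                criterion="reference IgG", n=n1,
                acc_bulls=selection.accuracy_progeny_test(n1, h2_ref_igg),
                acc_dams=selection.accuracy_own_performance(h2_ref_igg),
            ),
            "I": dict(
                criterion="reference IgG", n=n2,
                acc_bulls=selection.accuracy_progeny_test(n2, h2_ref_igg),
                acc_dams=selection.accuracy_own_performance(h2_ref_igg),
            ),
            "II": dict(
                criterion="NIR IgG", n=n1,
                acc_bulls=selection.accuracy_correlated_criterion(
                    selection.accuracy_progeny_test(n1, h2_pred_igg), r_g_igg
                ),
                acc_dams=selection.accuracy_correlated_criterion(
                    selection.accuracy_own_performance(h2_pred_igg), r_g_igg
                ),
            ),
            "III": dict(
                criterion="NIR IgG", n=n2,
                acc_bulls=selection.accuracy_correlated_criterion(
                    selection.accuracy_progeny_test(n2, h2_pred_igg), r_g_igg
                ),
                acc_dams=selection.accuracy_correlated_criterion(
                    selection.accuracy_own_performance(h2_pred_igg), r_g_igg
                ),
            ),
        }
        scenario_table = selection.run_scenarios(
            scenarios, i=cfg.intensity, sigma_a=sigma_a_goal
        )

    return {
        "split": pd.DataFrame({"animal": phen["animal"], "set": assignment}),
        "calibration": pd.DataFrame(calib_rows_out),
        "leaderboards": leaderboards,
        "predictions": predictions,
        "models": models,
        "genetics": pd.DataFrame(genetics_rows),
        "response_ratios": pd.DataFrame(ratio_rows),
        "scenarios": scenario_table,
        "scenario_inputs": scen_inputs,
        "accounting": pd.DataFrame(accounting),
    }


def write_report(report: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("split", "calibration", "genetics", "response_ratios", "scenarios", "accounting"):
        df = report.get(key)
        if isinstance(df, pd.DataFrame):
            df.to_csv(outdir / f"{key}.csv", index=False)
    for label, board in report.get("leaderboards", {}).items():
        board.to_csv(outdir / f"leaderboard_{label}.csv", index=False)
    for label, pred in report.get("predictions", {}).items():
        pred.to_csv(outdir / f"predictions_{label}.csv", index=False)
    for label, model in report.get("models", {}).items():
        (outdir / f"model_{label}.json").write_text(model.to_json())
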