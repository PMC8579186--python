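"""Radial immunodiffusion (RID) reference-assay arithmetic.

A 24-well RID plate carries three reference sera of known concentration
plus up to 21 diluted colostrum samples.  After the 24-h endpoint the
precipitin ring diameter of each well is converted to a concentration
through a per-plate standard curve fitted to the reference sera.  Two
classical curve models are provided:

* ``mancini`` — endpoint regime, concentration linear in squared
  diameter: ``conc = intercept + slope * d**2`` (the default, matching a
  24-h incubation endpoint read);
* ``fahey`` — timed regime, ``log10(conc) = intercept + slope * d``.

Well-level concentrations are multiplied back by the dilution factor
(1:5 for IgG, 1:3 for IgA and IgM).  Assay precision is summarised by the
intra-assay coefficient of variation, the average of per-sample
replicate CVs; values below 10% justify single-well determination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANALYTES = ("IgG", "IgA", "IgM")

#: dilution factors applied before plating (v/v)
DILUTION_FACTOR = {"IgG": 5.0, "IgA": 3.0, "IgM": 3.0}

#: kit reference-serum concentrations, g/L (well level, already diluted)
REFERENCE_SERA = {
    "IgG": (1.80, 14.72, 28.03),
    "IgA": (0.53, 1.94, 3.87),
    "IgM": (0.62, 2.00, 3.81),
}

#: maximum number of colostrum samples on a 24-well plate
PLATE_CAPACITY = 21

#: QC rules that set a well to missing
QC_RULES = ("no_signal", "weak_ring", "elliptical")

#: CV threshold (percent) below which single-well reads are acceptable
CV_PRECISION_THRESHOLD = 10.0


class RidError(ValueError):
    pass


def default_kit_range(analyte: str) -> tuple[float, float]:
    """Well-level detection range: reference-sera span widened by 20%."""
    sera = REFERENCE_SERA[analyte]
    return (min(sera) * 0.8, max(sera) * 1.2)


@dataclass
class StandardCurve:
    """Per-plate standard curve mapping ring diameter to concentration."""

    model: str
    intercept: float
    slope: float
    analyte: str
    kit_range: tuple[float, float]
    r_squared: float = 1.0

    def concentration(self, diameter) -> np.ndarray:
        """Well-level concentration (before dilution back-correction)."""
        d = np.asarray(diameter, dtype=float)
        if self.model == "mancini":
            return self.intercept + self.slope * d**2
        return 10.0 ** (self.intercept + self.slope * d)

    def diameter(self, well_conc) -> np.ndarray:
        """Inverse map, used when simulating plates."""
        c = np.asarray(well_conc, dtype=float)
        if self.model == "mancini":
            arg = (c - self.intercept) / self.slope
            if np.any(arg <= 0):
                raise RidError("concentration below curve support")
            return np.sqrt(arg)
        return (np.log10(c) - self.intercept) / self.slope


@dataclass
class RidPlate:
    """One 24-well plate: 3 reference wells and up to 21 sample wells.

    ``wells`` columns: ``well_id``, ``role`` ('reference'/'sample'),
    ``sample_id``, ``known_conc`` (reference wells; NaN otherwise),
    ``diameter`` (mm) and one boolean column per QC rule.
    """

    analyte: str
    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise RidError(f"unknown analyte {self.analyte!r}")
        roles = self.wells["role"]
        if int((roles == "reference").sum()) != 3:
            raise RidError("a plate must carry exactly 3 reference wells")
        n_samples = int((roles == "sample").sum())
        if n_samples > PLATE_CAPACITY:
            raise RidError(
                f"{n_samples} sample wells exceed plate capacity {PLATE_CAPACITY}"
            )
        meas = self.wells["diameter"].dropna()
        if (meas <= 0).any():
            raise RidError("measured diameters must be positive")

    @property
    def reference_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "reference"]

    @property
    def sample_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "sample"]


def fit_standard_curve(
    reference_points,
    model: str = "mancini",
    analyte: str = "IgG",
    kit_range: tuple[float, float] | None = None,
) -> StandardCurve:
    """Least-squares standard curve through the three reference sera.

    ``reference_points`` is a sequence of ``(concentration, diameter)``
    pairs (well level).  With exactly collinear points the least-squares
    line reduces to exact interpolation.
    """
    pts = np.asarray(reference_points, dtype=float)
    if pts.shape != (3, 2):
        raise RidError("a standard curve needs exactly 3 (conc, diameter) points")
    conc, diam = pts[:, 0], pts[:, 1]
    if len(np.unique(diam)) < 3:
        raise RidError("degenerate reference diameters (ties)")
    if model == "mancini":
        x, y = diam**2, conc
    elif model == "fahey":
        if np.any(conc <= 0):
            raise RidError("fahey model needs positive concentrations")
        x, y = diam, np.log10(conc)
    else:
        raise RidError(f"unknown curve model {model!r}")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise RidError("standard curve slope must be positive")
    resid = y - (intercept + slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    if kit_range is None:
        kit_range = default_kit_range(analyte)
    return StandardCurve(model, float(intercept), float(slope), analyte, kit_range, r2)


def diameter_to_concentration(
    curve: StandardCurve, diameter: float, dilution_factor: float | None = None
) -> tuple[float, str | None]:
    """Ring diameter to sample concentration (g/L).

    Returns ``(value, flag)``; a well-level concentration outside the kit
    range yields ``(nan, "out_of_range")``.
    """
    if diameter <= 0:
        raise RidError("diameter must be positive")
    if dilution_factor is None:
        dilution_factor = DILUTION_FACTOR[curve.analyte]
    well = float(curve.concentration(diameter))
    lo, hi = curve.kit_range
    if not (lo <= well <= hi):
        return float("nan"), "out_of_range"
    return well * dilution_factor, None


def qc_filter(measurements: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four QC exclusion rules.

    ``measurements`` needs a ``value`` column plus boolean columns for the
    well-level rules in :data:`QC_RULES` and (optionally) an
    ``out_of_range`` flag produced by the curve conversion.  Flagged
    values are set to missing; retained values are never altered.
    Returns the filtered copy and per-rule exclusion counts.
    """
    out = measurements.copy()
    counts: dict[str, int] = {}
    for rule in (*QC_RULES, "out_of_range"):
        if rule not in out.columns:
            counts[rule] = 0
            continue
        mask = out[rule].fillna(False).astype(bool)
        counts[rule] = int(mask.sum())
        out.loc[mask, "value"] = np.nan
    return out, counts


@dataclass
class IntraAssayCV:
    cv_percent: float
    per_sample_cv: np.ndarray
    sufficiently_precise: bool


def intra_assay_cv(replicates) -> IntraAssayCV:
    """Intra-assay coefficient of variation.

    ``replicates`` is a (samples x replicates) array, by default four
    colostrum samples measured in quintuplicate.  The statistic is the
    mean over samples of ``sd / mean * 100`` with the n-1 SD divisor; a
    value below 10% is reported as sufficiently precise for single-well
    determination.
    """
    arr = np.asarray(replicates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise RidError("need a (samples x replicates>=2) array")
    means = arr.mean(axis=1)
    if np.any(means <= 0):
        raise RidError("replicate means must be positive")
    sds = arr.std(axis=1, ddof=1)
    per = sds / means * 100.0
    cv = float(per.mean())
    return IntraAssayCV(cv, per, cv < CV_PRECISION_THRESHOLD)


def process_plate(
    plate: RidPlate, model: str = "mancini", kit_range: tuple[float, float] | None = None
) -> tuple[pd.DataFrame, StandardCurve, dict[str, int]]:
    """Full per-plate workflow: fit curve, convert samples, apply QC.

    Returns a tidy table (``sample_id``, ``value`` in g/L with exclusions
    set to missing), the fitted curve, and QC exclusion counts.
    """
    ref = plate.reference_wells
    curve = fit_standard_curve(
        list(zip(ref["known_conc"], ref["diameter"])),
        model=model,
        analyte=plate.analyte,
        kit_range=kit_range,
    )
    rows = []
    for w in plate.sample_wells.itertuples(index=False):
        value, range_flag = diameter_to_concentration(curve, w.diameter)
        rows.append(
            {
                "sample_id": w.sample_id,
                "value": value,
                "out_of_range": range_flag is not None,
                **{rule: bool(getattr(w, rule, False)) for rule in QC_RULES},
            }
        )
    table = pd.DataFrame(rows)
    table, counts = qc_filter(table)
    return table[["sample_id", "value"]], curve, counts


def merge_plates(tables: list[pd.DataFrame], analyte: str) -> pd.DataFrame:
    """Concatenate per-plate sample tables into one per-animal column."""
    merged = pd.concat(tables, ignore_index=True)
    return merged.rename(columns={"value": analyte})
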