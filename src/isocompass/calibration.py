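"""GC-IRMS delta-scale calibration and methyl-group correction.

Raw instrument delta values become fatty-acid values on the
international scales (VPDB for delta13C, VSMOW for delta2H) in three
steps:

1. optional linear *drift* removal within an analytical sequence,
2. *scale normalization* by an ordinary least-squares line through
   certified FAME reference materials (three-point calibration with
   USGS70/71/72 by default),
3. *methylation correction* removing the methanol-derived methyl group
   by isotope mass balance:

   delta_FA = (n_FAME * delta_FAME - n_Me * delta_MeOH) / (n_FAME - n_Me)

   with n_FAME the total C (for 13C, n_Me = 1) or H (for 2H, n_Me = 3)
   atoms of the methyl ester.

The mass balance is linear in delta space; over the natural-abundance
range the deviation from exact atom-fraction bookkeeping is well below
0.1 per mil, the usual field practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fatty_acids import FattyAcid

__all__ = [
    "ReferenceStandard",
    "DEFAULT_STANDARDS",
    "MethanolReference",
    "CalibrationModel",
    "fit_normalization",
    "apply_normalization",
    "methylation_correct",
    "calibrate_peak_table",
]


@dataclass(frozen=True)
class ReferenceStandard:
    """A certified FAME isotope reference material (Me-C20:0)."""

    name: str
    accepted_d13C: float  # per mil VPDB
    accepted_d2H: float   # per mil VSMOW

    def accepted(self, isotope: str) -> float:
        if isotope == "13C":
            return self.accepted_d13C
        if isotope == "2H":
            return self.accepted_d2H
        raise ValueError(f"unknown isotope {isotope!r}")


DEFAULT_STANDARDS: dict[str, ReferenceStandard] = {
    "USGS70": ReferenceStandard("USGS70", -30.53, -183.9),
    "USGS71": ReferenceStandard("USGS71", -10.5, -4.9),
    "USGS72": ReferenceStandard("USGS72", -1.54, +348.3),
}


@dataclass(frozen=True)
class MethanolReference:
    """Delta values of the methanol used for FAME derivatization.

    These are lab-specific and must be measured; there is no defensible
    default, so the pipeline refuses to correct without them.
    """

    d13C: float
    d2H: float

    def delta(self, isotope: str) -> float:
        if isotope == "13C":
            return self.d13C
        if isotope == "2H":
            return self.d2H
        raise ValueError(f"unknown isotope {isotope!r}")


@dataclass
class CalibrationModel:
    """Fitted affine map from instrument scale to the reference scale."""

    isotope: str
    slope: float
    intercept: float
    drift_rate: float = 0.0  # per mil per run index, removed before scaling
    fit_residuals: dict[str, float] = field(default_factory=dict)

    def transform(self, delta_raw, run_index=None):
        x = np.asarray(delta_raw, dtype=float)
        if self.drift_rate != 0.0:
            if run_index is None:
                raise ValueError("model has a drift term; run_index required")
            x = x - self.drift_rate * np.asarray(run_index, dtype=float)
        return self.slope * x + self.intercept

    def inverse(self, delta_cal, run_index=None):
        x = (np.asarray(delta_cal, dtype=float) - self.intercept) / self.slope
        if self.drift_rate != 0.0 and run_index is not None:
            x = x + self.drift_rate * np.asarray(run_index, dtype=float)
        return x


def fit_normalization(
    measured: list[tuple],
    isotope: str,
    standards: dict[str, ReferenceStandard] | None = None,
) -> CalibrationModel:
    """Fit the scale-normalization line from reference-standard runs.

    Parameters
    ----------
    measured : list of (standard_name, delta_raw) or (standard_name, delta_raw, run_index)
        Repeated measurements of the certified standards, raw scale.
    isotope : {"13C", "2H"}
    standards : optional registry overriding the USGS70/71/72 defaults.

    With run indices supplied, a linear drift (slope of measured-minus-
    accepted on run index) is estimated first and removed from the
    measured values; the normalization line is then accepted ~ corrected
    OLS. Requires at least two distinct standards.
    """
    reg = standards or DEFAULT_STANDARDS
    names, raws, runs = [], [], []
    for row in measured:
        if len(row) == 3:
            name, raw, run = row
        else:
            name, raw = row
            run = np.nan
        if name not in reg:
            raise ValueError(f"unknown standard {name!r}; registered: {sorted(reg)}")
        names.append(name)
        raws.append(float(raw))
        runs.append(float(run) if run is not None else np.nan)
    if len(set(names)) < 2:
        raise ValueError(
            "need measurements of >= 2 distinct standards for normalization; "
            f"got {sorted(set(names))}")
    raws = np.asarray(raws)
    runs = np.asarray(runs)
    accepted = np.array([reg[n].accepted(isotope) for n in names])

    drift_rate = 0.0
    corrected = raws.copy()
    if np.isfinite(runs).all() and len(np.unique(runs)) > 1:
        # drift: systematic run-order trend of measured relative to accepted
        drift_rate = float(np.polyfit(runs, raws - accepted, 1)[0])
        if abs(drift_rate) < 1e-8:  # numerically zero: no drift term
            drift_rate = 0.0
        corrected = raws - drift_rate * runs

    if np.ptp(corrected) < 1e-12:
        raise ValueError("degenerate normalization: identical measured values")
    slope, intercept = np.polyfit(corrected, accepted, 1)
    if slope <= 0:
        raise ValueError(f"non-positive normalization slope ({slope:.4g})")
    pred = slope * corrected + intercept
    residuals: dict[str, float] = {}
    for name in sorted(set(names)):
        mask = np.array([n == name for n in names])
        residuals[name] = float(np.mean(accepted[mask] - pred[mask]))
    return CalibrationModel(isotope=isotope, slope=float(slope),
                            intercept=float(intercept), drift_rate=drift_rate,
                            fit_residuals=residuals)


def apply_normalization(model: CalibrationModel, peaks: pd.DataFrame,
                        run_index_col: str | None = None) -> pd.DataFrame:
    """Fill ``delta_cal`` (FAME, reference scale) for the model's isotope.

    Re-applying to rows that are already calibrated raises: the map is
    affine, so silently applying it twice would corrupt the scale.
    """
    out = peaks.copy()
    mask = out["isotope"].astype(str) == model.isotope
    if not mask.any():
        raise ValueError(f"no {model.isotope} rows to calibrate")
    if "delta_cal" in out.columns and out.loc[mask, "delta_cal"].notna().any():
        raise ValueError(
            f"{model.isotope} rows already calibrated; refusing to re-apply")
    if "delta_cal" not in out.columns:
        out["delta_cal"] = np.nan
    run = None
    if model.drift_rate != 0.0:
        if run_index_col is None or run_index_col not in out.columns:
            raise ValueError("model has a drift term; supply run_index_col")
        run = out.loc[mask, run_index_col].to_numpy(float)
    out.loc[mask, "delta_cal"] = model.transform(
        out.loc[mask, "delta_raw"].to_numpy(float), run)
    return out


def methylation_correct_value(delta_fame: float, fa: FattyAcid,
                              isotope: str, methanol: MethanolReference) -> float:
    """Mass-balance removal of the methanol methyl from one delta value."""
    if isotope == "13C":
        n_fame, n_me = fa.c_count_fame, 1
    elif isotope == "2H":
        n_fame, n_me = fa.h_count_fame, 3
    else:
        raise ValueError(f"unknown isotope {isotope!r}")
    if n_fame <= n_me:
        raise ValueError(f"{fa.code}: n_FAME ({n_fame}) must exceed n_Me ({n_me})")
    return (n_fame * delta_fame - n_me * methanol.delta(isotope)) / (n_fame - n_me)


def methylation_correct(peaks: pd.DataFrame, methanol: MethanolReference,
                        registry=None) -> pd.DataFrame:
    """Convert FAME-scale ``delta_cal`` to fatty-acid scale for all rows."""
    from .fatty_acids import DEFAULT_REGISTRY

    if methanol is None:
        raise ValueError("methanol reference values are required for correction")
    reg = registry or DEFAULT_REGISTRY
    out = peaks.copy()
    if "delta_cal" not in out.columns or out["delta_cal"].isna().any():
        raise ValueError("peaks must be scale-normalized (delta_cal) before correction")
    fas = {code: reg.parse(str(code)) for code in out["fa"].unique()}
    corrected = np.empty(len(out))
    for i, (code, iso, val) in enumerate(
            zip(out["fa"], out["isotope"], out["delta_cal"])):
        corrected[i] = methylation_correct_value(float(val), fas[str(code)],
                                                 str(iso), methanol)
    out["delta_cal"] = corrected
    return out


def calibrate_peak_table(
    peaks: pd.DataFrame,
    standard_runs: pd.DataFrame,
    methanol: MethanolReference,
    standards: dict[str, ReferenceStandard] | None = None,
    run_index_col: str | None = None,
    registry=None,
) -> tuple[pd.DataFrame, dict[str, CalibrationModel]]:
    """Full calibration: per-isotope normalization then methyl correction.

    *standard_runs* needs columns ``standard, isotope, delta_raw`` and
    optionally a run-index column.
    """
    models: dict[str, CalibrationModel] = {}
    out = peaks
    for isotope in sorted(peaks["isotope"].astype(str).unique()):
        runs = standard_runs[standard_runs["isotope"].astype(str) == isotope]
        triples = []
        for _, r in runs.iterrows():
            if run_index_col and run_index_col in runs.columns:
                triples.append((r["standard"], r["delta_raw"], r[run_index_col]))
            else:
                triples.append((r["standard"], r["delta_raw"]))
        model = fit_normalization(triples, isotope, standards)
        models[isotope] = model
        out = apply_normalization(model, out, run_index_col)
    out = methylation_correct(out, methanol, registry)
    return out, models
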