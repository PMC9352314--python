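"""End-to-end run orchestration with a declarative config and manifest.

A run executes validate -> calibrate -> feature matrix -> composites ->
repeatability -> canonical correlation -> per-tissue site assignment
(-> cross-year transfer when two years are present), writing each
stage's tables as CSV into the run directory plus a ``manifest.json``
recording the config hash, package versions, seeds, row counts and
warnings. Identical config and seeds give identical outputs.

Analyses are per tissue type by default; pooling tissues into one
feature matrix inflates within-site variance with tissue fractionation
and must be requested explicitly (``cross_tissue_pooled``).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import composites as comp
from . import discriminant as disc
from . import io as iio
from . import multivariate as mv
from . import repeatability as rep
from .calibration import MethanolReference, calibrate_peak_table
from .fatty_acids import CORE_PANEL

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    peaks: str = ""
    meta: str = ""
    sites: str = ""
    standard_runs: str = ""
    methanol_d13C: float | None = None
    methanol_d2H: float | None = None
    panel: tuple = CORE_PANEL
    pooling_map: dict = field(default_factory=dict)
    tolerance_km: float = 1.0
    n_boot_cv: int = 999
    n_boot_repeatability: int = 1000
    seed_cv: int = 7
    seed_repeatability: int = 42
    repeatability_variables: tuple = ()   # default: all panel features
    cross_tissue_pooled: bool = False
    output_dir: str = "run"

    def save(self, path) -> None:
        data = asdict(self)
        data["panel"] = list(data["panel"])
        data["repeatability_variables"] = list(data["repeatability_variables"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "panel" in data:
            data["panel"] = tuple(data["panel"])
        if "repeatability_variables" in data:
            data["repeatability_variables"] = tuple(data["repeatability_variables"])
        return cls(**data)

    def canonical_hash(self) -> str:
        data = asdict(self)
        data["panel"] = list(data["panel"])
        data["repeatability_variables"] = list(data["repeatability_variables"])
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _stage(manifest, name):
    manifest["stages"].append(name)
    return name


def run(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.canonical_hash(),
                "isocompass_version": __version__,
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
                "seeds": {"cv": config.seed_cv,
                          "repeatability": config.seed_repeatability},
                "stages": [], "rows": {}, "warnings": []}
    stage = "validate"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _stage(manifest, stage)
            peaks = iio.read_peak_table(config.peaks)
            meta = iio.read_sample_meta(config.meta)
            sites = iio.read_site_table(config.sites) if config.sites else None
            site_dist = iio.site_distances(sites) if sites is not None else None
            if site_dist is None and config.tolerance_km > 0:
                years = meta["year"].nunique()
                if years > 1:
                    raise ValueError(
                        "tolerance scoring requested but no site table given")
            manifest["rows"]["peaks"] = len(peaks)
            manifest["rows"]["meta"] = len(meta)

            stage = _stage(manifest, "calibrate")
            if config.standard_runs:
                if config.methanol_d13C is None or config.methanol_d2H is None:
                    raise ValueError("methanol delta values required for calibration")
                std = iio.read_table(config.standard_runs)
                methanol = MethanolReference(config.methanol_d13C,
                                             config.methanol_d2H)
                peaks, models = calibrate_peak_table(peaks, std, methanol)
                pd.DataFrame(
                    [(i, m.slope, m.intercept, m.drift_rate)
                     for i, m in sorted(models.items())],
                    columns=["isotope", "slope", "intercept", "drift_rate"],
                ).to_csv(out / "calibration_models.csv", index=False)
            elif "delta_cal" not in peaks.columns:
                raise ValueError("peaks are uncalibrated and no standards given")
            peaks.to_csv(out / "calibrated_peaks.csv", index=False)

            stage = _stage(manifest, "features")
            matrix, report = iio.build_feature_matrix(peaks, meta, config.panel)
            manifest["rows"]["feature_matrix"] = report.n_samples
            manifest["rows"]["dropped_incomplete"] = len(report.dropped_samples)
            matrix.to_csv(out / "features.csv")

            stage = _stage(manifest, "composites")
            bulk = comp.bulk_delta_table(peaks)
            diffs = comp.pair_difference(matrix, "2H", "LIN", "ALA")
            bulk.to_csv(out / "composites.csv", index=False)
            corr_rows = []
            for iso in iio.ISOTOPES:
                tab = comp.correlate_with_bulk(matrix, bulk, iso)
                tab.insert(0, "isotope", iso)
                corr_rows.append(tab)
            pd.concat(corr_rows).to_csv(out / "bulk_correlations.csv", index=False)
            diffs.to_frame().to_csv(out / "lin_ala_difference.csv")

            stage = _stage(manifest, "repeatability")
            variables = (list(config.repeatability_variables)
                         or list(matrix.columns))
            covs = tuple(c for c in ("taxon", "year") if meta[c].nunique() > 1)
            rtab = rep.repeatability_table(
                matrix, meta, variables, by_tissue=not config.cross_tissue_pooled,
                fixed_covariates=covs, n_boot=config.n_boot_repeatability,
                seed=config.seed_repeatability)
            rtab.to_csv(out / "repeatability.csv", index=False)

            stage = _stage(manifest, "cca")
            x_cols = [c for c in matrix.columns if c.endswith("_13C")]
            y_cols = [c for c in matrix.columns if c.endswith("_2H")]
            cca = mv.canonical_correlation(matrix[x_cols], matrix[y_cols])
            tests = mv.wilks_lambda_test(cca)
            pd.DataFrame({"dimension": np.arange(1, len(cca.correlations) + 1),
                          "correlation": cca.correlations}).to_csv(
                out / "cca_correlations.csv", index=False)
            tests.to_csv(out / "cca_dimension_tests.csv", index=False)
            cca.x_scores.to_csv(out / "cca_scores_13C.csv")
            cca.y_scores.to_csv(out / "cca_scores_2H.csv")

            stage = _stage(manifest, "assignment")
            meta_idx = meta.set_index("sample_id")
            first_year = int(meta["year"].min())
            acc_rows, assign_frames = [], []
            for tissue in sorted(meta["tissue"].unique()):
                sids = meta_idx.index[(meta_idx["tissue"] == tissue)
                                      & (meta_idx["year"] == first_year)]
                sub = matrix.loc[matrix.index.intersection(sids)]
                labels = meta_idx.loc[sub.index, "site_id"]
                if config.pooling_map:
                    labels = disc.pool_sites(labels, config.pooling_map)
                if labels.nunique() < 2 or len(sub) <= labels.nunique() * 2:
                    manifest["warnings"].append(
                        f"assignment skipped for {tissue}: too few samples")
                    continue
                cv = disc.bootstrap_cv_accuracy(sub, labels,
                                                n_boot=config.n_boot_cv,
                                                seed=config.seed_cv)
                acc_rows.append((tissue, cv.resubstitution, cv.accuracy,
                                 cv.ci_low, cv.ci_high))
                model = disc.fit_lda(sub, labels)
                scores = model.scores(sub)
                scores["site_id"] = labels.to_numpy()
                scores.to_csv(out / f"lda_scores_{tissue}.csv")
                a = disc.predict(model, sub, true_labels=labels)
                a.insert(1, "tissue", tissue)
                assign_frames.append(
                    a[["sample_id", "tissue", "true_site", "predicted_site",
                       "correct", "tie"]])
            pd.DataFrame(acc_rows, columns=["tissue", "resubstitution",
                                            "cv_accuracy", "ci_low",
                                            "ci_high"]).to_csv(
                out / "assignment_accuracy.csv", index=False)
            if assign_frames:
                assignments = pd.concat(assign_frames, ignore_index=True)
                assignments.to_csv(out / "assignments.csv", index=False)
                consensus = disc.consensus_assign(assignments, meta)
                consensus.to_csv(out / "consensus.csv", index=False)
                manifest["rows"]["consensus_fish"] = len(consensus)

            years = sorted(meta["year"].unique())
            if len(years) == 2:
                stage = _stage(manifest, "cross_year")
                rows = []
                for tissue in sorted(meta["tissue"].unique()):
                    m_t = meta_idx[meta_idx["tissue"] == tissue]
                    tr = matrix.loc[matrix.index.intersection(
                        m_t.index[m_t["year"] == years[0]])]
                    te = matrix.loc[matrix.index.intersection(
                        m_t.index[m_t["year"] == years[1]])]
                    if len(tr) == 0 or len(te) == 0:
                        continue
                    try:
                        res = disc.cross_year_predict(
                            tr, meta_idx.loc[tr.index, "site_id"],
                            te, meta_idx.loc[te.index, "site_id"],
                            site_dist=site_dist,
                            tolerance_km=config.tolerance_km)
                    except ValueError as err:
                        manifest["warnings"].append(
                            f"cross-year skipped for {tissue}: {err}")
                        continue
                    res.confusion.to_csv(out / f"confusion_{tissue}.csv")
                    rows.append((tissue, res.exact_accuracy,
                                 res.tolerant_accuracy))
                pd.DataFrame(rows, columns=["tissue", "exact_accuracy",
                                            "tolerant_accuracy"]).to_csv(
                    out / "cross_year_accuracy.csv", index=False)
            manifest["warnings"].extend(
                sorted({str(w.message) for w in caught}))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
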