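"""Reading, validating and writing the tabular artifacts.

Everything is plain delimited text (comma- or tab-separated, sniffed
from the header line) and lives in tidy :class:`pandas.DataFrame`
containers:

peak table
    one row per identified FAME peak per isotope run:
    ``sample_id, fa, isotope, delta_raw[, delta_cal], mass_fraction``.
sample metadata
    ``sample_id, fish_id, taxon, tissue, site_id, year``.
site table
    ``site_id, altitude`` plus either ``x_km, y_km`` coordinates or an
    explicit square distance matrix; optional ``pool_label``.
feature matrix
    samples x (fatty acid, isotope) wide table used by every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fatty_acids import CORE_PANEL, DEFAULT_REGISTRY, FattyAcidRegistry

__all__ = [
    "ISOTOPES",
    "TISSUES",
    "read_table",
    "read_peak_table",
    "write_peak_table",
    "read_sample_meta",
    "read_site_table",
    "site_distances",
    "validate_peak_table",
    "validate_sample_meta",
    "build_feature_matrix",
    "feature_column",
    "split_feature_column",
    "FeatureMatrixReport",
]

ISOTOPES = ("13C", "2H")
TISSUES = ("muscle", "brain", "liver", "eye")

_PEAK_REQUIRED = ("sample_id", "fa", "isotope", "delta", "mass_fraction")
_META_REQUIRED = ("sample_id", "fish_id", "taxon", "tissue", "site_id", "year")


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_table(path) -> pd.DataFrame:
    """Read a delimited text file, auto-detecting comma vs tab."""
    return pd.read_csv(path, sep=_sniff_sep(path))


def validate_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Validate a peak table in place and return it.

    Raises ``ValueError`` on a missing required column, an unknown
    isotope label, a non-numeric or missing delta, a negative mass
    fraction, or duplicated ``(sample_id, fa, isotope)`` keys.
    """
    missing = [c for c in _PEAK_REQUIRED
               if c not in peaks.columns and not (c == "delta" and "delta_raw" in peaks.columns)]
    if missing:
        raise ValueError(f"peak table missing required column(s): {missing}")
    if "delta" in peaks.columns and "delta_raw" not in peaks.columns:
        peaks = peaks.rename(columns={"delta": "delta_raw"})
    bad_iso = sorted(set(peaks["isotope"].astype(str)) - set(ISOTOPES))
    if bad_iso:
        raise ValueError(
            f"unknown isotope label(s) {bad_iso}; allowed isotopes: {list(ISOTOPES)}")
    delta = pd.to_numeric(peaks["delta_raw"], errors="coerce")
    if delta.isna().any():
        rows = peaks.index[delta.isna()].tolist()[:5]
        raise ValueError(f"non-numeric or missing delta values at rows {rows}")
    peaks["delta_raw"] = delta.astype(float)
    mf = pd.to_numeric(peaks["mass_fraction"], errors="coerce")
    if mf.isna().any() or (mf < 0).any():
        raise ValueError("mass_fraction must be numeric and >= 0")
    peaks["mass_fraction"] = mf.astype(float)
    key = ["sample_id", "fa", "isotope"]
    dup = peaks.duplicated(key, keep=False)
    if dup.any():
        keys = peaks.loc[dup, key].drop_duplicates().head(5).to_records(index=False)
        raise ValueError(f"duplicate (sample, fa, isotope) rows, e.g. {list(keys)}")
    return peaks


def read_peak_table(path, registry: FattyAcidRegistry | None = None) -> pd.DataFrame:
    """Read and validate a peak table; fatty-acid names must all parse."""
    peaks = validate_peak_table(read_table(path))
    reg = registry or DEFAULT_REGISTRY
    for code in peaks["fa"].unique():
        reg.parse(str(code))
    return peaks


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing required column(s): {missing}")
    bad_tissue = sorted(set(meta["tissue"].astype(str)) - set(TISSUES))
    if bad_tissue:
        raise ValueError(f"unknown tissue(s) {bad_tissue}; allowed: {list(TISSUES)}")
    dup = meta.duplicated(["fish_id", "tissue"], keep=False)
    if dup.any():
        keys = meta.loc[dup, ["fish_id", "tissue"]].drop_duplicates().head(5)
        raise ValueError(
            f"(fish_id, tissue) must be unique; duplicates: {keys.to_records(index=False)}")
    if meta.duplicated("sample_id").any():
        raise ValueError("sample_id must be unique in the metadata table")
    meta["year"] = meta["year"].astype(int)
    return meta


def read_sample_meta(path) -> pd.DataFrame:
    return validate_sample_meta(read_table(path))


def read_site_table(path) -> pd.DataFrame:
    sites = read_table(path)
    if "site_id" not in sites.columns:
        raise ValueError("site table missing 'site_id' column")
    if sites.duplicated("site_id").any():
        raise ValueError("site_id must be unique in the site table")
    return sites


def site_distances(sites: pd.DataFrame,
                   distance_matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise site distances (km) as a labeled square DataFrame.

    If *distance_matrix* is given it is validated (symmetric, zero
    diagonal) and returned; otherwise Euclidean distances are computed
    from ``x_km`` / ``y_km`` columns of the site table. Stream distances
    supplied directly need not satisfy the triangle inequality.
    """
    if distance_matrix is not None:
        dm = distance_matrix.astype(float)
        if list(dm.index) != list(dm.columns):
            raise ValueError("distance matrix index and columns must match")
        arr = dm.to_numpy()
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        return dm
    if not {"x_km", "y_km"} <= set(sites.columns):
        raise ValueError(
            "need x_km/y_km coordinates in the site table or an explicit distance matrix")
    ids = sites["site_id"].astype(str).tolist()
    xy = sites[["x_km", "y_km"]].to_numpy(float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=ids, columns=ids)


def feature_column(fa_code: str, isotope: str) -> str:
    return f"{fa_code}_{isotope}"


def split_feature_column(col: str) -> tuple[str, str]:
    code, iso = col.rsplit("_", 1)
    return code, iso


@dataclass
class FeatureMatrixReport:
    """What :func:`build_feature_matrix` kept and dropped."""

    n_samples: int
    n_features: int
    dropped_samples: list[str] = field(default_factory=list)
    missing_by_sample: dict[str, list[str]] = field(default_factory=dict)


def build_feature_matrix(
    peaks: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    panel: tuple[str, ...] = CORE_PANEL,
    require_complete: bool = True,
    value_col: str = "delta_cal",
) -> tuple[pd.DataFrame, FeatureMatrixReport]:
    """Pivot a (calibrated) peak table into a samples x features matrix.

    Columns are ordered fatty acid-major, 13C before 2H, independent of
    input row order. With ``require_complete`` (the default,
    complete-case policy) samples missing any panel feature are dropped
    and listed in the report.
    """
    if value_col not in peaks.columns:
        raise ValueError(f"peak table has no {value_col!r} column; calibrate first")
    panel = tuple(panel)
    cols = [feature_column(fa, iso) for fa in panel for iso in ISOTOPES]
    sub = peaks[peaks["fa"].astype(str).isin(panel)]
    if sub.empty:
        raise ValueError("no overlap between panel and peak table fatty acids")
    wide = sub.pivot_table(index="sample_id", values=value_col,
                           columns=["fa", "isotope"], aggfunc="first")
    wide.columns = [feature_column(fa, iso) for fa, iso in wide.columns]
    wide = wide.reindex(columns=cols)
    if meta is not None:
        wide = wide.loc[wide.index.intersection(meta["sample_id"])]
    wide = wide.sort_index()
    report = FeatureMatrixReport(n_samples=len(wide), n_features=len(cols))
    if require_complete:
        incomplete = wide.isna().any(axis=1)
        for sid in wide.index[incomplete]:
            report.missing_by_sample[str(sid)] = [
                c for c in cols if pd.isna(wide.at[sid, c])]
        report.dropped_samples = [str(s) for s in wide.index[incomplete]]
        wide = wide.loc[~incomplete]
        report.n_samples = len(wide)
    return wide, report
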