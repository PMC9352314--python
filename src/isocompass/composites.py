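"""Per-sample composite isotope quantities.

The mass-fraction-weighted "bulk" fatty-acid value

    delta_FAbulk = sum(m_i * delta_i) / sum(m_i)

over all identified peaks of one sample and isotope serves as a proxy
for the bulk-lipid isotope value; it is computed per isotope from that
isotope's own peak set, because the hydrogen runs typically resolve
fewer peaks than the carbon runs. Pair differences (e.g. the delta2H
difference between linoleic and alpha-linolenic acid) remove shared
water/diet signal and can isolate site-specific metabolic imprints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import feature_column

__all__ = [
    "CompositeValue",
    "bulk_delta",
    "bulk_delta_table",
    "pair_difference",
    "correlate_with_bulk",
]


@dataclass(frozen=True)
class CompositeValue:
    sample_id: str
    isotope: str
    value: float        # per mil
    n_peaks_used: int
    mass_covered: float  # fraction of total identified mass entering the mean


def bulk_delta(records: pd.DataFrame, value_col: str = "delta_cal") -> CompositeValue:
    """Weighted bulk delta for the records of one sample and isotope."""
    sids = records["sample_id"].unique()
    isos = records["isotope"].unique()
    if len(sids) != 1 or len(isos) != 1:
        raise ValueError("bulk_delta expects records of exactly one sample and isotope")
    delta = records[value_col].to_numpy(float)
    mass = records["mass_fraction"].to_numpy(float)
    ok = np.isfinite(delta) & (mass > 0)
    if not ok.any():
        raise ValueError(f"sample {sids[0]}: no usable peaks (all mass fractions zero?)")
    total = mass[np.isfinite(mass)].sum()
    value = float(np.sum(mass[ok] * delta[ok]) / mass[ok].sum())
    return CompositeValue(str(sids[0]), str(isos[0]), value,
                          int(ok.sum()), float(mass[ok].sum() / total))


def bulk_delta_table(peaks: pd.DataFrame, panel: tuple[str, ...] | None = None,
                     value_col: str = "delta_cal") -> pd.DataFrame:
    """Bulk composites for every (sample, isotope) in a calibrated peak table.

    By default all identified peaks contribute; pass *panel* to restrict
    to a fatty-acid subset for sensitivity analysis.
    """
    sub = peaks
    if panel is not None:
        sub = peaks[peaks["fa"].astype(str).isin(tuple(panel))]
    rows = []
    for (sid, iso), grp in sub.groupby(["sample_id", "isotope"], sort=True):
        cv = bulk_delta(grp, value_col)
        rows.append((cv.sample_id, cv.isotope, cv.value, cv.n_peaks_used,
                     cv.mass_covered))
    return pd.DataFrame(rows, columns=["sample_id", "isotope", "bulk_delta",
                                       "n_peaks_used", "mass_covered"])


def pair_difference(matrix: pd.DataFrame, isotope: str,
                    fa_a: str, fa_b: str) -> pd.Series:
    """Per-sample delta(fa_a) - delta(fa_b) for one isotope.

    Samples missing either fatty acid yield NaN (flagged, not dropped).
    """
    col_a, col_b = feature_column(fa_a, isotope), feature_column(fa_b, isotope)
    for col in (col_a, col_b):
        if col not in matrix.columns:
            raise ValueError(f"feature matrix has no column {col!r}")
    diff = matrix[col_a] - matrix[col_b]
    diff.name = f"{fa_a}-{fa_b}_{isotope}"
    return diff


def correlate_with_bulk(matrix: pd.DataFrame, composites: pd.DataFrame,
                        isotope: str, min_pairs: int = 3) -> pd.DataFrame:
    """Pearson r of each fatty acid's delta against the bulk composite.

    Complete cases only; fatty acids with fewer than *min_pairs* pairs
    get NaN. The summary row ``mean_r``/``sd_r`` aggregates the defined
    per-FA coefficients.
    """
    comp = composites[composites["isotope"].astype(str) == isotope]
    bulk = comp.set_index("sample_id")["bulk_delta"]
    cols = [c for c in matrix.columns if c.endswith(f"_{isotope}")]
    if not cols:
        raise ValueError(f"no {isotope} columns in feature matrix")
    rows = []
    for col in cols:
        fa = col[: -len(isotope) - 1]
        paired = pd.concat([matrix[col], bulk], axis=1, join="inner").dropna()
        if len(paired) < min_pairs:
            rows.append((fa, np.nan, len(paired)))
        else:
            r = float(np.corrcoef(paired.iloc[:, 0], paired.iloc[:, 1])[0, 1])
            rows.append((fa, r, len(paired)))
    out = pd.DataFrame(rows, columns=["fa", "r", "n"])
    out.attrs["mean_r"] = float(out["r"].mean())
    out.attrs["sd_r"] = float(out["r"].std(ddof=1))
    return out


def summarize_correlations(r_values) -> tuple[float, float]:
    """Mean and SD (ddof=1) of a set of per-FA correlation coefficients."""
    arr = np.asarray(list(r_values), dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()), float(arr.std(ddof=1))
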