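"""Synthetic hierarchical CSIA datasets with known ground truth.

The generator mirrors the variance structure the analysis assumes for a
sub-alpine stream catchment: 15 sites spanning 525-1070 m a.s.l., three
fish taxa, four tissues, two sampling years, and an 11-fatty-acid panel
measured for both delta13C and delta2H. Per fish x tissue x FA x
isotope,

    delta = mu(FA, isotope)
          + altitude term (delta13C only, isotopically lighter upstream)
          + site random effect (equicorrelated across FA: one shared
            site draw plus FA-specific draws, correlation high for 13C,
            low for 2H)
          + tissue offset + taxon offset
          + year drift (an independent per-(site, FA) shock in the
            second year, so cross-year transfer degrades patchily)
          + residual noise.

Values are emitted on the *raw instrument FAME scale* — fatty-acid delta
truth is pushed through the inverse methylation mass balance and the
inverse of a configurable "true" calibration line — together with a
reference-standard run table, so the full calibration stage is
exercised. A truth record keeps every drawn effect for parameter
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import (CalibrationModel, DEFAULT_STANDARDS,
                          MethanolReference)
from .fatty_acids import CORE_PANEL, DEFAULT_REGISTRY

__all__ = ["SimConfig", "SimResult", "simulate", "make_fixture", "FIXTURES"]

TAXA = ("C. gobio", "O. mykiss", "S. trutta")
TISSUES = ("muscle", "brain", "liver", "eye")

# baseline per-FA means (per mil), in the natural-abundance range of
# freshwater fish lipids
_MU_13C = {"14:0": -29.0, "16:0": -30.0, "16:1": -31.0, "18:0": -30.5,
           "18:1": -32.0, "LIN": -33.0, "ALA": -34.0, "SDA": -34.5,
           "ARA": -33.5, "ETA": -34.0, "EPA": -35.0, "DPA": -35.5,
           "DHA": -36.0}
_MU_2H = {"14:0": -180.0, "16:0": -190.0, "16:1": -200.0, "18:0": -170.0,
          "18:1": -210.0, "LIN": -230.0, "ALA": -255.0, "SDA": -248.0,
          "ARA": -220.0, "ETA": -235.0, "EPA": -240.0, "DPA": -233.0,
          "DHA": -228.0}
# rough fish-tissue FA profile used as the Dirichlet base for mass fractions
_MASS_PROFILE = {"14:0": 0.03, "16:0": 0.18, "16:1": 0.06, "18:0": 0.06,
                 "18:1": 0.16, "LIN": 0.06, "ALA": 0.04, "SDA": 0.02,
                 "ARA": 0.05, "ETA": 0.02, "EPA": 0.10, "DPA": 0.04,
                 "DHA": 0.18}


def _default_positions(n_sites: int) -> np.ndarray:
    """Stream-kilometre positions on a transect, max span ~35 km.

    Two pairs sit closer than 1 km so that distance-tolerant assignment
    scoring has something to credit.
    """
    base = np.array([0.0, 0.8, 3.0, 5.0, 7.5, 9.0, 9.7, 12.0, 15.0, 18.0,
                     21.0, 24.0, 27.0, 30.0, 35.0])
    if n_sites <= len(base):
        return base[:n_sites]
    extra = 35.0 + 2.5 * np.arange(1, n_sites - len(base) + 1)
    return np.concatenate([base, extra])


@dataclass
class SimConfig:
    """Generating parameters; defaults are the study-like regime."""

    n_sites: int = 15
    site_altitudes: tuple = ()            # m a.s.l.; default spans 525-1070
    n_fish_per_site_year: Mapping = field(
        default_factory=lambda: {2016: 11, 2018: 3})
    years: tuple = (2016, 2018)
    taxa_mix: tuple = (0.40, 0.23, 0.37)  # C. gobio, O. mykiss, S. trutta
    year_taxa: Mapping = field(default_factory=dict)  # year -> forced taxon
    tissues: tuple = TISSUES
    panel: tuple = CORE_PANEL
    d13C_altitude_slope: float = -2.0     # per mil per km altitude
    site_effect_sd_13C: float = 1.5
    site_effect_sd_2H: float = 8.0
    within_isotope_corr_13C: float = 0.7
    within_isotope_corr_2H: float = 0.3
    tissue_offsets: Mapping = field(default_factory=lambda: {
        "muscle": (0.0, 0.0), "brain": (-1.5, -25.0),
        "liver": (0.8, 10.0), "eye": (-0.5, -10.0)})
    taxa_offsets: Mapping = field(default_factory=lambda: {
        "C. gobio": (0.0, 0.0), "O. mykiss": (0.3, 15.0),
        "S. trutta": (0.3, 12.0)})
    year_drift_sd_13C: float = 2.0
    year_drift_sd_2H: float = 16.0
    residual_sd_13C: float = 1.0
    residual_sd_2H: float = 10.0
    mass_fraction_concentration: float = 60.0
    methanol_d13C: float = -38.0
    methanol_d2H: float = -120.0
    true_calibration: Mapping = field(default_factory=lambda: {
        "13C": (0.98, -1.2), "2H": (0.95, -8.0)})  # slope, intercept
    n_standard_runs: int = 3
    seed: int | None = None

    def altitudes(self) -> np.ndarray:
        if self.site_altitudes:
            return np.asarray(self.site_altitudes, dtype=float)
        return np.linspace(525.0, 1070.0, self.n_sites)

    def fish_counts(self, year: int) -> np.ndarray:
        spec = self.n_fish_per_site_year[year]
        if np.isscalar(spec):
            return np.full(self.n_sites, int(spec))
        counts = np.asarray(spec, dtype=int)
        if len(counts) != self.n_sites:
            raise ValueError("per-site fish counts must match n_sites")
        return counts

    @property
    def methanol(self) -> MethanolReference:
        return MethanolReference(self.methanol_d13C, self.methanol_d2H)


@dataclass
class SimResult:
    peaks: pd.DataFrame          # raw instrument scale
    meta: pd.DataFrame
    sites: pd.DataFrame
    standard_runs: pd.DataFrame
    truth: dict                  # site_effects, year_drift, fa_means, config
    config: SimConfig


def _sd(config: SimConfig, what: str, isotope: str) -> float:
    return getattr(config, f"{what}_{'13C' if isotope == '13C' else '2H'}")


def simulate(config: SimConfig) -> SimResult:
    """Draw one dataset; ``config.seed`` is mandatory for reproducibility."""
    if config.seed is None:
        raise ValueError("config.seed is mandatory")
    total_fish = sum(int(config.fish_counts(y).sum()) for y in config.years)
    if total_fish == 0:
        raise ValueError("zero fish requested")
    rng = np.random.default_rng(config.seed)
    panel = tuple(config.panel)
    altitudes = config.altitudes()
    site_ids = [f"S{i+1:02d}" for i in range(config.n_sites)]
    positions = _default_positions(config.n_sites)
    sites = pd.DataFrame({"site_id": site_ids, "altitude": altitudes,
                          "x_km": positions, "y_km": 0.0})

    mean_alt_km = altitudes.mean() / 1000.0
    fa_means = {("13C", fa): _MU_13C.get(fa, -32.0) for fa in panel}
    fa_means.update({("2H", fa): _MU_2H.get(fa, -220.0) for fa in panel})

    # site random effects: shared draw + FA-specific draws, equicorrelated
    site_eff = {}
    truth_rows = []
    for iso in ("13C", "2H"):
        sd = _sd(config, "site_effect_sd", iso)
        rho = (config.within_isotope_corr_13C if iso == "13C"
               else config.within_isotope_corr_2H)
        shared = rng.standard_normal(config.n_sites)
        for s_i, sid in enumerate(site_ids):
            own = rng.standard_normal(len(panel))
            for f_i, fa in enumerate(panel):
                eff = sd * (np.sqrt(rho) * shared[s_i]
                            + np.sqrt(1.0 - rho) * own[f_i])
                alt_term = (config.d13C_altitude_slope
                            * (altitudes[s_i] / 1000.0 - mean_alt_km)
                            if iso == "13C" else 0.0)
                site_eff[(iso, sid, fa)] = eff + alt_term
                truth_rows.append((sid, iso, fa, eff, alt_term))
    truth_site = pd.DataFrame(truth_rows, columns=[
        "site_id", "isotope", "fa", "site_effect", "altitude_term"])

    # per-(site, FA, isotope) shock applied in the later year only
    later_years = list(config.years)[1:]
    drift_rows = []
    drift = {}
    for year in later_years:
        for iso in ("13C", "2H"):
            sd = _sd(config, "year_drift_sd", iso)
            for sid in site_ids:
                for fa in panel:
                    d = rng.normal(0.0, sd) if sd > 0 else 0.0
                    drift[(year, iso, sid, fa)] = d
                    drift_rows.append((year, sid, iso, fa, d))
    truth_drift = pd.DataFrame(drift_rows, columns=[
        "year", "site_id", "isotope", "fa", "drift"])

    methanol = config.methanol
    reg = DEFAULT_REGISTRY
    atoms = {}
    for fa in panel:
        f = reg.parse(fa)
        atoms[fa] = {"13C": (f.c_count_fame, 1), "2H": (f.h_count_fame, 3)}
    cal = {iso: CalibrationModel(iso, *config.true_calibration[iso])
           for iso in ("13C", "2H")}
    alpha = np.array([_MASS_PROFILE.get(fa, 0.03) for fa in panel])
    alpha = alpha / alpha.sum() * config.mass_fraction_concentration

    meta_rows, peak_rows = [], []
    fish_no = 0
    for year in config.years:
        counts = config.fish_counts(year)
        forced_taxon = config.year_taxa.get(year)
        for s_i, sid in enumerate(site_ids):
            for _ in range(counts[s_i]):
                fish_no += 1
                fish_id = f"F{fish_no:04d}"
                taxon = (forced_taxon if forced_taxon is not None
                         else TAXA[rng.choice(len(TAXA), p=config.taxa_mix)])
                for tissue in config.tissues:
                    sample_id = f"{fish_id}-{tissue}"
                    meta_rows.append((sample_id, fish_id, taxon, tissue,
                                      sid, year))
                    for iso in ("13C", "2H"):
                        res_sd = _sd(config, "residual_sd", iso)
                        t_off = config.tissue_offsets[tissue][0 if iso == "13C" else 1]
                        x_off = config.taxa_offsets[taxon][0 if iso == "13C" else 1]
                        mass = rng.dirichlet(alpha)
                        for f_i, fa in enumerate(panel):
                            delta_fa = (fa_means[(iso, fa)]
                                        + site_eff[(iso, sid, fa)]
                                        + t_off + x_off
                                        + drift.get((year, iso, sid, fa), 0.0)
                                        + rng.normal(0.0, res_sd))
                            n_fame, n_me = atoms[fa][iso]
                            delta_fame = ((n_fame - n_me) * delta_fa
                                          + n_me * methanol.delta(iso)) / n_fame
                            delta_raw = float(cal[iso].inverse(delta_fame))
                            peak_rows.append((sample_id, fa, iso, delta_raw,
                                              mass[f_i]))

    peaks = pd.DataFrame(peak_rows, columns=["sample_id", "fa", "isotope",
                                             "delta_raw", "mass_fraction"])
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "fish_id", "taxon",
                                            "tissue", "site_id", "year"])

    std_rows = []
    for iso in ("13C", "2H"):
        for name, std in DEFAULT_STANDARDS.items():
            accepted = std.accepted(iso)
            for run in range(config.n_standard_runs):
                std_rows.append((name, iso, float(cal[iso].inverse(accepted)),
                                 run))
    standard_runs = pd.DataFrame(std_rows, columns=["standard", "isotope",
                                                    "delta_raw", "run_index"])

    truth = {"site_effects": truth_site, "year_drift": truth_drift,
             "fa_means": pd.DataFrame(
                 [(iso, fa, mu) for (iso, fa), mu in sorted(fa_means.items())],
                 columns=["isotope", "fa", "mu"]),
             "config": asdict(config)}
    return SimResult(peaks=peaks, meta=meta, sites=sites,
                     standard_runs=standard_runs, truth=truth, config=config)


#: named fixtures regenerated from fixed seeds
FIXTURES = {
    "tiny": SimConfig(
        n_sites=3,
        n_fish_per_site_year={2016: 6},
        years=(2016,),
        seed=20160901,
    ),
    "paper_shape": SimConfig(
        n_sites=15,
        # 159 fish in the first year, 49 sedentary bullheads in the second
        n_fish_per_site_year={2016: [11] * 9 + [10] * 6,
                              2018: [4] * 4 + [3] * 11},
        years=(2016, 2018),
        year_taxa={2018: "C. gobio"},
        seed=20180901,
    ),
}


def make_fixture(name: str) -> SimResult:
    """Regenerate a named, versioned fixture from its fixed seed."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return simulate(FIXTURES[name])
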