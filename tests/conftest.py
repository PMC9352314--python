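import numpy as np
import pytest
from hypothesis import settings

from isocompass.calibration import calibrate_peak_table
from isocompass.io import build_feature_matrix, site_distances
from isocompass.simulate import make_fixture

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_sim():
    """Small deterministic dataset: 3 sites x 6 fish, one year, 4 tissues."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_calibrated(tiny_sim):
    peaks, models = calibrate_peak_table(tiny_sim.peaks, tiny_sim.standard_runs,
                                         tiny_sim.config.methanol)
    return peaks, models


@pytest.fixture(scope="session")
def tiny_matrix(tiny_calibrated, tiny_sim):
    peaks, _ = tiny_calibrated
    matrix, report = build_feature_matrix(peaks, tiny_sim.meta)
    return matrix


@pytest.fixture(scope="session")
def paper_shape():
    """Study-shaped dataset: 15 sites, 3 taxa, 4 tissues, 2016+2018."""
    sim = make_fixture("paper_shape")
    peaks, _ = calibrate_peak_table(sim.peaks, sim.standard_runs,
                                    sim.config.methanol)
    matrix, _ = build_feature_matrix(peaks, sim.meta)
    return {"sim": sim, "peaks": peaks, "matrix": matrix, "meta": sim.meta,
            "sites": sim.sites, "distances": site_distances(sim.sites)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
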