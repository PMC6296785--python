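"""Shared fixtures: stimulus manifest and synthetic populations.

The default-scale population (115/70/40 sites) is generated once per session
at the generator's calibrated defaults; module tests that only need
structure use a reduced world to stay fast.
"""

import numpy as np
import pytest

from facedyn import processing
from facedyn.stimuli import build_screen_image_set
from facedyn.synth import generate_population, generate_screen_responses

#: reduced world for structural tests: same statistics, fewer sites
SMALL_CONFIG = {
    "regions": {
        "pIT": {"n_sites": 24},
        "cIT": {"n_sites": 12},
        "aIT": {"n_sites": 8},
    },
}


@pytest.fixture(scope="session")
def manifest():
    return build_screen_image_set()


@pytest.fixture(scope="session")
def small_population():
    return generate_population(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def default_population():
    """Calibrated default world (115/70/40 sites), preprocessed."""
    ds = generate_population(seed=0)
    ds = processing.latency_correct(ds)
    ds = processing.baseline_subtract_dataset(ds)
    return ds


@pytest.fixture(scope="session")
def default_screen():
    ds = generate_screen_responses(seed=0)
    ds = processing.latency_correct(ds)
    ds = processing.baseline_subtract_dataset(ds)
    return ds


@pytest.fixture(scope="session")
def matched_sets(default_population):
    """(typical, atypical, reference) image lists from the population-level
    response-matching step on the default world."""
    ds = default_population
    reference = ds.meta["reference_image"]
    pit = ds.region_sites("pIT")
    matched = processing.select_matched_images(pit, reference)
    typicality = {img.image_id: img.typicality for img in ds.manifest}
    typical = [i for i in matched if typicality[i] == "typical"]
    atypical = [i for i in matched if typicality[i] == "atypical"]
    return typical, atypical, reference


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
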