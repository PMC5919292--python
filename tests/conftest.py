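import numpy as np
import pytest

import hlikit
from hlikit.classifier import fit_reference_profile
from hlikit.synthgen import NoiseModel


def table(preset, n, rng, **overrides):
    spec = hlikit.make_population_spec(preset, {"n_cells": n, **overrides})
    return hlikit.sample_feature_table(spec, rng=rng)


@pytest.fixture(scope="session")
def reference_profile():
    """Profile calibrated on adult hepatocytes vs fibroblasts (table level)."""
    rng = np.random.default_rng(101)
    ref = table("adult_hep", 500, rng)
    neg = table("fibroblast", 500, rng)
    return fit_reference_profile(ref, neg)


@pytest.fixture(scope="session")
def clean_adult_field():
    """Noise-free 50-cell adult field with ground truth, shared across tests."""
    spec = hlikit.make_population_spec("adult_hep", {"n_cells": 50, "seed": 7})
    noise = NoiseModel(gaussian_frac=0.0)
    cells, field, nuclei, cellmap = hlikit.simulate_field(spec, noise=noise)
    return cells, field, nuclei, cellmap
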