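import numpy as np
import pytest

import crumbscan as cs


@pytest.fixture(scope="session")
def tables():
    return cs.load_reference_tables()


@pytest.fixture
def two_spike_hist():
    """Histogram of a perfectly separated two-level image: 100 px at 50, 100 at 200."""
    counts = np.zeros(256, dtype=int)
    counts[50] = 100
    counts[200] = 100
    return cs.IntensityHistogram(counts=counts, total=200)


@pytest.fixture(scope="session")
def clean_synth():
    """One clean high-contrast synthetic crumb image with ground truth."""
    params = cs.CrumbSynthParams(seed=7, gray_sd=5.0)
    image, truth = cs.generate_crumb_image(params)
    return params, image, truth


def bimodal_histogram(rng, lo_mean=70, hi_mean=180, sd=8.0, n=20_000):
    """Random clearly-bimodal histogram (helper for property tests)."""
    frac = rng.uniform(0.2, 0.5)
    a = np.rint(rng.normal(lo_mean, sd, int(n * frac)))
    b = np.rint(rng.normal(hi_mean, sd, n - int(n * frac)))
    values = np.clip(np.concatenate([a, b]), 0, 255).astype(int)
    counts = np.bincount(values, minlength=256)
    return cs.IntensityHistogram(counts=counts, total=int(counts.sum()))
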