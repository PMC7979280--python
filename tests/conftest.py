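import numpy as np
import pytest

import facefat as ff
from facefat import io as fio


@pytest.fixture(scope="session")
def default_config():
    return ff.GeneratorConfig(n_subjects=106, seed=20210310)


@pytest.fixture(scope="session")
def default_run(default_config):
    """One default-condition simulated cohort with contours fitted."""
    cohort, contours = ff.simulate(default_config)
    geometry = ff.characterize_cohort(contours)
    return cohort, contours, geometry


@pytest.fixture(scope="session")
def noise_free_config():
    cfg = ff.GeneratorConfig(n_subjects=24, seed=7, sigma_a=0.0, contour_noise_sd=0.0)
    return cfg.with_noise(**{name: 0.0 for name in ff.PARAMETERS})


@pytest.fixture(scope="session")
def noise_free_run(noise_free_config):
    cohort, contours = ff.simulate(noise_free_config)
    return cohort, contours


@pytest.fixture()
def cohort_frame():
    return fio.cohort_frame


def parabola_contour(a=0.1, x_max=2.0, n=5, noise_sd=0.0, rng=None):
    """Exact (or y-noisy) parabola as a NormalizedContour."""
    x = np.linspace(-x_max, x_max, n)
    y = a * x**2
    if noise_sd:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, n)
    return ff.NormalizedContour(
        points=np.column_stack([x, y]), endpoint_indices=(0, n - 1)
    )
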