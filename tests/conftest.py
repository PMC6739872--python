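import numpy as np
import pytest

from scalegrad import (NoiseSpec, generate_paradigm, generate_tuning_field,
                       simulate_bold)


@pytest.fixture(scope="session")
def small_paradigm():
    """One 12-block run, TR 2.5 s: two blocks per scale."""
    return generate_paradigm(n_runs=1, blocks_per_run=12, tr=2.5, seed=3)


@pytest.fixture(scope="session")
def tuned_grid():
    """Small noise-free dataset with known tuning: (paradigm, field, bold)."""
    paradigm = generate_paradigm(n_runs=1, blocks_per_run=12, tr=2.5, seed=3)
    shape = (3, 8, 3)
    mask = np.zeros(shape, dtype=bool)
    mask[1, 1:7, 1] = True
    field = generate_tuning_field(shape, mask, axis=1, slope=5.0 / (5 * 3.0),
                                  jitter_sd=0.0, seed=4)
    noise = NoiseSpec(innovation_sd=0.0, drift_amplitude=0.0)
    bold = simulate_bold(paradigm, field, noise, seed=5)
    return paradigm, field, bold


def gaussian_betas(center, amplitude=1.0, width=1.0):
    s = np.arange(1, 7, dtype=float)
    return amplitude * np.exp(-(s - center) ** 2 / (2 * width ** 2))
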