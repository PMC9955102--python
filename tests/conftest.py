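import itertools

import numpy as np
import pytest

from ordicp import EmbeddingConfig, SimConfig, Segment, generate


@pytest.fixture
def worked_series():
    """Seven-sample series whose m=3 symbolization is known exactly."""
    return [3, 6, 8, 9, 5, 10, 2]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230267)


def brute_force_symbolize(series, m, tau=1):
    """Independent oracle: explicit sort of each embedded vector, rank by
    position in the enumerated lexicographic permutation list."""
    perms = sorted(itertools.permutations(range(1, m + 1)))
    out = []
    n = len(series)
    for start in range(n - (m - 1) * tau):
        window = [series[start + k * tau] for k in range(m)]
        indexed = sorted(range(m), key=lambda i: (window[i], i))
        digits = tuple(i + 1 for i in indexed)
        out.append(perms.index(digits) + 1)
    return out


@pytest.fixture(scope="session")
def noise_free_exponential():
    """Pure pressure-volume ramp: ICP = 5 * exp(0.3 V), no pulse/noise."""
    cfg = SimConfig(
        p0_mmhg=0.0,
        p1_mmhg=5.0,
        elastance_per_ml=0.3,
        pulse_amp_mmhg=0.0,
        noise_sd_mmhg=0.0,
        powerline_amp_mmhg=0.0,
        stage_plan=(Segment(2, 200.0, 7.0),),
        seed=0,
    )
    return generate(cfg), cfg
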