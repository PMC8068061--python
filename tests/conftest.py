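import numpy as np
import pytest

from blotmap.synthetic import SpotModel, SyntheticStudyConfig


@pytest.fixture
def small_config():
    """A small, fast study: 64x64 images, two spots, mild noise."""
    return SyntheticStudyConfig(
        n_samples=12,
        image_shape=(64, 64),
        spots=[
            SpotModel("FL2", 24.0, 20.0, 3.0, 2.5, 600.0),
            SpotModel("BETA", 28.0, 44.0, 3.0, 2.5, 400.0),
        ],
        planted_rho={"FL2": 0.8, "BETA": -0.6},
        noise_sd=10.0,
        max_shift=2,
        background_level=30.0,
        seed=11,
    )


@pytest.fixture
def noiseless_config(small_config):
    import dataclasses

    return dataclasses.replace(small_config, noise_sd=0.0, max_shift=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def brute_spearman(x, y):
    """Independent Spearman oracle: explicit midranks + np.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    return float(np.corrcoef(midranks(x), midranks(y))[0, 1])
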