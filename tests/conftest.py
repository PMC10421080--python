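import numpy as np
import pandas as pd
import pytest

from isopair import PeakTable, PROPANOYL


def make_random_table(seed: int, n_background: int = 300, n_pairs: int = 30,
                      jitter_ppm: float = 2.0, rt_jitter: float = 0.02,
                      intensity_ratio_sd: float = 0.15) -> PeakTable:
    """A random feature table with planted twin pairs at varying quality.

    Jitters straddle the default tolerances so some planted pairs pass and
    others fail — exactly the regime where a fast join and an exhaustive
    join could disagree.
    """
    rng = np.random.default_rng(seed)
    bg_mz = rng.uniform(100.0, 900.0, n_background)
    bg_rt = rng.uniform(0.0, 30.0, n_background)
    bg_int = 10 ** rng.uniform(3.0, 7.0, n_background)

    light_mz = rng.uniform(100.0, 900.0, n_pairs)
    heavy_mz = (light_mz + PROPANOYL.pair_delta) * (
        1 + rng.normal(0.0, jitter_ppm, n_pairs) * 1e-6)
    light_rt = rng.uniform(0.0, 30.0, n_pairs)
    heavy_rt = light_rt + rng.normal(0.0, rt_jitter, n_pairs)
    light_int = 10 ** rng.uniform(3.0, 7.0, n_pairs)
    heavy_int = light_int * np.exp(rng.normal(0.0, intensity_ratio_sd, n_pairs))

    frame = pd.DataFrame({
        "peak_id": np.arange(n_background + 2 * n_pairs),
        "mz": np.concatenate([bg_mz, light_mz, heavy_mz]),
        "rt": np.concatenate([bg_rt, light_rt, np.clip(heavy_rt, 0, None)]),
        "intensity": np.concatenate([bg_int, light_int, heavy_int]),
    })
    return PeakTable(sample_label=f"random{seed}", peaks=frame)


@pytest.fixture
def random_table_factory():
    return make_random_table


@pytest.fixture
def twin_pair_table() -> PeakTable:
    """Minimal table holding one clean isotopologue pair."""
    return PeakTable("twin", peaks=pd.DataFrame({
        "peak_id": [0, 1],
        "mz": [500.0000, 503.0101],
        "rt": [10.00, 10.01],
        "intensity": [1.0e5, 0.9e5],
    }))
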