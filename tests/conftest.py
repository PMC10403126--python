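import numpy as np
import pytest

from moascreen.config import ScreenConfig
from moascreen.synthetic import generate_layout


def small_screen(seed: int = 7, **overrides) -> ScreenConfig:
    params = dict(
        n_plates=2, wells_per_plate=96, sites_per_well=2,
        moa_compound_counts={"MoA-A": 5, "MoA-B": 5, "MoA-C": 5},
        dmso_wells_per_plate=8, technical_reps=3, biological_rep_plates=2,
        image_size=32, n_features=16, effect_size=3.0, seed=seed)
    params.update(overrides)
    return ScreenConfig(**params)


@pytest.fixture
def small_cfg() -> ScreenConfig:
    return small_screen()


@pytest.fixture
def small_platemap(small_cfg):
    return generate_layout(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
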