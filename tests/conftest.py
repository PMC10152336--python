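import datetime as dt

import numpy as np
import pytest

from snapp import (
    EngineConfig,
    UserProfile,
    gen_green_spaces,
    gen_message_library,
)
from snapp.bct import PREFERENCE_BCTS

AMSTERDAM_BBOX = (52.30, 4.80, 52.42, 5.00)


@pytest.fixture
def config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture
def library():
    return gen_message_library(per_pool=2, seed=7)


@pytest.fixture
def green_db():
    return gen_green_spaces(6, AMSTERDAM_BBOX, seed=3)


def make_profile(score: int = 5, user_id: str = "u001", name: str = "Anna", **kwargs):
    return UserProfile(
        user_id=user_id,
        first_name=name,
        scores={tag: score for tag in PREFERENCE_BCTS},
        **kwargs,
    )


@pytest.fixture
def profile() -> UserProfile:
    return make_profile()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)


@pytest.fixture
def a_monday() -> dt.date:
    return dt.date(2024, 1, 1)  # a Monday
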