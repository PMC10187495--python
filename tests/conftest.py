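from datetime import datetime, timezone

import pytest
from hypothesis import HealthCheck, settings

from tweetsent import Tweet, bundled_lexicon, default_phase_scheme

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def scheme():
    return default_phase_scheme()


@pytest.fixture
def make_tweet():
    """Factory for in-window, original, German tweets with overridable fields."""

    counter = {"n": 0}

    def factory(**overrides) -> Tweet:
        counter["n"] += 1
        fields = dict(
            id=f"tw{counter['n']:04d}",
            created_at=datetime(2020, 5, 15, 12, 0, tzinfo=timezone.utc),
            author="acct_01",
            group="authority",
            text="Corona Lage heute",
            lang="de",
        )
        fields.update(overrides)
        return Tweet(**fields)

    return factory
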