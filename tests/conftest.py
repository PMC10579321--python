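import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def night2h():
    """One default 2-hour synthetic night shared by fast unit tests."""
    from somnoloop import SimConfig, simulate_night
    return simulate_night(SimConfig(seed=42, duration_min=120))


# ---- heavy corpora for the end-to-end benchmarks (built on first use) ----

@pytest.fixture(scope="session")
def staging_corpus():
    from somnoloop.experiments import build_corpus
    return build_corpus(40, seed=1010, duration_min=120)


@pytest.fixture(scope="session")
def staging_test_nights():
    from somnoloop.experiments import build_corpus
    return build_corpus(10, seed=2020, duration_min=120)


@pytest.fixture(scope="session")
def finetune_pool():
    from somnoloop.experiments import build_corpus
    return build_corpus(6, seed=3030, duration_min=120)


@pytest.fixture(scope="session")
def long_sessions():
    """4-hour sessions for the missing-segment experiment."""
    from somnoloop.experiments import build_corpus
    return build_corpus(3, seed=4040, duration_min=240)


@pytest.fixture(scope="session")
def trained_models(staging_corpus):
    from somnoloop.experiments import train_models
    return train_models(staging_corpus, seed=0)
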