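import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(seed: int = 0):
    """A scaled-down synthetic study for fast module tests."""
    from driftwatch.synthdata import SynthConfig

    return SynthConfig(
        seed=seed,
        n_asp_females=40,
        n_asp_males=10,
        n_bleak=8,
        season_length_days=7,
        detection_rate_hz=0.003,
    )


@pytest.fixture(scope="session")
def small_season():
    from driftwatch.synthdata import generate_season

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_season(small_config(seed=11))


@pytest.fixture(scope="session")
def small_run(small_season):
    """Pipeline result on the small season (models fitted)."""
    from driftwatch import pipeline

    cfg = pipeline.RunConfig(
        season_windows=[
            (str(a.date()), str(b.date()))
            for a, b in small_season.config.season_windows()
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run(
            small_season.detections,
            small_season.registry,
            small_season.temperature,
            cfg,
        )


def utc(s: str) -> pd.Timestamp:
    return pd.Timestamp(s, tz="UTC")
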