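import numpy as np
import pandas as pd
import pytest

from feedernet.synth import SynthConfig, generate_study


@pytest.fixture(scope="session")
def small_cfg():
    """One compact network: quick to generate, still exercises every
    pipeline stage."""
    return SynthConfig(seed=101, n_networks=1, n_feeders=8, n_tags=30)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg)


@pytest.fixture(scope="session")
def full_study():
    """Three networks at the field design scale (17 feeders each)."""
    return generate_study(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def full_events(full_study):
    from feedernet.connections import collapse_bouts, extract_connections

    bouts = collapse_bouts(full_study.detections)
    events, report = extract_connections(
        bouts, full_study.stations, full_study.tags, full_study.config.calendar
    )
    return events, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_stations():
    return pd.DataFrame(
        {
            "feeder_id": ["F1", "F2", "F3"],
            "network_id": ["net"] * 3,
            "x": [0.0, 100.0, 200.0],
            "y": [0.0, 0.0, 50.0],
        }
    )


@pytest.fixture()
def toy_tags():
    return pd.DataFrame(
        {
            "tag_id": ["T1", "T2"],
            "species": ["blue_tit", "great_tit"],
            "ringing_site_id": ["R1", "R1"],
            "tag_date": [pd.Timestamp("2013-07-01").date()] * 2,
        }
    )
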