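import datetime

import numpy as np
import pytest

from exsertia.records import OccurrenceRecord

#: suite-wide base seed for every stochastic check
GLOBAL_SEED = 20231127


def make_record(
    record_id="r1",
    species="inflata",
    latitude=42.0,
    longitude=-75.0,
    observation_date=datetime.date(2020, 7, 15),
    exsertion_score="absent",
    n_visible_flowers=3,
    n_exserted_flowers=0,
    fruit_present="no",
    sex="hermaphrodite",
    elevation=250.0,
    **kwargs,
):
    return OccurrenceRecord(
        record_id=record_id,
        source_observation_id=f"obs-{record_id}",
        species=species,
        latitude=latitude,
        longitude=longitude,
        observation_date=observation_date,
        exsertion_score=exsertion_score,
        n_visible_flowers=n_visible_flowers,
        n_exserted_flowers=n_exserted_flowers,
        fruit_present=fruit_present,
        sex=sex,
        elevation=elevation,
        **kwargs,
    )


def present_record(record_id="p1", n_exserted=2, n_visible=4, **kwargs):
    return make_record(record_id=record_id, exsertion_score="present",
                       n_visible_flowers=n_visible,
                       n_exserted_flowers=n_exserted, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(GLOBAL_SEED)


def random_point_cloud(rng, n=40, lon0=-90.0, lat0=35.0, span=12.0):
    """Uniform points in a random rectangle; generic position w.p. 1."""
    lon = lon0 + rng.uniform(0, span, n)
    lat = lat0 + rng.uniform(0, span * 0.7, n)
    return lon, lat
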