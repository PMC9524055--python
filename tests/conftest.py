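import datetime as dt

import pytest

from tweetwarn.config import PipelineConfig
from tweetwarn.pipeline import build_geo_resources
from tweetwarn.stream import TweetRecord


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def geo_resources(config):
    """(entries, classifier, index) built once per session: training the
    candidate classifier dominates fixture cost."""
    return build_geo_resources(config)


@pytest.fixture(scope="session")
def entries(geo_resources):
    return geo_resources[0]


@pytest.fixture(scope="session")
def classifier(geo_resources):
    return geo_resources[1]


@pytest.fixture(scope="session")
def index(geo_resources):
    return geo_resources[2]


def make_record(**kwargs) -> TweetRecord:
    defaults = dict(
        tweet_id="t1",
        created_at=dt.datetime(2020, 10, 5, 12, 0, tzinfo=dt.timezone.utc),
        topic="measles",
        text="measles outbreak in Paris",
        lang="en",
    )
    defaults.update(kwargs)
    return TweetRecord(**defaults)
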