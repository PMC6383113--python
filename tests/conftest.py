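from __future__ import annotations

from datetime import datetime
from zoneinfo import ZoneInfo

import pytest

from alertlog.fixture import make_canonical_fixture
from alertlog.pipeline import run_pipeline

TZ = ZoneInfo("America/New_York")


def dt(*args, tz: ZoneInfo = TZ) -> datetime:
    """Aware clinic-local datetime shorthand for tests."""
    return datetime(*args, tzinfo=tz)


@pytest.fixture(scope="session")
def canonical():
    return make_canonical_fixture()


@pytest.fixture(scope="session")
def canonical_result(canonical):
    return run_pipeline(canonical.events, canonical.alerts)


@pytest.fixture(scope="session")
def canonical_table(canonical_result):
    return canonical_result.table
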