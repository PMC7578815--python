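from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import pytest
from hypothesis import HealthCheck, settings

from fraudscreen.schema_io import ResponseRecord, schema_from_dict

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_schema():
    """Two pages: 10 + 5 closed items, 2 open, 1 hidden."""
    pages = [
        {"id": "p1", "items": [f"c{i:02d}" for i in range(1, 11)] + ["o1", "h1"]},
        {"id": "p2", "items": [f"c{i:02d}" for i in range(11, 16)] + ["o2"]},
    ]
    items = {f"c{i:02d}": {"kind": "closed", "domain": ["1", "2", "3", "4", "5"]} for i in range(1, 16)}
    items |= {"o1": {"kind": "open"}, "o2": {"kind": "open"}, "h1": {"kind": "hidden"}}
    return schema_from_dict(
        {
            "pages": pages,
            "items": items,
            "time_fields": ["start_ts", "end_ts"],
            "identity_fields": {
                "state": "reported_state",
                "zip_prefix": "zip_prefix",
                "facility": "facility",
                "referral": "referral_source",
                "email_hash": "email_hash",
                "tz": "tz",
            },
        }
    )


@pytest.fixture(scope="session")
def zipmap():
    from fraudscreen.schema_io import packaged_zip_map

    return packaged_zip_map()


@pytest.fixture
def rec():
    """Factory for a fully consistent record that triggers no indicator."""

    def make(
        case_id="C1",
        minutes=15.0,
        state="MA",
        zip3="021",
        zone="America/New_York",
        end_hour=10,
        open_texts=None,
        hidden=None,
        closed=None,
        facility="Dana-Farber Cancer Institute",
        referral="Facebook",
        valid_ts=True,
    ):
        end = datetime(2020, 1, 15, end_hour, 0, 0, tzinfo=ZoneInfo(zone))
        start = end - timedelta(minutes=minutes)
        if not valid_ts:
            start, end, zone = None, None, None
        if closed is None:
            closed = {f"c{i:02d}": str(1 + i % 5) for i in range(1, 16)}
        return ResponseRecord(
            case_id=case_id,
            start_ts=start,
            end_ts=end,
            tzname=zone,
            closed=closed,
            open=dict(open_texts or {}),
            hidden=dict(hidden or {}),
            reported_state=state,
            zip_prefix=zip3,
            facility=facility,
            referral_source=referral,
            email_hash=f"eh-{case_id}",
        )

    return make
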