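import datetime as dt

import pytest

from podnet import (
    Activity,
    IndividualRegistry,
    SightingRecord,
    SightingTable,
)


def rec(sid, day, hhmm, members, activity="travel", n_unid=0):
    """Shorthand sighting constructor for fixtures."""
    hh, mm = hhmm.split(":")
    return SightingRecord(
        sighting_id=sid,
        date=dt.date(2008, 7, day),
        time=dt.time(int(hh), int(mm)),
        activity=Activity(activity),
        members=frozenset(members),
        n_unidentified=n_unid,
    )


@pytest.fixture
def three_record_table():
    """Records {A,B}, {A,C}, {B}: pair (A,B) has X=1, Ya=1, Yb=1."""
    return SightingTable(
        (
            rec("s1", 1, "09:00", "AB"),
            rec("s2", 2, "09:00", "AC"),
            rec("s3", 3, "09:00", "B"),
        )
    )


@pytest.fixture
def registry_abc():
    return IndividualRegistry({"A": False, "B": False, "C": True})
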