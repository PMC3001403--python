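"""Shared fixtures: small synthetic libraries, users and screens."""

from __future__ import annotations

from datetime import date

import pytest

import screenkit as sk
from screenkit.core_model import LOGIN_ROLE, VOLUME_ADMIN_ROLE
from screenkit.fixtures import FixtureSpec


@pytest.fixture
def admin():
    return sk.User(
        id="staff1",
        category="administrator",
        roles={LOGIN_ROLE, VOLUME_ADMIN_ROLE, "readEverythingAdmin"},
    )


@pytest.fixture
def volume_admin():
    return sk.User(id="staff2", category="administrator", roles={LOGIN_ROLE, VOLUME_ADMIN_ROLE})


@pytest.fixture
def screener():
    return sk.User(id="alice", category="screener", roles={LOGIN_ROLE}, lab_name="Smith Lab")


@pytest.fixture
def log():
    return sk.ActivityLog()


@pytest.fixture
def today():
    return date(2024, 3, 1)


@pytest.fixture
def sm_library():
    """A 2-plate, 384-well small-molecule library with column-1 controls."""
    return sk.generate_library(FixtureSpec(seed=11, n_plates=2, short_name="SM1"))[0]


@pytest.fixture
def rnai_libraries():
    """A pool library and its duplex library (1 pool plate, 4 duplexes/pool)."""
    return sk.generate_library(
        FixtureSpec(seed=12, library_type=sk.ScreenType.RNAI, n_plates=1, short_name="RN1")
    )


@pytest.fixture
def sm_screen(sm_library, screener):
    screen = sk.Screen(
        facility_id="S100",
        screen_type=sk.ScreenType.SMALL_MOLECULE,
        title="synthetic assay",
        lead_screener=screener,
        libraries=[sm_library],
        data_sharing_level=1,
    )
    screen.add_status(date(2024, 1, 1), "pending")
    return screen


@pytest.fixture
def sm_screen_with_result(sm_screen, sm_library):
    spec = FixtureSpec(seed=21, n_plates=2, positives_rate=0.02, short_name="SM1")
    workbook = sk.generate_screen_result(sm_library, spec)
    sk.import_screen_result(sm_screen, workbook, date=date(2024, 2, 1))
    return sm_screen
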