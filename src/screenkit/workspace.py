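"""On-disk workspace binding the domain model to files between CLI runs.

A workspace is a directory holding a pickled object store (the libraries,
screens, users, cherry-pick requests and the activity log) plus a small
JSON config (default plate format, access-policy choice, SD-file field-name
mapping for foreign dialects).  All CLI commands operate on one workspace;
the store survives process restarts.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

from .activities import ActivityLog
from .core_model import ScreenkitError, User, ValidationError
from .library_io import Library
from .screen_results import Screen
from .cherrypick import CherryPickRequest

__all__ = ["Workspace", "Store", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "policy": "reciprocity",
    "default_plate_format": 384,
    "sdf_field_map": {},
    # data sharing level vocabulary, for reference by facility staff
    "data_sharing_levels": {
        "0": "shared (everything)",
        "1": "shared (non-positive details withheld)",
        "2": "positives and protocol shared",
        "3": "private",
    },
}

_STORE_FILE = "store.pkl"
_CONFIG_FILE = "config.json"


@dataclass
class Store:
    users: dict[str, User] = field(default_factory=dict)
    libraries: dict[str, Library] = field(default_factory=dict)
    screens: dict[str, Screen] = field(default_factory=dict)
    requests: list[CherryPickRequest] = field(default_factory=list)
    log: ActivityLog = field(default_factory=ActivityLog)


class Workspace:
    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._config_path = self.root / _CONFIG_FILE
        self._store_path = self.root / _STORE_FILE
        if self._config_path.exists():
            self.config = json.loads(self._config_path.read_text())
        else:
            self.config = dict(DEFAULT_CONFIG)
            self._config_path.write_text(json.dumps(self.config, indent=2) + "\n")
        if self._store_path.exists():
            with open(self._store_path, "rb") as fh:
                self.store: Store = pickle.load(fh)
        else:
            self.store = Store()

    def save(self) -> None:
        with open(self._store_path, "wb") as fh:
            pickle.dump(self.store, fh)

    # -- convenience lookups -------------------------------------------------

    def library(self, name: str) -> Library:
        try:
            return self.store.libraries[name]
        except KeyError:
            raise ValidationError(f"no library {name!r} in this workspace") from None

    def screen(self, facility_id: str) -> Screen:
        try:
            return self.store.screens[facility_id]
        except KeyError:
            raise ValidationError(f"no screen {facility_id!r} in this workspace") from None

    def request(self, index: int) -> CherryPickRequest:
        try:
            return self.store.requests[index - 1]
        except IndexError:
            raise ValidationError(f"no cherry-pick request #{index}") from None

    def user(self, user_id: str, create: bool = True) -> User:
        if user_id not in self.store.users:
            if not create:
                raise ValidationError(f"no user {user_id!r} in this workspace")
            from .core_model import LOGIN_ROLE, VOLUME_ADMIN_ROLE

            self.store.users[user_id] = User(
                id=user_id,
                category="administrator",
                roles={LOGIN_ROLE, VOLUME_ADMIN_ROLE},
            )
        return self.store.users[user_id]
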