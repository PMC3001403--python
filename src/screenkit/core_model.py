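"""Plate/well coordinate system and the shared entity vocabulary.

High-throughput screening work is organised around microtitre plates in the
three industry-standard densities (96, 384 and 1536 wells).  Every other part
of the package — library contents, copy volume ledgers, screen results,
cherry-pick plate mapping — addresses reagents by a plate number plus a well
name such as ``"A01"``.  This module owns that coordinate system: the plate
formats, the canonical well-name dialect (letter row + zero-padded column),
parsing/formatting between names and 0-based coordinates, and the small
shared types (well kinds, users) that the rest of the domain model builds on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

__all__ = [
    "ScreenkitError",
    "ValidationError",
    "AuthorizationError",
    "WorkflowError",
    "PlateFormat",
    "WellCoordinate",
    "WellKey",
    "WellType",
    "ScreenType",
    "User",
    "ChecklistItem",
    "LOGIN_ROLE",
    "READ_EVERYTHING_ROLE",
    "VOLUME_ADMIN_ROLE",
    "parse_well_name",
    "format_well_name",
    "wells_in_row_major",
]


class ScreenkitError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ScreenkitError):
    """Malformed or out-of-range input data."""


class AuthorizationError(ScreenkitError):
    """The acting user lacks a required role."""


class WorkflowError(ScreenkitError):
    """An operation was applied in a state that does not permit it."""


#: Role granting login privileges (screeners and administrators alike).
LOGIN_ROLE = "screenkitUserLogin"
#: Administrator role that bypasses the data-sharing policy for reads.
READ_EVERYTHING_ROLE = "readEverythingAdmin"
#: Administrator role required for manual well-volume corrections.
VOLUME_ADMIN_ROLE = "libraryCopyVolumeAdmin"


class PlateFormat(Enum):
    """A standard microplate density: 96, 384 or 1536 wells.

    Rows are lettered ``A..H``, ``A..P`` and ``A..AF`` respectively (the
    1536 format runs past ``Z`` into the conventional two-letter extension
    ``AA..AF``); columns are numbered from 1.
    """

    F96 = (96, 8, 12)
    F384 = (384, 16, 24)
    F1536 = (1536, 32, 48)

    def __init__(self, wells_per_plate: int, n_rows: int, n_cols: int):
        self.wells_per_plate = wells_per_plate
        self.n_rows = n_rows
        self.n_cols = n_cols

    @classmethod
    def from_wells(cls, wells_per_plate: int) -> "PlateFormat":
        for fmt in cls:
            if fmt.wells_per_plate == wells_per_plate:
                return fmt
        raise ValidationError(
            f"unsupported plate format: {wells_per_plate} wells (expected 96, 384 or 1536)"
        )

    def row_label(self, row: int) -> str:
        if not 0 <= row < self.n_rows:
            raise ValidationError(f"row index {row} out of range for {self.wells_per_plate}-well format")
        if row < 26:
            return chr(ord("A") + row)
        return "A" + chr(ord("A") + row - 26)

    def row_index(self, label: str) -> int:
        label = label.upper()
        if len(label) == 1:
            idx = ord(label) - ord("A")
        elif len(label) == 2 and label[0] == "A":
            idx = 26 + ord(label[1]) - ord("A")
        else:
            raise ValidationError(f"unrecognised row label {label!r}")
        if not 0 <= idx < self.n_rows:
            raise ValidationError(
                f"row {label!r} out of range for {self.wells_per_plate}-well format"
            )
        return idx


@dataclass(frozen=True, order=True)
class WellCoordinate:
    """0-based (row, col) position on a plate of some :class:`PlateFormat`."""

    row: int
    col: int


@dataclass(frozen=True, order=True)
class WellKey:
    """A well address unique within a library: plate number + canonical name.

    The well name is always stored zero-padded (``"A01"``, never ``"A1"``);
    parsers accept the unpadded dialect, writers emit the padded one.
    """

    plate_number: int
    well_name: str

    def __post_init__(self):
        if self.plate_number < 1:
            raise ValidationError(f"plate number must be positive, got {self.plate_number}")

    def __str__(self) -> str:  # "1:A01" — the token dialect used in pick lists
        return f"{self.plate_number}:{self.well_name}"

    @classmethod
    def parse(cls, token: str, fmt: PlateFormat) -> "WellKey":
        """Parse a ``"plate:well"`` token, normalising the well name."""
        plate_str, sep, well = token.partition(":")
        if not sep:
            raise ValidationError(f"expected 'plate:well' token, got {token!r}")
        try:
            plate = int(plate_str)
        except ValueError:
            raise ValidationError(f"bad plate number in token {token!r}") from None
        coord = parse_well_name(well, fmt)
        return cls(plate, format_well_name(coord, fmt))


class WellType(Enum):
    """What a library well physically holds."""

    EXPERIMENTAL = "experimental"
    EMPTY = "empty"
    DMSO_CONTROL = "dmso_control"
    LIBRARY_CONTROL = "library_control"
    BUFFER = "buffer"

    @property
    def is_cherry_pickable(self) -> bool:
        # Only experimental wells carry screenable reagents.
        return self is WellType.EXPERIMENTAL

    @classmethod
    def parse(cls, text: str) -> "WellType":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValidationError(f"unknown well type {text!r}") from None


class ScreenType(Enum):
    SMALL_MOLECULE = "small_molecule"
    RNAI = "rnai"


CHECKLIST_STATUSES = frozenset({"pending", "completed", "activated", "deactivated"})


@dataclass
class ChecklistItem:
    name: str
    status: str = "pending"
    date: str | None = None

    def __post_init__(self):
        if self.status not in CHECKLIST_STATUSES:
            raise ValidationError(f"unknown checklist status {self.status!r}")


@dataclass
class User:
    """A facility user: a screener or a member of the administrative staff.

    ``roles`` carries data-access and administrative role names; login is
    permitted only when the dedicated login role is present.
    ``data_sharing_levels`` records, per screen type, how much of the user's
    own data they have agreed to share (0 = everything .. 3 = private); the
    reciprocity policy in :mod:`screenkit.access_policy` reads it.
    """

    id: str
    category: str = "screener"  # or "administrator"
    roles: set[str] = field(default_factory=set)
    classification: str = ""
    lab_name: str = ""
    checklist_items: list[ChecklistItem] = field(default_factory=list)
    data_sharing_levels: dict[ScreenType, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in ("screener", "administrator"):
            raise ValidationError(f"unknown user category {self.category!r}")

    @property
    def can_login(self) -> bool:
        return LOGIN_ROLE in self.roles

    def __hash__(self):
        return hash(self.id)

    def __eq__(self, other):
        return isinstance(other, User) and other.id == self.id


_WELL_NAME_RE = re.compile(r"^([A-Za-z]{1,2})(\d{1,3})$")


def parse_well_name(name: str, fmt: PlateFormat) -> WellCoordinate:
    """Parse a well name like ``"A01"`` / ``"a1"`` / ``"AF48"`` to a coordinate.

    Case-insensitive on the row letters; accepts both padded and unpadded
    column digits.  Raises :class:`ValidationError` naming the offending
    token when the name is malformed or out of range for ``fmt``.
    """
    m = _WELL_NAME_RE.match(name.strip())
    if not m:
        raise ValidationError(f"malformed well name {name!r}")
    row = fmt.row_index(m.group(1))
    col = int(m.group(2)) - 1
    if not 0 <= col < fmt.n_cols:
        raise ValidationError(
            f"column {m.group(2)} out of range in well name {name!r} "
            f"for the {fmt.wells_per_plate}-well format"
        )
    return WellCoordinate(row, col)


def format_well_name(coord: WellCoordinate, fmt: PlateFormat) -> str:
    """Inverse of :func:`parse_well_name`; columns zero-padded to two digits."""
    if not (0 <= coord.row < fmt.n_rows and 0 <= coord.col < fmt.n_cols):
        raise ValidationError(
            f"coordinate ({coord.row}, {coord.col}) out of range for the "
            f"{fmt.wells_per_plate}-well format"
        )
    return f"{fmt.row_label(coord.row)}{coord.col + 1:02d}"


def iter_well_names(fmt: PlateFormat) -> Iterator[str]:
    """All well names of a format in row-major order (A01, A02, …, B01, …)."""
    for row in range(fmt.n_rows):
        label = fmt.row_label(row)
        for col in range(fmt.n_cols):
            yield f"{label}{col + 1:02d}"


def wells_in_row_major(plate_number: int, fmt: PlateFormat) -> list[WellKey]:
    """All wells of a plate as :class:`WellKey`, row-major."""
    if plate_number < 1:
        raise ValidationError(f"plate number must be positive, got {plate_number}")
    return [WellKey(plate_number, name) for name in iter_well_names(fmt)]


def well_sort_index(name: str, fmt: PlateFormat) -> int:
    """Row-major ordinal of a well name within its plate (A01 → 0)."""
    c = parse_well_name(name, fmt)
    return c.row * fmt.n_cols + c.col
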