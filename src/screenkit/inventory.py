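"""Library copies and the per-well reagent-volume ledger.

Stock libraries are aliquoted into working *copies* so that the master
plates are not repeatedly frozen and thawed.  Each copy plate starts with a
uniform per-well volume; screening debits every well of a plate by
``volume × replicates`` and bumps the plate's freeze/thaw count, cherry-pick
reservation debits individual wells, and staff can correct a well's volume
when reality (evaporation, pipetting error) has drifted from the ledger.

All volumes are held internally as integer nanolitres and rendered as
microlitres, so ledger conservation is exact: for any operation sequence,
``remaining = initial − Σ debits + Σ correction deltas`` holds well by well
with no floating-point drift.  Debits are atomic — an operation that would
drive any well negative is rejected without touching anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

from .activities import Activity, ActivityLog
from .core_model import (
    AuthorizationError,
    User,
    ValidationError,
    VOLUME_ADMIN_ROLE,
    WellKey,
    iter_well_names,
)
from .library_io import Library

__all__ = [
    "Copy",
    "CopyPlate",
    "ul_to_nl",
    "nl_to_ul",
    "create_copy",
    "record_library_screening",
    "apply_volume_correction",
    "deprecate_wells",
    "remaining_volume_report",
]


def ul_to_nl(volume_ul: float) -> int:
    """Convert microlitres to the integer-nanolitre ledger unit."""
    return round(volume_ul * 1000)


def nl_to_ul(volume_nl: int) -> float:
    return volume_nl / 1000


@dataclass
class CopyPlate:
    plate_number: int
    initial_well_volume_nl: int
    remaining_nl: dict[str, int]  # well name -> nanolitres
    retired: bool = False
    freeze_thaw_count: int = 0


@dataclass
class Copy:
    """A physical instance of a library's plates with its own volume ledger."""

    library: Library
    name: str
    usage_type: str  # "library_screening" | "cherry_pick_source"
    plates: dict[int, CopyPlate] = field(default_factory=dict)

    def plate(self, plate_number: int) -> CopyPlate:
        try:
            return self.plates[plate_number]
        except KeyError:
            raise ValidationError(
                f"copy {self.name!r} has no plate {plate_number}"
            ) from None

    def remaining_ul(self, well: WellKey) -> float:
        return nl_to_ul(self.plate(well.plate_number).remaining_nl[well.well_name])


def create_copy(
    library: Library, name: str, usage_type: str, initial_well_volume_ul: float
) -> Copy:
    """Register a new copy of a library, every well at the initial volume."""
    if usage_type not in ("library_screening", "cherry_pick_source"):
        raise ValidationError(f"unknown copy usage type {usage_type!r}")
    if name in library.copies:
        raise ValidationError(f"library {library.short_name!r} already has a copy {name!r}")
    initial_nl = ul_to_nl(initial_well_volume_ul)
    if initial_nl <= 0:
        raise ValidationError("initial well volume must be positive")
    copy = Copy(library=library, name=name, usage_type=usage_type)
    names = list(iter_well_names(library.plate_format))
    for plate_number in library.plate_numbers:
        copy.plates[plate_number] = CopyPlate(
            plate_number=plate_number,
            initial_well_volume_nl=initial_nl,
            remaining_nl={n: initial_nl for n in names},
        )
    library.copies[name] = copy
    return copy


def record_library_screening(
    copy: Copy,
    plate_numbers: list[int],
    volume_per_well_ul: float,
    replicates: int,
    performer: User,
    date: _date,
    log: ActivityLog,
) -> Activity:
    """Debit every well of the listed plates for a screening run.

    Each plate loses ``volume × replicates`` from every well and gains one
    freeze/thaw cycle.  The debit is atomic: if any well would go negative,
    nothing changes and the first offending well is named.
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be ≥ 1, got {replicates}")
    debit_nl = ul_to_nl(volume_per_well_ul) * replicates
    if debit_nl <= 0:
        raise ValidationError("screening volume must be positive")
    plates = [copy.plate(p) for p in plate_numbers]
    for plate in plates:
        if plate.retired:
            raise ValidationError(
                f"plate {plate.plate_number} of copy {copy.name!r} is retired"
            )
    # Pre-check so a failure leaves every well untouched.
    for plate in plates:
        for well_name, remaining in plate.remaining_nl.items():
            if remaining < debit_nl:
                raise ValidationError(
                    f"insufficient volume in well {plate.plate_number}:{well_name} "
                    f"of copy {copy.name!r} ({nl_to_ul(remaining)} µL remaining, "
                    f"{nl_to_ul(debit_nl)} µL required); screening rejected"
                )
    for plate in plates:
        for well_name in plate.remaining_nl:
            plate.remaining_nl[well_name] -= debit_nl
        plate.freeze_thaw_count += 1
    return log.record(
        "library_screening",
        performer,
        date,
        links=(copy,),
        payload={
            "copy": copy.name,
            "plates": list(plate_numbers),
            "volume_per_well_ul": volume_per_well_ul,
            "replicates": replicates,
        },
    )


def apply_volume_correction(
    copy: Copy,
    well: WellKey,
    new_volume_ul: float,
    reason: str,
    admin: User,
    log: ActivityLog,
    date: _date | None = None,
) -> Activity:
    """Set a well's remaining volume to a measured value, with an audit record."""
    if VOLUME_ADMIN_ROLE not in admin.roles:
        raise AuthorizationError(
            f"user {admin.id!r} lacks the {VOLUME_ADMIN_ROLE} role required "
            "for volume corrections"
        )
    new_nl = ul_to_nl(new_volume_ul)
    if new_nl < 0:
        raise ValidationError("corrected volume may not be negative")
    plate = copy.plate(well.plate_number)
    if well.well_name not in plate.remaining_nl:
        raise ValidationError(f"unknown well {well} on copy {copy.name!r}")
    old_nl = plate.remaining_nl[well.well_name]
    plate.remaining_nl[well.well_name] = new_nl
    return log.record(
        "well_volume_correction",
        admin,
        date or _date.today(),
        links=(copy,),
        payload={
            "copy": copy.name,
            "well": str(well),
            "old_ul": nl_to_ul(old_nl),
            "new_ul": nl_to_ul(new_nl),
            "reason": reason,
        },
    )


def deprecate_wells(
    library: Library,
    keys: list[WellKey],
    reason: str,
    admin: User,
    log: ActivityLog,
    date: _date | None = None,
) -> Activity:
    """Flag wells as no longer valid for screening (contamination, bad lot…).

    Idempotent on already-deprecated wells (the reason is updated).
    Deprecated wells are excluded from cherry-pick availability.
    """
    if not reason.strip():
        raise ValidationError("a deprecation reason is required")
    wells = [library.well(k) for k in keys]  # raises on unknown key, before mutating
    for well in wells:
        well.deprecated = True
        well.deprecation_reason = reason
    return log.record(
        "well_deprecation",
        admin,
        date or _date.today(),
        links=(library,),
        payload={
            "library": library.short_name,
            "wells": [str(k) for k in keys],
            "reason": reason,
        },
    )


def remaining_volume_report(
    library: Library, well: WellKey
) -> list[tuple[str, bool, float]]:
    """Per-copy remaining volume for one well: (copy name, retired?, µL)."""
    library.well(well)
    report = []
    for name in sorted(library.copies):
        copy: Copy = library.copies[name]
        plate = copy.plates.get(well.plate_number)
        if plate is None:
            continue
        report.append((name, plate.retired, nl_to_ul(plate.remaining_nl[well.well_name])))
    return report
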