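"""The cherry-pick request workflow, from screener picks to robot files.

After a primary screen, the screener selects positives for follow-up and
submits them as ``plate:well`` designations.  The facility then:

1. validates the picks (uniqueness, pick-count policy, deprecated and
   non-experimental wells are refused) and — for pool-format siRNA
   libraries — *deconvolutes* each pool pick into one lab pick per
   constituent duplex reagent;
2. reserves reagent volume for each lab pick from a cherry-pick source copy,
   choosing deterministically among copies with sufficient remaining volume
   (nearly-empty copies are depleted first); picks no copy can satisfy stay
   unfulfilled and can be rolled over into a fresh request;
3. maps the reserved picks onto destination plates — keeping source plates
   batched together for efficient robot runs, honouring wells deliberately
   left empty (controls, edge-effect avoidance) and an optional seeded
   randomised layout — and exports the machine-readable mapping file used to
   program the liquid handler;
4. tracks each produced plate as *plated*, *failed* (reagent consumed; the
   affected picks re-enter the reservation/mapping workflow on a successor
   plate) or *canceled* (reservations credited back to the source wells).

Volume accounting shares the integer-nanolitre ledger of
:mod:`screenkit.inventory`, so debits and credits are exactly conserved.
"""

from __future__ import annotations

import io
import math
import random
from dataclasses import dataclass, field
from datetime import date as _date

from .activities import Activity, ActivityLog
from .core_model import (
    PlateFormat,
    ScreenType,
    User,
    ValidationError,
    WellKey,
    WorkflowError,
    iter_well_names,
    well_sort_index,
)
from .inventory import Copy, nl_to_ul, ul_to_nl
from .library_io import Library, SilencingReagent, Well
from .screen_results import Screen

__all__ = [
    "CherryPickRequest",
    "ScreenerCherryPick",
    "LabCherryPick",
    "CherryPickPlate",
    "create_request",
    "validate_picks",
    "deconvolute",
    "view_well_volumes",
    "reserve_reagent",
    "map_to_plates",
    "export_plate_mapping",
    "update_plate_status",
    "rollover_unfulfilled",
]

REJECTION_REASONS = ("duplicate", "deprecated", "non_experimental", "over_limit", "unknown_well")
LAB_PICK_STATUSES = ("unfulfilled", "reserved", "mapped", "plated", "failed", "canceled")
_LAB_PICK_TRANSITIONS = {
    "unfulfilled": {"reserved"},
    "reserved": {"mapped"},
    "mapped": {"plated", "failed", "canceled"},
    "plated": set(),
    "failed": set(),
    "canceled": set(),
}
PLATE_STATUSES = ("not_plated", "plated", "failed", "canceled")


@dataclass
class ScreenerCherryPick:
    source_well: WellKey
    status: str = "accepted"  # or "rejected"
    rejection_reason: str | None = None


@dataclass
class LabCherryPick:
    """One physical transfer: a source well (duplex-level for RNAi) to plate."""

    source_well: WellKey
    screener_pick: ScreenerCherryPick
    status: str = "unfulfilled"
    source_copy: str | None = None
    destination_plate_ordinal: int | None = None
    destination_well: str | None = None
    # ordinal of the failed plate this pick was respawned from, if any
    respawn_of_ordinal: int | None = None

    def transition(self, new_status: str) -> None:
        if new_status not in _LAB_PICK_TRANSITIONS.get(self.status, set()):
            raise WorkflowError(
                f"lab pick {self.source_well}: illegal transition "
                f"{self.status} → {new_status}"
            )
        self.status = new_status


@dataclass
class CherryPickPlate:
    ordinal: int
    attempt: int = 1
    status: str = "not_plated"
    picks: list[LabCherryPick] = field(default_factory=list)


@dataclass
class CherryPickRequest:
    screen: Screen
    requested_by: User
    date: _date
    requested_volume_ul: float
    approved_volume_ul: float | None = None
    randomize_layout: bool = False
    required_empty_wells: frozenset[str] = frozenset()
    random_seed: int = 0
    max_picks_policy: int | None = None
    screener_picks: list[ScreenerCherryPick] = field(default_factory=list)
    lab_picks: list[LabCherryPick] = field(default_factory=list)
    plates: list[CherryPickPlate] = field(default_factory=list)
    libraries: list[Library] = field(default_factory=list)
    rolled_over: bool = False

    def __post_init__(self):
        if self.requested_volume_ul <= 0:
            raise ValidationError("requested volume must be positive")
        if (
            self.approved_volume_ul is not None
            and self.approved_volume_ul > self.requested_volume_ul
        ):
            raise ValidationError("approved volume may not exceed the requested volume")

    @property
    def effective_volume_ul(self) -> float:
        """Approved volume when the facility set one, else the requested volume."""
        return (
            self.approved_volume_ul
            if self.approved_volume_ul is not None
            else self.requested_volume_ul
        )

    @property
    def effective_volume_nl(self) -> int:
        return ul_to_nl(self.effective_volume_ul)

    def plate_by_ordinal(self, ordinal: int, attempt: int | None = None) -> CherryPickPlate:
        matches = [p for p in self.plates if p.ordinal == ordinal]
        if attempt is not None:
            matches = [p for p in matches if p.attempt == attempt]
        if not matches:
            raise ValidationError(f"no cherry-pick plate with ordinal {ordinal}")
        return max(matches, key=lambda p: p.attempt)


def _find_well(libraries: list[Library], key: WellKey) -> Well | None:
    for lib in libraries:
        if lib.contains_plate(key.plate_number):
            well = lib.wells.get(key)
            if well is not None:
                return well
    return None


def _library_of(libraries: list[Library], key: WellKey) -> Library | None:
    for lib in libraries:
        if lib.contains_plate(key.plate_number) and key in lib.wells:
            return lib
    return None


# ---------------------------------------------------------------------------
# Step 1: submission and validation
# ---------------------------------------------------------------------------


def create_request(
    screen: Screen,
    picks: list[WellKey],
    requested_volume_ul: float,
    libraries: list[Library],
    requested_by: User,
    date: _date,
    log: ActivityLog | None = None,
    **options,
) -> CherryPickRequest:
    """Record a new cherry-pick request and validate its picks."""
    request = CherryPickRequest(
        screen=screen,
        requested_by=requested_by,
        date=date,
        requested_volume_ul=requested_volume_ul,
        libraries=list(libraries),
        **options,
    )
    request.screener_picks = [ScreenerCherryPick(source_well=k) for k in picks]
    validate_picks(request, libraries)
    if log is not None:
        log.record(
            "cherry_pick_request",
            requested_by,
            date,
            links=(request, screen),
            payload={"request": screen.facility_id, "n_picks": len(picks)},
        )
    return request


def validate_picks(
    request: CherryPickRequest, libraries: list[Library]
) -> list[ScreenerCherryPick]:
    """Apply the facility's pick policies; returns the rejected picks.

    In submission order: unknown wells, duplicates of an earlier pick,
    deprecated wells and non-experimental (control/empty) wells are
    rejected, and picks beyond ``max_picks_policy`` accepted picks are
    rejected as over the limit.
    """
    seen: set[WellKey] = set()
    accepted = 0
    rejections: list[ScreenerCherryPick] = []
    for pick in request.screener_picks:
        reason = None
        well = _find_well(libraries, pick.source_well)
        if well is None:
            reason = "unknown_well"
        elif pick.source_well in seen:
            reason = "duplicate"
        elif well.deprecated:
            reason = "deprecated"
        elif not well.well_type.is_cherry_pickable:
            reason = "non_experimental"
        elif (
            request.max_picks_policy is not None and accepted >= request.max_picks_policy
        ):
            reason = "over_limit"
        if well is not None:
            seen.add(pick.source_well)
        if reason is None:
            pick.status, pick.rejection_reason = "accepted", None
            accepted += 1
        else:
            pick.status, pick.rejection_reason = "rejected", reason
            rejections.append(pick)
    return rejections


def deconvolute(request: CherryPickRequest, libraries: list[Library]) -> list[LabCherryPick]:
    """Expand accepted screener picks into lab picks.

    Small-molecule and duplex picks map one to one; a pool-format siRNA pick
    expands into one lab pick per constituent duplex well (validated to
    exist in the duplex library).  All lab picks start unfulfilled.
    """
    lab_picks: list[LabCherryPick] = []
    for pick in request.screener_picks:
        if pick.status != "accepted":
            continue
        well = _find_well(libraries, pick.source_well)
        reagent = well.reagent if well else None
        if isinstance(reagent, SilencingReagent) and reagent.silencing_type == "pool":
            for dkey in reagent.duplex_well_keys:
                dwell = _find_well(libraries, dkey)
                if dwell is None or not isinstance(dwell.reagent, SilencingReagent):
                    raise ValidationError(
                        f"pool {reagent.vendor_id!r} at {pick.source_well} references "
                        f"{dkey}, which is missing from the duplex library"
                    )
                lab_picks.append(LabCherryPick(source_well=dkey, screener_pick=pick))
        else:
            lab_picks.append(LabCherryPick(source_well=pick.source_well, screener_pick=pick))
    request.lab_picks = lab_picks
    return lab_picks


# ---------------------------------------------------------------------------
# Step 2: volume reservation
# ---------------------------------------------------------------------------


def _eligible_copies(request: CherryPickRequest, key: WellKey) -> list[Copy]:
    lib = _library_of(request.libraries, key)
    if lib is None:
        return []
    out = []
    for name in sorted(lib.copies):
        copy: Copy = lib.copies[name]
        if copy.usage_type != "cherry_pick_source":
            continue
        plate = copy.plates.get(key.plate_number)
        if plate is None or plate.retired:
            continue
        out.append(copy)
    return out


def view_well_volumes(
    request: CherryPickRequest,
) -> list[tuple[LabCherryPick, str, float, bool]]:
    """Availability report: one row per (lab pick × eligible source copy).

    ``sufficient`` means remaining ≥ the request's effective volume (a well
    holding exactly the needed volume qualifies).  Retired plates and
    screening-only copies are excluded.
    """
    need_nl = request.effective_volume_nl
    rows = []
    for pick in request.lab_picks:
        for copy in _eligible_copies(request, pick.source_well):
            remaining = copy.plates[pick.source_well.plate_number].remaining_nl[
                pick.source_well.well_name
            ]
            rows.append((pick, copy.name, nl_to_ul(remaining), remaining >= need_nl))
    return rows


def reserve_reagent(request: CherryPickRequest, log: ActivityLog | None = None,
                    performer: User | None = None, date: _date | None = None) -> int:
    """Select a source copy and debit the reserved volume for each lab pick.

    Among eligible copies whose source well holds at least the effective
    volume, the copy with the *smallest* sufficient remaining volume wins
    (nearly-empty copies are depleted first; ties break on copy name), so
    the selection is deterministic and auditable.  Picks no copy can satisfy
    stay unfulfilled.  Returns the number of picks reserved.
    """
    need_nl = request.effective_volume_nl
    reserved = 0
    for pick in request.lab_picks:
        if pick.status != "unfulfilled":
            continue
        candidates = []
        for copy in _eligible_copies(request, pick.source_well):
            remaining = copy.plates[pick.source_well.plate_number].remaining_nl[
                pick.source_well.well_name
            ]
            if remaining >= need_nl:
                candidates.append((remaining, copy.name, copy))
        if not candidates:
            continue
        _, _, chosen = min(candidates, key=lambda t: (t[0], t[1]))
        chosen.plates[pick.source_well.plate_number].remaining_nl[
            pick.source_well.well_name
        ] -= need_nl
        pick.source_copy = chosen.name
        pick.transition("reserved")
        reserved += 1
    return reserved


# ---------------------------------------------------------------------------
# Step 3: plate mapping and the robot file
# ---------------------------------------------------------------------------


def _pick_sort_key(request: CherryPickRequest, pick: LabCherryPick):
    lib = _library_of(request.libraries, pick.source_well)
    fmt = lib.plate_format if lib else PlateFormat.F384
    return (
        pick.source_well.plate_number,
        well_sort_index(pick.source_well.well_name, fmt),
        pick.source_copy or "",
    )


def map_to_plates(
    request: CherryPickRequest, destination_format: PlateFormat = PlateFormat.F384
) -> list[CherryPickPlate]:
    """Lay reserved picks out onto destination cherry-pick plates.

    Picks are ordered by (source plate, source well, copy) so each source
    plate's transfers are batched together for the liquid handler, then
    assigned to consecutive available destination wells — the plate format's
    wells minus the request's required-empty set — overflowing onto further
    plates; the plate count is ``ceil(n_reserved / n_available)``.  With
    ``randomize_layout`` the destination wells within each plate are
    permuted by a generator seeded with the request's persisted seed, so the
    layout is reproducible.  Picks respawned from one failed plate are
    mapped onto a successor plate carrying the same ordinal and the next
    attempt number.  Returns the newly created plates.
    """
    available = [
        n for n in iter_well_names(destination_format) if n not in request.required_empty_wells
    ]
    if not available:
        raise ValidationError("the required-empty set covers the whole destination plate")
    bad = set(request.required_empty_wells) - set(iter_well_names(destination_format))
    if bad:
        raise ValidationError(
            f"required-empty wells {sorted(bad)} are not wells of the "
            f"{destination_format.wells_per_plate}-well destination format"
        )
    to_map = [p for p in request.lab_picks if p.status == "reserved"]
    if not to_map:
        raise WorkflowError("no reserved picks to map")

    rng = random.Random(request.random_seed)

    # Respawned picks from a single failed plate become its successor plate.
    groups: list[tuple[int | None, list[LabCherryPick]]] = []
    respawn_ordinals = sorted({p.respawn_of_ordinal for p in to_map if p.respawn_of_ordinal})
    for ordinal in respawn_ordinals:
        groups.append((ordinal, [p for p in to_map if p.respawn_of_ordinal == ordinal]))
    fresh = [p for p in to_map if not p.respawn_of_ordinal]
    if fresh:
        groups.append((None, fresh))

    new_plates: list[CherryPickPlate] = []
    next_ordinal = max((p.ordinal for p in request.plates), default=0) + 1
    for successor_of, picks in groups:
        picks = sorted(picks, key=lambda p: _pick_sort_key(request, p))
        n_plates = math.ceil(len(picks) / len(available))
        for i in range(n_plates):
            chunk = picks[i * len(available) : (i + 1) * len(available)]
            if successor_of is not None and n_plates == 1:
                prior = request.plate_by_ordinal(successor_of)
                plate = CherryPickPlate(ordinal=successor_of, attempt=prior.attempt + 1)
            else:
                plate = CherryPickPlate(ordinal=next_ordinal)
                next_ordinal += 1
            slots = list(available)
            if request.randomize_layout:
                rng.shuffle(slots)
            for pick, slot in zip(chunk, slots):
                pick.destination_plate_ordinal = plate.ordinal
                pick.destination_well = slot
                pick.transition("mapped")
                plate.picks.append(pick)
            request.plates.append(plate)
            new_plates.append(plate)
    return new_plates


def export_plate_mapping(request: CherryPickRequest) -> str:
    """The machine-readable mapping file for the liquid handler (CSV text).

    One row per mapped/processed pick, ordered by destination plate then
    source plate (source plates batched within each destination plate).
    """
    picks = [
        p
        for p in request.lab_picks
        if p.destination_plate_ordinal is not None and p.status in ("mapped", "plated")
    ]
    if not picks:
        raise WorkflowError("request has no mapped picks; run map_to_plates first")
    volume = request.effective_volume_ul
    buf = io.StringIO()
    buf.write("source_plate,source_copy,source_well,destination_plate_ordinal,destination_well,volume_uL\n")
    for p in sorted(
        picks,
        key=lambda p: (p.destination_plate_ordinal,) + _pick_sort_key(request, p),
    ):
        buf.write(
            f"{p.source_well.plate_number},{p.source_copy},{p.source_well.well_name},"
            f"{p.destination_plate_ordinal},{p.destination_well},{volume:g}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Step 4: plating outcomes
# ---------------------------------------------------------------------------


def update_plate_status(
    request: CherryPickRequest,
    plate_ordinal: int,
    new_status: str,
    performer: User,
    date: _date,
    log: ActivityLog,
) -> Activity:
    """Record the outcome of producing one cherry-pick plate.

    ``plated`` marks the transfers done (a lab liquid-transfer activity is
    recorded).  ``canceled`` reverses every reservation on the plate,
    crediting the volumes back to their source copy wells.  ``failed``
    keeps the debits — the reagent was consumed in the failed attempt — and
    respawns the plate's picks as fresh unfulfilled picks that repeat the
    reservation and mapping workflow, yielding a successor plate with the
    next attempt number.
    """
    if new_status not in ("plated", "failed", "canceled"):
        raise ValidationError(f"unknown plate status {new_status!r}")
    plate = request.plate_by_ordinal(plate_ordinal)
    if plate.status != "not_plated":
        raise WorkflowError(
            f"plate {plate_ordinal} is already {plate.status}; terminal statuses are final"
        )
    plate.status = new_status
    if new_status == "plated":
        for pick in plate.picks:
            pick.transition("plated")
        return log.record(
            "cherry_pick_liquid_transfer",
            performer,
            date,
            links=(request, plate),
            payload={
                "request": request.screen.facility_id,
                "plate_ordinal": plate_ordinal,
                "n_picks": len(plate.picks),
            },
        )
    if new_status == "canceled":
        need_nl = request.effective_volume_nl
        for pick in plate.picks:
            lib = _library_of(request.libraries, pick.source_well)
            copy: Copy = lib.copies[pick.source_copy]
            copy.plates[pick.source_well.plate_number].remaining_nl[
                pick.source_well.well_name
            ] += need_nl
            pick.transition("canceled")
    else:  # failed — volumes stay debited, picks respawn for another attempt
        for pick in plate.picks:
            pick.transition("failed")
            request.lab_picks.append(
                LabCherryPick(
                    source_well=pick.source_well,
                    screener_pick=pick.screener_pick,
                    respawn_of_ordinal=plate.ordinal,
                )
            )
    return log.record(
        "cherry_pick_plate_status",
        performer,
        date,
        links=(request, plate),
        payload={
            "request": request.screen.facility_id,
            "plate_ordinal": plate_ordinal,
            "status": new_status,
        },
    )


def rollover_unfulfilled(request: CherryPickRequest, date: _date | None = None) -> CherryPickRequest:
    """Move the unfulfillable picks into a fresh request for later processing.

    The unfulfilled lab picks are re-collapsed to screener-pick level (a
    pool whose duplexes were all unfulfillable reappears as one pick of the
    pool well) and the originals are marked rolled over; a second rollover
    of the same request is an error.
    """
    if request.rolled_over:
        raise WorkflowError("this request's unfulfilled picks were already rolled over")
    unfulfilled = [p for p in request.lab_picks if p.status == "unfulfilled"]
    if not unfulfilled:
        raise WorkflowError("request has no unfulfilled picks to roll over")
    source_wells: list[WellKey] = []
    for pick in unfulfilled:
        origin = pick.screener_pick.source_well
        if origin not in source_wells:
            source_wells.append(origin)
    request.rolled_over = True
    new_request = create_request(
        screen=request.screen,
        picks=source_wells,
        requested_volume_ul=request.requested_volume_ul,
        libraries=request.libraries,
        requested_by=request.requested_by,
        date=date or request.date,
        approved_volume_ul=request.approved_volume_ul,
        randomize_layout=request.randomize_layout,
        required_empty_wells=request.required_empty_wells,
        random_seed=request.random_seed,
        max_picks_policy=None,
    )
    deconvolute(new_request, new_request.libraries)
    return new_request
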