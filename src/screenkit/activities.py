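"""Append-only audit trail of lab and administrative events.

Every volume-mutating or policy-relevant operation in the package records an
activity: who performed it, when, on what, and a kind-specific payload (the
"who, what, when and why").  Lab activities describe physical events
(screening a set of plates, plating cherry picks); administrative activities
describe data decisions made by staff (deprecating wells, correcting
volumes, ticking a screener's checklist).  The log is strictly append-only —
activities are never edited or deleted — and the set of kinds is an open
registry so facilities can add their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Any, Iterable

from .core_model import User, ValidationError

__all__ = ["Activity", "ActivityLog", "register_kind", "KIND_REGISTRY"]

# kind -> (category, required payload keys); extensible via register_kind().
KIND_REGISTRY: dict[str, tuple[str, tuple[str, ...]]] = {
    "library_screening": ("lab", ("copy", "plates", "volume_per_well_ul", "replicates")),
    "cherry_pick_liquid_transfer": ("lab", ("request", "plate_ordinal", "n_picks")),
    "well_deprecation": ("administrative", ("library", "wells", "reason")),
    "well_volume_correction": ("administrative", ("copy", "well", "old_ul", "new_ul", "reason")),
    "checklist_item_event": ("administrative", ("user", "item", "status")),
    # Audited but package-specific kinds:
    "library_contents_import": ("administrative", ("library", "version")),
    "cherry_pick_request": ("administrative", ("request", "n_picks")),
    "cherry_pick_plate_status": ("administrative", ("request", "plate_ordinal", "status")),
}


def register_kind(kind: str, category: str, required_payload: Iterable[str] = ()) -> None:
    """Add a new activity kind to the registry (the hierarchy is extensible)."""
    if category not in ("lab", "administrative"):
        raise ValidationError(f"activity category must be lab/administrative, got {category!r}")
    if kind in KIND_REGISTRY:
        raise ValidationError(f"activity kind {kind!r} already registered")
    KIND_REGISTRY[kind] = (category, tuple(required_payload))


@dataclass(frozen=True)
class Activity:
    id: int
    kind: str
    category: str
    performed_by: User
    date: _date
    links: tuple[Any, ...]
    payload: dict[str, Any]
    comments: str = ""


class ActivityLog:
    """The facility-wide, append-only activity store."""

    def __init__(self):
        self._activities: list[Activity] = []
        self._next_id = 1

    def record(
        self,
        kind: str,
        performer: User,
        date: _date,
        links: Iterable[Any] = (),
        payload: dict[str, Any] | None = None,
        comments: str = "",
    ) -> Activity:
        """Append an activity, assigning the next sequential id.

        The event ``date`` may precede the record time (activities are often
        entered after the fact).  Raises on an unknown kind or a payload
        missing that kind's required fields.
        """
        if kind not in KIND_REGISTRY:
            raise ValidationError(f"unknown activity kind {kind!r}")
        category, required = KIND_REGISTRY[kind]
        payload = dict(payload or {})
        missing = [k for k in required if k not in payload]
        if missing:
            raise ValidationError(
                f"activity kind {kind!r} payload missing fields: {', '.join(missing)}"
            )
        act = Activity(
            id=self._next_id,
            kind=kind,
            category=category,
            performed_by=performer,
            date=date,
            links=tuple(links),
            payload=payload,
            comments=comments,
        )
        self._next_id += 1
        self._activities.append(act)
        if kind == "checklist_item_event":
            self._apply_checklist_event(act)
        return act

    @staticmethod
    def _apply_checklist_event(act: Activity) -> None:
        # A checklist event materialises on the target user's checklist.
        from .core_model import ChecklistItem

        target: User = act.payload["user"]
        name, status = act.payload["item"], act.payload["status"]
        for item in target.checklist_items:
            if item.name == name:
                item.status = status
                item.date = act.date.isoformat()
                return
        target.checklist_items.append(
            ChecklistItem(name=name, status=status, date=act.date.isoformat())
        )

    def query(
        self,
        kind: str | None = None,
        performer: User | None = None,
        date_from: _date | None = None,
        date_to: _date | None = None,
        entity: Any = None,
    ) -> list[Activity]:
        """Matching activities, ordered by (date, id); filters are conjunctive."""
        out = []
        for a in self._activities:
            if kind is not None and a.kind != kind:
                continue
            if performer is not None and a.performed_by != performer:
                continue
            if date_from is not None and a.date < date_from:
                continue
            if date_to is not None and a.date > date_to:
                continue
            if entity is not None and not any(link is entity for link in a.links):
                continue
            out.append(a)
        return sorted(out, key=lambda a: (a.date, a.id))

    def __len__(self) -> int:
        return len(self._activities)

    def __iter__(self):
        return iter(self._activities)

    def to_rows(self) -> list[dict[str, Any]]:
        """Flat export rows (for the CSV/CLI listing)."""
        return [
            {
                "id": a.id,
                "kind": a.kind,
                "category": a.category,
                "performed_by": a.performed_by.id,
                "date": a.date.isoformat(),
                "comments": a.comments,
            }
            for a in self._activities
        ]
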