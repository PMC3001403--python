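"""Tiered, reciprocity-based visibility of screens and their data.

A facility hosting many independent research groups must let screeners
choose how much of their data to share.  Each screen carries a *data
sharing level*: 0 shares everything, 1 withholds details of non-positive
wells, 2 shares positives and the protocol, 3 is private.  Access is
reciprocal — a screener who shares more of their own data sees more of
others': with the user's own level ``u`` and the target screen's level
``s``, the default policy grants

* **full** access to a screen's own lab head, lead screener and
  collaborators, and to administrators holding the read-everything role;
* otherwise **none** when either side is private (``u = 3`` or ``s = 3``);
* otherwise **full** when ``u ≤ s`` (the user shares at least as much as
  the target screen does);
* otherwise **metadata only** (``u > s``): the screen's existence and
  descriptive fields, but no data columns.

Reciprocity is partitioned by screen type — small-molecule sharing does not
unlock RNAi screens and vice versa.  The policy object is pluggable so a
facility can substitute its own decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

from .core_model import READ_EVERYTHING_ROLE, User, ValidationError
from .screen_results import DataColumn, Screen, ScreenResult

__all__ = [
    "AccessLevel",
    "VisibilityDecision",
    "DataSharingPolicy",
    "ReciprocityPolicy",
    "effective_access",
    "visible_columns",
]

PRIVATE_LEVEL = 3


def _check_level(level: int) -> int:
    if not 0 <= level <= 3:
        raise ValidationError(f"data sharing level must be 0–3, got {level}")
    return level


class AccessLevel(IntEnum):
    """How much of a screen a user may see (higher grants strictly more)."""

    NONE = 0
    METADATA_ONLY = 1
    POSITIVES_AND_PROTOCOL = 2
    FULL = 3


@dataclass(frozen=True)
class VisibilityDecision:
    subject: User
    screen: Screen
    access: AccessLevel


class DataSharingPolicy:
    """Interface for pluggable access policies."""

    def effective_access(self, user: User, screen: Screen) -> VisibilityDecision:
        raise NotImplementedError


class ReciprocityPolicy(DataSharingPolicy):
    """The default share-more-see-more policy described in the module docs."""

    def effective_access(self, user: User, screen: Screen) -> VisibilityDecision:
        access = AccessLevel.NONE
        if user in screen.members() or READ_EVERYTHING_ROLE in user.roles:
            access = AccessLevel.FULL
        elif screen.screen_type in user.data_sharing_levels:
            u = _check_level(user.data_sharing_levels[screen.screen_type])
            s = _check_level(screen.data_sharing_level)
            if s == PRIVATE_LEVEL or u == PRIVATE_LEVEL:
                access = AccessLevel.NONE
            elif u <= s:
                access = AccessLevel.FULL
            else:
                access = AccessLevel.METADATA_ONLY
        return VisibilityDecision(subject=user, screen=screen, access=access)


_DEFAULT_POLICY = ReciprocityPolicy()


def effective_access(
    user: User, screen: Screen, policy: DataSharingPolicy | None = None
) -> VisibilityDecision:
    """Evaluate the (possibly facility-customised) sharing policy."""
    return (policy or _DEFAULT_POLICY).effective_access(user, screen)


def visible_columns(
    decision: VisibilityDecision, screen_result: ScreenResult
) -> list[DataColumn]:
    """The data columns a decision exposes.

    Full access exposes every column; positives-and-protocol access exposes
    only the positives-indicator columns; metadata-only and no access expose
    none.
    """
    if decision.access is AccessLevel.FULL:
        return list(screen_result.columns)
    if decision.access is AccessLevel.POSITIVES_AND_PROTOCOL:
        return [c for c in screen_result.columns if c.is_positives_column]
    return []
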