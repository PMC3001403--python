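"""Screens, imported result data, positives, and cross-screen comparison.

A *screen* records one screening effort — its protocol, people, status
history and data-sharing level — and owns at most one *screen result*: the
per-well values imported from a two-part workbook (a "Data Headers" sheet
describing each data column, then one or more data sheets of values).
Columns are either raw readouts (with replicate / time-point / readout
metadata) or *derived* columns computed outside this system by the
screener's analysis software; derived values are imported as-is, and only
the derivation graph (each derived column referencing strictly earlier
columns) is validated here.

Positives — the reagents the screener calls active — are expressed by a
column's *positive indicator*: a boolean column, a partitioned column
(strong / medium / weak / none, any non-none partition counting as
positive), or a numeric column with a screener-chosen cutoff that values
must strictly exceed in the stated direction (inhibition screens cut
downward).

Screens that tested common reagents can be merged into a single outer-joined
comparison table, optionally decorated with per-reagent *study* annotations
(externally sourced information such as toxicity or off-target flags), and
any numeric column of a screened plate can be pivoted into a plate-shaped
matrix for heat-map display.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Any, Iterable

import numpy as np
import pandas as pd
from openpyxl import load_workbook

from .core_model import (
    ScreenType,
    User,
    ValidationError,
    WellKey,
    WellType,
    parse_well_name,
    format_well_name,
)
from .library_io import Library

__all__ = [
    "Screen",
    "ScreenResult",
    "DataColumn",
    "Study",
    "PARTITIONS",
    "SCREEN_STATUSES",
    "import_screen_result",
    "classify_positives",
    "positives_summary",
    "merge_comparison_table",
    "filter_table",
    "plate_heatmap",
    "export_table",
]

PARTITIONS = ("strong", "medium", "weak", "none")
SCREEN_STATUSES = ("pending", "accepted", "ongoing", "completed", "dropped")
VALUE_KINDS = ("numeric", "text", "boolean", "partitioned")


@dataclass
class DataColumn:
    """One named column of per-well values in a screen result."""

    name: str
    value_kind: str = "numeric"
    replicate_ordinal: int | None = None
    time_point: str | None = None
    readout_technology: str | None = None
    derived: bool = False
    derived_from: list[str] = field(default_factory=list)
    description: str = ""
    # None, or {"kind": "boolean"} / {"kind": "partition"}
    # / {"kind": "threshold", "cutoff": float, "direction": "above"|"below"}
    positive_indicator: dict[str, Any] | None = None

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"column {self.name!r}: unknown value kind {self.value_kind!r}")
        if self.derived and not self.derived_from:
            raise ValidationError(f"derived column {self.name!r} must reference source columns")
        pi = self.positive_indicator
        if pi is not None:
            kind = pi.get("kind")
            if kind == "partition" and self.value_kind != "partitioned":
                raise ValidationError(
                    f"column {self.name!r}: a partition indicator requires partitioned values"
                )
            if kind == "threshold":
                if self.value_kind != "numeric":
                    raise ValidationError(
                        f"column {self.name!r}: a threshold indicator requires numeric values"
                    )
                if pi.get("direction") not in ("above", "below"):
                    raise ValidationError(
                        f"column {self.name!r}: threshold direction must be above/below"
                    )
                float(pi["cutoff"])
            elif kind == "boolean":
                if self.value_kind != "boolean":
                    raise ValidationError(
                        f"column {self.name!r}: a boolean indicator requires boolean values"
                    )
            elif kind != "partition":
                raise ValidationError(f"column {self.name!r}: unknown indicator kind {kind!r}")

    @property
    def is_positives_column(self) -> bool:
        return self.positive_indicator is not None


@dataclass
class ScreenResult:
    """The imported data of one screen: columns plus typed per-well values."""

    screen: "Screen"
    columns: list[DataColumn] = field(default_factory=list)
    # column name -> {WellKey: typed value}
    data: dict[str, dict[WellKey, Any]] = field(default_factory=dict)
    assay_well_types: dict[WellKey, WellType] = field(default_factory=dict)
    date_created: _date | None = None
    date_last_updated: _date | None = None

    def column(self, name: str) -> DataColumn:
        for col in self.columns:
            if col.name == name:
                return col
        raise ValidationError(f"screen {self.screen.facility_id!r} has no column {name!r}")

    @property
    def n_values(self) -> int:
        return sum(len(v) for v in self.data.values())

    def experimental_wells(self, column: DataColumn | str) -> list[WellKey]:
        """Experimental wells holding a value in the given column."""
        name = column if isinstance(column, str) else column.name
        return [
            w
            for w in self.data.get(name, {})
            if self.assay_well_types.get(w) is WellType.EXPERIMENTAL
        ]


@dataclass
class Screen:
    facility_id: str
    screen_type: ScreenType
    title: str = ""
    summary: str = ""
    assay_protocol: str = ""
    lab_head: User | None = None
    lead_screener: User | None = None
    collaborators: set[User] = field(default_factory=set)
    status_history: list[tuple[_date, str]] = field(default_factory=list)
    data_sharing_level: int = 3
    screen_result: ScreenResult | None = None
    libraries: list[Library] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)

    def add_status(self, date: _date, status: str) -> None:
        if status not in SCREEN_STATUSES:
            raise ValidationError(f"unknown screen status {status!r}")
        if self.status_history and date < self.status_history[-1][0]:
            raise ValidationError("screen status dates must be non-decreasing")
        self.status_history.append((date, status))

    def members(self) -> set[User]:
        out = set(self.collaborators)
        if self.lab_head:
            out.add(self.lab_head)
        if self.lead_screener:
            out.add(self.lead_screener)
        return out


@dataclass
class Study:
    """Externally sourced per-reagent annotations (publication or database data)."""

    study_id: str
    title: str = ""
    annotation_columns: list[DataColumn] = field(default_factory=list)
    # reagent vendor_id -> {annotation column name: value}
    values: dict[str, dict[str, Any]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Workbook import
# ---------------------------------------------------------------------------

DATA_HEADERS_SHEET = "Data Headers"
HEADER_COLUMNS = (
    "Name",
    "Kind",
    "Replicate",
    "Time_Point",
    "Readout_Technology",
    "Derived",
    "Derived_From",
    "Positive_Indicator",
    "Description",
)


def parse_indicator(spec: str | None) -> dict[str, Any] | None:
    """Parse a positive-indicator cell: '', 'boolean', 'partition', 'threshold:2.0:above'."""
    if not spec or not str(spec).strip():
        return None
    parts = str(spec).strip().split(":")
    if parts[0] == "boolean":
        return {"kind": "boolean"}
    if parts[0] == "partition":
        return {"kind": "partition"}
    if parts[0] == "threshold":
        if len(parts) != 3:
            raise ValidationError(
                f"threshold indicator must be 'threshold:<cutoff>:<above|below>', got {spec!r}"
            )
        return {"kind": "threshold", "cutoff": float(parts[1]), "direction": parts[2]}
    raise ValidationError(f"unknown positive-indicator spec {spec!r}")


def indicator_to_spec(pi: dict[str, Any] | None) -> str:
    if pi is None:
        return ""
    if pi["kind"] == "threshold":
        return f"threshold:{pi['cutoff']}:{pi['direction']}"
    return pi["kind"]


def _parse_header_rows(ws) -> list[DataColumn]:
    rows = ws.iter_rows(values_only=True)
    header = [str(h).strip() if h is not None else "" for h in next(rows)]
    columns: list[DataColumn] = []
    seen: set[str] = set()
    for values in rows:
        if values is None or all(v is None for v in values):
            continue
        row = dict(zip(header, values))
        name = str(row.get("Name") or "").strip()
        if not name:
            raise ValidationError("data header row with no Name")
        derived = str(row.get("Derived") or "").strip().lower() in ("true", "1", "yes")
        derived_from = [
            t.strip() for t in str(row.get("Derived_From") or "").split(";") if t.strip()
        ]
        col = DataColumn(
            name=name,
            value_kind=str(row.get("Kind") or "numeric").strip().lower(),
            replicate_ordinal=int(row["Replicate"]) if row.get("Replicate") else None,
            time_point=str(row["Time_Point"]) if row.get("Time_Point") else None,
            readout_technology=(
                str(row["Readout_Technology"]) if row.get("Readout_Technology") else None
            ),
            derived=derived,
            derived_from=derived_from,
            description=str(row.get("Description") or ""),
            positive_indicator=parse_indicator(row.get("Positive_Indicator")),
        )
        if col.derived:
            for ref in col.derived_from:
                if ref not in seen:
                    raise ValidationError(
                        f"derived column {name!r} references {ref!r}, which is not an "
                        "earlier column"
                    )
        columns.append(col)
        seen.add(name)
    if not columns:
        raise ValidationError("the Data Headers sheet defines no columns")
    return columns


def _type_value(raw: Any, col: DataColumn, where: str) -> Any:
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        return None
    kind = col.value_kind
    if kind == "numeric":
        if isinstance(raw, bool) or not isinstance(raw, (int, float)):
            try:
                return float(str(raw))
            except ValueError:
                raise ValidationError(
                    f"{where}: expected a number in column {col.name!r}, got {raw!r}"
                ) from None
        return float(raw)
    if kind == "boolean":
        if isinstance(raw, bool):
            return raw
        text = str(raw).strip().lower()
        if text in ("true", "1", "yes"):
            return True
        if text in ("false", "0", "no"):
            return False
        raise ValidationError(f"{where}: expected a boolean in column {col.name!r}, got {raw!r}")
    if kind == "partitioned":
        text = str(raw).strip().lower()
        if text not in PARTITIONS:
            raise ValidationError(
                f"{where}: expected one of {PARTITIONS} in column {col.name!r}, got {raw!r}"
            )
        return text
    return str(raw)


def import_screen_result(
    screen: Screen, workbook_stream, date: _date | None = None
) -> ScreenResult:
    """Import (or re-import) a screen's result workbook.

    The workbook must contain a ``"Data Headers"`` sheet describing each
    data column, and one or more data sheets with ``Plate``, ``Well`` and
    ``Assay_Well_Type`` columns followed by one column per data header.
    Wells are validated against the screen's libraries when those are
    attached.  A re-import replaces all values and bumps the last-updated
    date while preserving the created date.
    """
    if isinstance(workbook_stream, (bytes, bytearray)):
        workbook_stream = io.BytesIO(workbook_stream)
    wb = load_workbook(workbook_stream, read_only=True, data_only=True)
    if DATA_HEADERS_SHEET not in wb.sheetnames:
        raise ValidationError(f'workbook lacks the "{DATA_HEADERS_SHEET}" sheet')
    columns = _parse_header_rows(wb[DATA_HEADERS_SHEET])
    col_by_name = {c.name: c for c in columns}

    fmt = screen.libraries[0].plate_format if screen.libraries else None
    result = ScreenResult(screen=screen, columns=columns)
    for ws in wb.worksheets:
        if ws.title == DATA_HEADERS_SHEET:
            continue
        rows = ws.iter_rows(values_only=True)
        try:
            header = [str(h).strip() if h is not None else "" for h in next(rows)]
        except StopIteration:
            continue
        for c in ("Plate", "Well"):
            if c not in header:
                raise ValidationError(f"sheet {ws.title!r} lacks the {c!r} column")
        data_names = [h for h in header if h in col_by_name]
        for row_ordinal, values in enumerate(rows, start=2):
            if values is None or all(v is None for v in values):
                continue
            row = dict(zip(header, values))
            where = f"sheet {ws.title!r} row {row_ordinal}"
            plate = int(row["Plate"])
            if fmt is None:
                well_fmt = _guess_format(str(row["Well"]))
            else:
                well_fmt = fmt
            coord = parse_well_name(str(row["Well"]), well_fmt)
            key = WellKey(plate, format_well_name(coord, well_fmt))
            if screen.libraries and not any(
                lib.contains_plate(plate) for lib in screen.libraries
            ):
                raise ValidationError(
                    f"{where}: well {key} is not on any library screened by "
                    f"{screen.facility_id!r}"
                )
            awt = WellType.parse(str(row.get("Assay_Well_Type") or "experimental"))
            result.assay_well_types[key] = awt
            for name in data_names:
                value = _type_value(row.get(name), col_by_name[name], where)
                if value is not None:
                    result.data.setdefault(name, {})[key] = value
    wb.close()

    today = date or _date.today()
    if screen.screen_result is not None:
        result.date_created = screen.screen_result.date_created
        screen.comments.append(f"{today.isoformat()}: screen result re-imported")
    else:
        result.date_created = today
    result.date_last_updated = today
    screen.screen_result = result
    return result


def _guess_format(well_name: str):
    from .core_model import PlateFormat

    for fmt in (PlateFormat.F384, PlateFormat.F1536):
        try:
            parse_well_name(well_name, fmt)
            return fmt
        except ValidationError:
            continue
    return PlateFormat.F1536


# ---------------------------------------------------------------------------
# Positives
# ---------------------------------------------------------------------------


def classify_positives(
    result: ScreenResult, column: DataColumn | str
) -> dict[WellKey, bool]:
    """Per-well positive calls for one positives column (experimental wells only)."""
    col = result.column(column) if isinstance(column, str) else column
    if col.positive_indicator is None:
        raise ValidationError(f"column {col.name!r} has no positive indicator")
    pi = col.positive_indicator
    calls: dict[WellKey, bool] = {}
    for well in result.experimental_wells(col):
        value = result.data[col.name][well]
        if pi["kind"] == "boolean":
            calls[well] = bool(value)
        elif pi["kind"] == "partition":
            calls[well] = value != "none"
        else:  # threshold: strictly exceed the cutoff in the stated direction
            cutoff = float(pi["cutoff"])
            calls[well] = value > cutoff if pi["direction"] == "above" else value < cutoff
    return calls


def positives_summary(result: ScreenResult, column: DataColumn | str) -> tuple[int, float]:
    """(count, percent) of positives among experimental wells with a value."""
    col = result.column(column) if isinstance(column, str) else column
    calls = classify_positives(result, col)
    n_experimental = len(result.experimental_wells(col))
    if n_experimental == 0:
        raise ValidationError(
            f"column {col.name!r} has no experimental wells; the positives "
            "percentage is undefined"
        )
    count = sum(calls.values())
    return count, 100.0 * count / n_experimental


# ---------------------------------------------------------------------------
# Cross-screen comparison
# ---------------------------------------------------------------------------


def _source_id(source: ScreenResult | Study) -> str:
    return source.study_id if isinstance(source, Study) else source.screen.facility_id


def _well_vendor_id(source: ScreenResult, well: WellKey) -> str | None:
    for lib in source.screen.libraries:
        if lib.contains_plate(well.plate_number):
            w = lib.wells.get(well)
            if w is not None and w.reagent is not None:
                return w.reagent.vendor_id
    return None


def merge_comparison_table(
    sources: list[ScreenResult | Study], key_mode: str = "well"
) -> pd.DataFrame:
    """Merge screens (and studies) over common reagents into one table.

    One row per key present in any source (outer join); keys are
    ``"plate:well"`` strings or reagent vendor ids depending on
    ``key_mode``.  Data columns are provenance-named ``"<source>::<column>"``;
    missing cells are empty (NA), never zero.  Study annotations join by
    reagent in either mode: in well mode they decorate rows whose well
    resolves to an annotated reagent.
    """
    if key_mode not in ("well", "reagent"):
        raise ValidationError(f"key_mode must be well or reagent, got {key_mode!r}")
    key_order: list[str] = []
    key_seen: set[str] = set()
    cells: dict[str, dict[str, Any]] = {}  # column -> {key: value}
    col_order: list[str] = []
    key_vendor: dict[str, str] = {}  # well-mode key -> vendor id (for study joins)

    def add_key(key: str):
        if key not in key_seen:
            key_seen.add(key)
            key_order.append(key)

    screen_sources = [s for s in sources if isinstance(s, ScreenResult)]
    study_sources = [s for s in sources if isinstance(s, Study)]

    for src in screen_sources:
        sid = _source_id(src)
        wells: list[WellKey] = sorted({w for col in src.data.values() for w in col})
        for col in src.columns:
            full = f"{sid}::{col.name}"
            col_order.append(full)
            cells[full] = {}
        for well in wells:
            if key_mode == "well":
                key = str(well)
                vid = _well_vendor_id(src, well)
                if vid is not None:
                    key_vendor[key] = vid
            else:
                key = _well_vendor_id(src, well)
                if key is None:
                    continue
            add_key(key)
            for col in src.columns:
                value = src.data.get(col.name, {}).get(well)
                if value is not None:
                    cells[f"{sid}::{col.name}"][key] = value

    for study in study_sources:
        sid = _source_id(study)
        for col in study.annotation_columns:
            full = f"{sid}::{col.name}"
            col_order.append(full)
            cells[full] = {}
        if key_mode == "reagent":
            for vid in study.values:
                add_key(vid)
        for key in key_order:
            vid = key if key_mode == "reagent" else key_vendor.get(key)
            annotations = study.values.get(vid) if vid else None
            if annotations:
                for col in study.annotation_columns:
                    if col.name in annotations:
                        cells[f"{sid}::{col.name}"][key] = annotations[col.name]

    table = pd.DataFrame(index=key_order, columns=col_order, dtype=object)
    for full, by_key in cells.items():
        for key, value in by_key.items():
            table.at[key, full] = value
    table.insert(0, "key", key_order)
    return table.reset_index(drop=True)


_NUMERIC_OPS = ("lt", "le", "gt", "ge", "between")


def filter_table(
    table: pd.DataFrame, criteria: list[tuple[str, str, Any]]
) -> pd.DataFrame:
    """Filter rows by a conjunction of (column, operator, operand) criteria.

    Operators: eq, lt, le, gt, ge, between (ranking operators apply to
    numeric data only), contains (case-insensitive; text only).  Empty cells
    never satisfy any criterion.  Row order is preserved.
    """
    mask = pd.Series(True, index=table.index)
    for column, op, operand in criteria:
        if column not in table.columns:
            raise ValidationError(f"no such column {column!r}")
        series = table[column]
        present = series.notna()
        values = series[present]
        if op == "eq":
            ok = values == operand
        elif op in _NUMERIC_OPS:
            try:
                numeric = values.astype(float)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"operator {op!r} applies to numeric columns; {column!r} is not"
                ) from None
            if op == "between":
                lo, hi = operand
                ok = (numeric >= lo) & (numeric <= hi)
            else:
                ok = getattr(numeric, op)(float(operand))
        elif op == "contains":
            if not all(isinstance(v, str) for v in values):
                raise ValidationError(f"operator 'contains' applies to text columns; {column!r} is not")
            ok = values.str.contains(str(operand), case=False, regex=False)
        else:
            raise ValidationError(f"unknown filter operator {op!r}")
        crit_mask = pd.Series(False, index=table.index)
        crit_mask.loc[ok[ok.astype(bool)].index] = True
        mask &= crit_mask
    return table[mask]


# ---------------------------------------------------------------------------
# Heat-map matrix
# ---------------------------------------------------------------------------


def plate_heatmap(
    result: ScreenResult, plate_number: int, column: DataColumn | str
) -> np.ndarray:
    """Pivot one plate's values of a numeric column into a plate-shaped matrix.

    Returns an ``n_rows × n_cols`` float array with NaN for wells without a
    value.  Callers wanting to compare normalisation/scoring methods side by
    side simply request one matrix per column.
    """
    col = result.column(column) if isinstance(column, str) else column
    if col.value_kind != "numeric":
        raise ValidationError(f"heat maps require a numeric column; {col.name!r} is not")
    screen = result.screen
    fmt = None
    for lib in screen.libraries:
        if lib.contains_plate(plate_number):
            fmt = lib.plate_format
            break
    if fmt is None:
        fmt = _guess_format_from_wells(result, plate_number)
    values = {
        w: v for w, v in result.data.get(col.name, {}).items() if w.plate_number == plate_number
    }
    if not values:
        raise ValidationError(f"plate {plate_number} has not been screened in column {col.name!r}")
    matrix = np.full((fmt.n_rows, fmt.n_cols), np.nan)
    for well, value in values.items():
        c = parse_well_name(well.well_name, fmt)
        matrix[c.row, c.col] = value
    return matrix


def _guess_format_from_wells(result: ScreenResult, plate_number: int):
    from .core_model import PlateFormat

    names = [w.well_name for w in result.assay_well_types if w.plate_number == plate_number]
    for fmt in (PlateFormat.F96, PlateFormat.F384, PlateFormat.F1536):
        try:
            for n in names:
                parse_well_name(n, fmt)
            return fmt
        except ValidationError:
            continue
    raise ValidationError(f"cannot infer a plate format for plate {plate_number}")


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------


def export_table(table: pd.DataFrame, fmt: str = "csv"):
    """Serialise a comparison/filter table as CSV text or XLSX bytes."""
    if fmt == "csv":
        return table.to_csv(index=False)
    if fmt == "xlsx":
        buf = io.BytesIO()
        table.to_excel(buf, index=False)
        return buf.getvalue()
    raise ValidationError(f"unknown table export format {fmt!r}")
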