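"""Screening-library contents: import, versioning, search and export.

A *library* is a cohesive set of plated reagents — small molecules or RNAi
silencing reagents — spanning a contiguous plate-number range in one of the
standard microplate formats.  Small-molecule contents arrive as SD (SDF)
files whose per-record data fields carry plate/well locations and vendor and
structure information; RNAi contents arrive as spreadsheet workbooks.  Wells
absent from an import file are created as ``empty``: contents files
conventionally list only the filled wells.

Libraries are versioned: importing a corrected contents file increments the
version and retains every prior well map untouched, so historical screen
data can always be interpreted against the contents it was produced with.

Structure strings (SMILES/InChI) are stored verbatim; no chemical
registration or canonicalisation is attempted here.  SD-file molblocks are
tolerated and ignored — only the data fields matter to the importer.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

from openpyxl import Workbook, load_workbook

from .core_model import (
    PlateFormat,
    ScreenType,
    ValidationError,
    WellCoordinate,
    WellKey,
    WellType,
    format_well_name,
    parse_well_name,
)

__all__ = [
    "LibraryMeta",
    "Library",
    "Well",
    "SmallMoleculeReagent",
    "SilencingReagent",
    "import_small_molecule_library",
    "import_rnai_library",
    "import_contents_version",
    "batch_well_search",
    "export_wells",
    "SDF_FIELDS",
    "RNAI_COLUMNS",
]

# Canonical SD-file data-field names.  Foreign dialects can be accommodated
# by passing a {canonical: actual} mapping to the importer.
SDF_FIELDS = (
    "Plate",
    "Well",
    "Well_Type",
    "Vendor",
    "Vendor_ID",
    "Smiles",
    "InChI",
    "Molecular_Mass",
    "Chemical_Names",
    "PubChem_CIDs",
    "ChemBank_IDs",
    "Deprecated",
    "Deprecation_Reason",
)

RNAI_COLUMNS = (
    "Plate",
    "Well",
    "Well_Type",
    "Vendor",
    "Vendor_ID",
    "Silencing_Type",
    "Entrez_Gene_ID",
    "Gene_Symbol",
    "GenBank",
    "Species",
    "Sequence",
    "Duplex_Wells",
    "Deprecated",
    "Deprecation_Reason",
)


@dataclass
class SmallMoleculeReagent:
    vendor: str
    vendor_id: str
    smiles: str = ""
    inchi: str = ""
    molecular_mass: float | None = None
    chemical_names: list[str] = field(default_factory=list)
    pubchem_cids: list[int] = field(default_factory=list)
    chembank_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.smiles and not self.inchi:
            raise ValidationError(
                f"reagent {self.vendor_id!r}: at least one of SMILES/InChI is required"
            )
        if self.molecular_mass is not None and self.molecular_mass <= 0:
            raise ValidationError(
                f"reagent {self.vendor_id!r}: molecular mass must be positive"
            )


@dataclass
class SilencingReagent:
    vendor: str
    vendor_id: str
    silencing_type: str  # "pool" | "duplex"
    sequences: list[str] = field(default_factory=list)
    entrez_gene_id: int | None = None
    gene_symbol: str = ""
    genbank_accessions: list[str] = field(default_factory=list)
    species: str = ""
    duplex_well_keys: list[WellKey] = field(default_factory=list)

    def __post_init__(self):
        if self.silencing_type not in ("pool", "duplex"):
            raise ValidationError(
                f"reagent {self.vendor_id!r}: silencing type must be pool or duplex"
            )
        if self.silencing_type == "pool" and not self.duplex_well_keys:
            raise ValidationError(
                f"pool reagent {self.vendor_id!r} must reference its duplex wells"
            )
        if self.silencing_type == "duplex" and self.duplex_well_keys:
            raise ValidationError(
                f"duplex reagent {self.vendor_id!r} may not carry duplex well references"
            )


Reagent = SmallMoleculeReagent | SilencingReagent


@dataclass
class Well:
    key: WellKey
    well_type: WellType = WellType.EMPTY
    reagent: Reagent | None = None
    deprecated: bool = False
    deprecation_reason: str | None = None

    def __post_init__(self):
        if self.deprecated and not self.deprecation_reason:
            raise ValidationError(f"well {self.key}: deprecation requires a reason")
        if self.well_type in (WellType.EMPTY, WellType.BUFFER) and self.reagent is not None:
            raise ValidationError(f"well {self.key}: {self.well_type.value} wells hold no reagent")


@dataclass
class LibraryMeta:
    """Header fields supplied alongside a contents file."""

    short_name: str
    screen_type: ScreenType
    plate_format: PlateFormat
    start_plate: int
    end_plate: int

    def __post_init__(self):
        if self.start_plate > self.end_plate:
            raise ValidationError(
                f"library {self.short_name!r}: start plate {self.start_plate} "
                f"exceeds end plate {self.end_plate}"
            )


@dataclass
class Library:
    short_name: str
    screen_type: ScreenType
    plate_format: PlateFormat
    start_plate: int
    end_plate: int
    version: int = 1
    wells: dict[WellKey, Well] = field(default_factory=dict)
    superseded_versions: list[dict[WellKey, Well]] = field(default_factory=list)
    copies: dict[str, "object"] = field(default_factory=dict)  # name -> inventory.Copy

    @property
    def plate_numbers(self) -> range:
        return range(self.start_plate, self.end_plate + 1)

    def well(self, key: WellKey) -> Well:
        try:
            return self.wells[key]
        except KeyError:
            raise ValidationError(f"unknown well {key} in library {self.short_name!r}") from None

    def contains_plate(self, plate_number: int) -> bool:
        return self.start_plate <= plate_number <= self.end_plate

    def meta(self) -> LibraryMeta:
        return LibraryMeta(
            self.short_name, self.screen_type, self.plate_format, self.start_plate, self.end_plate
        )


# ---------------------------------------------------------------------------
# SD-file reading/writing (data fields only; molblocks passed through blind)
# ---------------------------------------------------------------------------

_SDF_TAG_RE = re.compile(r">\s*<([^>]+)>")


def _split_sdf_records(text: str) -> list[str]:
    records = []
    for chunk in text.split("\n$$$$"):
        if chunk.strip():
            records.append(chunk)
    return records


def _sdf_record_fields(record: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = record.splitlines()
    i = 0
    while i < len(lines):
        m = _SDF_TAG_RE.match(lines[i])
        if m:
            tag = m.group(1)
            value_lines = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            fields[tag] = "\n".join(value_lines).strip()
        else:
            i += 1
    return fields


def _split_list(raw: str | None) -> list[str]:
    if not raw:
        return []
    return [tok.strip() for tok in str(raw).split(";") if tok.strip()]


def _fill_empty_wells(lib: Library) -> None:
    from .core_model import iter_well_names

    for plate in lib.plate_numbers:
        for name in iter_well_names(lib.plate_format):
            key = WellKey(plate, name)
            if key not in lib.wells:
                lib.wells[key] = Well(key=key, well_type=WellType.EMPTY)


def _make_key(lib_or_meta, plate_raw, well_raw, ordinal: int) -> WellKey:
    try:
        plate = int(plate_raw)
    except (TypeError, ValueError):
        raise ValidationError(f"record {ordinal}: bad plate number {plate_raw!r}") from None
    fmt = lib_or_meta.plate_format
    coord = parse_well_name(str(well_raw), fmt)
    key = WellKey(plate, format_well_name(coord, fmt))
    if not (lib_or_meta.start_plate <= plate <= lib_or_meta.end_plate):
        raise ValidationError(
            f"record {ordinal}: plate {plate} outside the declared range "
            f"[{lib_or_meta.start_plate}, {lib_or_meta.end_plate}]"
        )
    return key


def _deprecation(fields: dict) -> tuple[bool, str | None]:
    dep_raw = str(fields.get("Deprecated") or "").strip().lower()
    deprecated = dep_raw in ("true", "1", "yes")
    reason = str(fields.get("Deprecation_Reason") or "").strip() or None
    return deprecated, reason


def import_small_molecule_library(
    sdf_text: str,
    meta: LibraryMeta,
    field_map: dict[str, str] | None = None,
) -> Library:
    """Build a small-molecule library from SD-file text.

    One well per record; data fields identify the well (``Plate``, ``Well``,
    ``Well_Type``) and describe the reagent.  ``field_map`` translates the
    canonical field names to a foreign dialect's, e.g.
    ``{"Vendor_ID": "CatalogNumber"}``.
    """
    if meta.screen_type is not ScreenType.SMALL_MOLECULE:
        raise ValidationError("SD-file import applies to small-molecule libraries only")
    fmap = {name: name for name in SDF_FIELDS}
    fmap.update(field_map or {})
    lib = Library(
        meta.short_name, meta.screen_type, meta.plate_format, meta.start_plate, meta.end_plate
    )
    for ordinal, record in enumerate(_split_sdf_records(sdf_text), start=1):
        raw = _sdf_record_fields(record)
        f = {canon: raw.get(actual) for canon, actual in fmap.items()}
        if f.get("Plate") is None or f.get("Well") is None:
            raise ValidationError(f"record {ordinal}: missing Plate/Well data fields")
        key = _make_key(meta, f["Plate"], f["Well"], ordinal)
        if key in lib.wells:
            raise ValidationError(f"record {ordinal}: duplicate well {key}")
        well_type = WellType.parse(f.get("Well_Type") or "experimental")
        reagent = None
        if well_type is WellType.EXPERIMENTAL:
            try:
                mass = float(f["Molecular_Mass"]) if f.get("Molecular_Mass") else None
                reagent = SmallMoleculeReagent(
                    vendor=f.get("Vendor") or "",
                    vendor_id=f.get("Vendor_ID") or "",
                    smiles=f.get("Smiles") or "",
                    inchi=f.get("InChI") or "",
                    molecular_mass=mass,
                    chemical_names=_split_list(f.get("Chemical_Names")),
                    pubchem_cids=[int(x) for x in _split_list(f.get("PubChem_CIDs"))],
                    chembank_ids=_split_list(f.get("ChemBank_IDs")),
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"record {ordinal}: {exc}") from None
        deprecated, reason = _deprecation(f)
        lib.wells[key] = Well(
            key=key,
            well_type=well_type,
            reagent=reagent,
            deprecated=deprecated,
            deprecation_reason=reason,
        )
    _fill_empty_wells(lib)
    return lib


# ---------------------------------------------------------------------------
# RNAi workbook reading
# ---------------------------------------------------------------------------


def _workbook_rows(stream) -> list[dict[str, object]]:
    if isinstance(stream, (bytes, bytearray)):
        stream = io.BytesIO(stream)
    wb = load_workbook(stream, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows = ws.iter_rows(values_only=True)
    try:
        header = [str(h).strip() if h is not None else "" for h in next(rows)]
    except StopIteration:
        raise ValidationError("workbook has no header row") from None
    out = []
    for values in rows:
        if values is None or all(v is None for v in values):
            continue
        out.append(dict(zip(header, values)))
    wb.close()
    return out


def _parse_duplex_tokens(raw: str, fmt: PlateFormat, ordinal: int) -> list[WellKey]:
    keys = []
    for tok in _split_list(raw):
        try:
            keys.append(WellKey.parse(tok, fmt))
        except ValidationError as exc:
            raise ValidationError(f"row {ordinal}: malformed duplex token {tok!r}: {exc}") from None
    return keys


def import_rnai_library(
    workbook_stream,
    meta: LibraryMeta,
    duplex_library: Library | None = None,
    duplex_format: PlateFormat | None = None,
) -> Library:
    """Build an RNAi library from a workbook.

    Pool rows must list their constituent duplex wells as semicolon-joined
    ``plate:well`` tokens; duplex rows must not.  When ``duplex_library`` is
    given, every pool's duplex references are checked to resolve to duplex
    wells there (pool integrity).
    """
    if meta.screen_type is not ScreenType.RNAI:
        raise ValidationError("workbook library import applies to RNAi libraries only")
    lib = Library(
        meta.short_name, meta.screen_type, meta.plate_format, meta.start_plate, meta.end_plate
    )
    dup_fmt = duplex_format or (duplex_library.plate_format if duplex_library else meta.plate_format)
    for ordinal, row in enumerate(_workbook_rows(workbook_stream), start=1):
        if row.get("Plate") is None or row.get("Well") is None:
            raise ValidationError(f"row {ordinal}: missing Plate/Well columns")
        key = _make_key(meta, row["Plate"], row["Well"], ordinal)
        if key in lib.wells:
            raise ValidationError(f"row {ordinal}: duplicate well {key}")
        well_type = WellType.parse(str(row.get("Well_Type") or "experimental"))
        reagent = None
        if well_type is WellType.EXPERIMENTAL:
            stype = str(row.get("Silencing_Type") or "duplex").strip().lower()
            duplex_keys = _parse_duplex_tokens(str(row.get("Duplex_Wells") or ""), dup_fmt, ordinal)
            try:
                entrez = int(row["Entrez_Gene_ID"]) if row.get("Entrez_Gene_ID") else None
                reagent = SilencingReagent(
                    vendor=str(row.get("Vendor") or ""),
                    vendor_id=str(row.get("Vendor_ID") or ""),
                    silencing_type=stype,
                    sequences=_split_list(str(row.get("Sequence") or "")),
                    entrez_gene_id=entrez,
                    gene_symbol=str(row.get("Gene_Symbol") or ""),
                    genbank_accessions=_split_list(str(row.get("GenBank") or "")),
                    species=str(row.get("Species") or ""),
                    duplex_well_keys=duplex_keys,
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"row {ordinal}: {exc}") from None
            if reagent.silencing_type == "pool" and duplex_library is not None:
                for dkey in reagent.duplex_well_keys:
                    dwell = duplex_library.wells.get(dkey)
                    if (
                        dwell is None
                        or dwell.reagent is None
                        or getattr(dwell.reagent, "silencing_type", None) != "duplex"
                    ):
                        raise ValidationError(
                            f"row {ordinal}: pool {reagent.vendor_id!r} references "
                            f"{dkey}, which is not a duplex well of "
                            f"library {duplex_library.short_name!r}"
                        )
        deprecated, reason = _deprecation(row)
        lib.wells[key] = Well(
            key=key,
            well_type=well_type,
            reagent=reagent,
            deprecated=deprecated,
            deprecation_reason=reason,
        )
    _fill_empty_wells(lib)
    return lib


# ---------------------------------------------------------------------------
# Versioned re-import
# ---------------------------------------------------------------------------


def import_contents_version(library: Library, stream, **import_kwargs) -> Library:
    """Import a new contents version, retaining the prior one for audit.

    The plate range is fixed at library creation; a file touching plates
    outside it is rejected.  Copy volume ledgers are untouched — they belong
    to the physical plates, not to a contents revision.
    """
    meta = library.meta()
    if library.screen_type is ScreenType.SMALL_MOLECULE:
        fresh = import_small_molecule_library(stream, meta, **import_kwargs)
    else:
        fresh = import_rnai_library(stream, meta, **import_kwargs)
    library.superseded_versions.append(library.wells)
    library.wells = fresh.wells
    library.version += 1
    return library


# ---------------------------------------------------------------------------
# Batch search
# ---------------------------------------------------------------------------

_PLATE_WELL_TOKEN_RE = re.compile(r"^\d+:")


def batch_well_search(
    libraries: list[Library], query: list[str]
) -> tuple[list[Well], list[str]]:
    """Resolve a mixed list of ``plate:well`` tokens and vendor reagent ids.

    Returns the union of matches in input order with duplicates removed,
    plus the tokens that matched nothing.  A vendor id may match wells in
    several libraries — the same reagent can exist in more than one library.
    """
    found: list[Well] = []
    seen: set[int] = set()
    unmatched: list[str] = []
    for token in query:
        token = token.strip()
        matches: list[Well] = []
        if _PLATE_WELL_TOKEN_RE.match(token):
            for lib in libraries:
                try:
                    key = WellKey.parse(token, lib.plate_format)
                except ValidationError:
                    continue
                if lib.contains_plate(key.plate_number) and key in lib.wells:
                    matches.append(lib.wells[key])
        else:
            for lib in libraries:
                for well in lib.wells.values():
                    if well.reagent is not None and well.reagent.vendor_id == token:
                        matches.append(well)
        if not matches:
            unmatched.append(token)
        for well in matches:
            if id(well) not in seen:
                seen.add(id(well))
                found.append(well)
    return found, unmatched


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_EMPTY_MOLBLOCK = "\n  screenkit\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n"


def _sm_field_values(well: Well) -> dict[str, str]:
    r = well.reagent
    out = {
        "Plate": str(well.key.plate_number),
        "Well": well.key.well_name,
        "Well_Type": well.well_type.value,
    }
    if isinstance(r, SmallMoleculeReagent):
        out.update(
            Vendor=r.vendor,
            Vendor_ID=r.vendor_id,
            Smiles=r.smiles,
            InChI=r.inchi,
            Molecular_Mass="" if r.molecular_mass is None else repr(r.molecular_mass),
            Chemical_Names=";".join(r.chemical_names),
            PubChem_CIDs=";".join(str(c) for c in r.pubchem_cids),
            ChemBank_IDs=";".join(r.chembank_ids),
        )
    if well.deprecated:
        out["Deprecated"] = "true"
        out["Deprecation_Reason"] = well.deprecation_reason or ""
    return out


def _rnai_row_values(well: Well) -> dict[str, object]:
    r = well.reagent
    out: dict[str, object] = {
        "Plate": well.key.plate_number,
        "Well": well.key.well_name,
        "Well_Type": well.well_type.value,
    }
    if isinstance(r, SilencingReagent):
        out.update(
            Vendor=r.vendor,
            Vendor_ID=r.vendor_id,
            Silencing_Type=r.silencing_type,
            Entrez_Gene_ID=r.entrez_gene_id,
            Gene_Symbol=r.gene_symbol,
            GenBank=";".join(r.genbank_accessions),
            Species=r.species,
            Sequence=";".join(r.sequences),
            Duplex_Wells=";".join(str(k) for k in r.duplex_well_keys),
        )
    if well.deprecated:
        out["Deprecated"] = "true"
        out["Deprecation_Reason"] = well.deprecation_reason or ""
    return out


def export_wells(wells: list[Well], columns: list[str] | None = None, fmt: str = "workbook"):
    """Serialise wells for exchange.

    ``fmt="sdf"`` (small-molecule wells only) returns SD-file text;
    ``fmt="workbook"`` returns XLSX bytes, one row per well.  Empty wells are
    skipped — a re-import regenerates them from the plate range.  ``columns``
    optionally restricts the exported reagent columns.
    """
    wells = [w for w in wells if w.well_type is not WellType.EMPTY]
    if fmt == "sdf":
        for w in wells:
            if isinstance(w.reagent, SilencingReagent):
                raise ValidationError("SD-file export is not supported for RNAi wells")
        chunks = []
        for w in wells:
            fields = _sm_field_values(w)
            if columns is not None:
                keep = set(columns) | {"Plate", "Well", "Well_Type"}
                fields = {k: v for k, v in fields.items() if k in keep}
            body = "".join(
                f">  <{tag}>\n{value}\n\n" for tag, value in fields.items() if value != ""
            )
            chunks.append(_EMPTY_MOLBLOCK + body + "$$$$\n")
        return "".join(chunks)
    if fmt == "workbook":
        is_rnai = any(isinstance(w.reagent, SilencingReagent) for w in wells)
        header = list(RNAI_COLUMNS if is_rnai else SDF_FIELDS)
        if columns is not None:
            keep = set(columns) | {"Plate", "Well", "Well_Type"}
            header = [h for h in header if h in keep]
        wb = Workbook(write_only=True)
        ws = wb.create_sheet("Contents")
        ws.append(header)
        row_values = _rnai_row_values if is_rnai else _sm_field_values
        for w in wells:
            values = row_values(w)
            ws.append([values.get(h) if values.get(h) != "" else None for h in header])
        buf = io.BytesIO()
        wb.save(buf)
        return buf.getvalue()
    raise ValidationError(f"unknown export format {fmt!r}")
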