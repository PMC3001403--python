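"""Deterministic synthetic screening data for tests, demos and dry runs.

The generator emulates the facility's study conditions at configurable
scale: small-molecule libraries as SD files (valid template SMILES with
counter-suffixed vendor ids — the structures are carriers, not chemistry),
RNAi libraries as pool + matching duplex workbooks (four duplexes per pool,
19–21-mer sequences), per-plate control layouts, and screen-result
workbooks with two replicate raw columns, a derived score column and a
threshold positives column whose realised positive fraction is binomial
around the requested rate.  Typical follow-up sizes guide the defaults: a
cherry-pick list of ~0.4% of compounds for small-molecule screens and ~2%
of genes for RNAi screens.

Everything is driven by one integer seed; the same seed yields byte-
identical files (workbook metadata timestamps are pinned for this).
"""

from __future__ import annotations

import io
import random
import re
import zipfile
from dataclasses import dataclass, field
from datetime import datetime

from openpyxl import Workbook

from .core_model import (
    PlateFormat,
    ScreenType,
    ValidationError,
    WellKey,
    WellType,
    iter_well_names,
)
from .library_io import (
    Library,
    LibraryMeta,
    import_rnai_library,
    import_small_molecule_library,
)
from .screen_results import HEADER_COLUMNS, DATA_HEADERS_SHEET

__all__ = [
    "FixtureSpec",
    "generate_library",
    "generate_small_molecule_sdf",
    "generate_rnai_workbooks",
    "generate_screen_result",
    "sample_cherry_picks",
    "SMILES_TEMPLATES",
]

# A small set of valid structures; fixtures never do chemistry with them.
SMILES_TEMPLATES = (
    "CCO",
    "c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CN1CCC[C@H]1c1cccnc1",
    "C1CCNCC1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "O=C(O)c1ccccc1",
    "CCN(CC)CC",
)

_NUCLEOTIDES = "ACGT"
DUPLEXES_PER_POOL = 4


@dataclass
class FixtureSpec:
    """Parameters of one synthetic data set.

    ``control_layout`` names the control wells stamped onto every plate
    (default: column 1 alternating DMSO/library controls, a common layout).
    ``positives_rate`` is the Bernoulli rate of true actives in generated
    screen results; ``cherry_pick_fraction`` the fraction of experimental
    wells drawn into a follow-up pick list.
    """

    seed: int
    library_type: ScreenType = ScreenType.SMALL_MOLECULE
    n_plates: int = 2
    plate_format: PlateFormat = PlateFormat.F384
    control_layout: frozenset[str] = frozenset()
    positives_rate: float = 0.01
    cherry_pick_fraction: float = 0.004
    start_plate: int = 1
    short_name: str = "FIX"

    def __post_init__(self):
        if not 0 <= self.positives_rate <= 1:
            raise ValidationError("positives_rate must lie in [0, 1]")
        if not 0 <= self.cherry_pick_fraction <= 1:
            raise ValidationError("cherry_pick_fraction must lie in [0, 1]")
        if self.n_plates < 1:
            raise ValidationError("n_plates must be ≥ 1")
        if not self.control_layout:
            controls = {}
            for i, name in enumerate(iter_well_names(self.plate_format)):
                if name.endswith("01"):
                    controls[name] = "dmso_control" if i % 2 == 0 else "library_control"
            object.__setattr__(self, "control_layout", frozenset(controls))

    def control_type(self, well_name: str) -> str:
        row = well_name[:-2]
        return "dmso_control" if (ord(row[-1]) % 2 == 1) else "library_control"


_FIXED_STAMP = datetime(2010, 5, 18, 0, 0, 0)
_FIXED_ZIP_DATE = (2010, 5, 18, 0, 0, 0)


_STAMP_RE = re.compile(
    rb"(<dcterms:(?:created|modified)[^>]*>)[^<]*(</dcterms:(?:created|modified)>)"
)


def deterministic_xlsx(wb: Workbook) -> bytes:
    """Serialise a workbook with pinned timestamps so bytes depend only on content."""
    raw = io.BytesIO()
    wb.save(raw)
    raw.seek(0)
    out = io.BytesIO()
    stamp = _FIXED_STAMP.strftime("%Y-%m-%dT%H:%M:%SZ").encode()
    with zipfile.ZipFile(raw) as src, zipfile.ZipFile(
        out, "w", zipfile.ZIP_DEFLATED
    ) as dst:
        for name in sorted(src.namelist()):
            payload = src.read(name)
            if name == "docProps/core.xml":
                # the writer stamps save time here; pin it
                payload = _STAMP_RE.sub(rb"\g<1>" + stamp + rb"\g<2>", payload)
            info = zipfile.ZipInfo(name, date_time=_FIXED_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, payload)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Libraries
# ---------------------------------------------------------------------------


def generate_small_molecule_sdf(spec: FixtureSpec) -> tuple[str, LibraryMeta]:
    """Synthesise SD-file text plus its library header for a SM library."""
    rng = random.Random(spec.seed)
    meta = LibraryMeta(
        short_name=spec.short_name,
        screen_type=ScreenType.SMALL_MOLECULE,
        plate_format=spec.plate_format,
        start_plate=spec.start_plate,
        end_plate=spec.start_plate + spec.n_plates - 1,
    )
    chunks = []
    counter = 0
    for plate in range(meta.start_plate, meta.end_plate + 1):
        for name in iter_well_names(spec.plate_format):
            if name in spec.control_layout:
                well_type = spec.control_type(name)
                fields = {"Plate": plate, "Well": name, "Well_Type": well_type}
            else:
                counter += 1
                smiles = SMILES_TEMPLATES[counter % len(SMILES_TEMPLATES)]
                mass = round(rng.uniform(150.0, 650.0), 2)
                fields = {
                    "Plate": plate,
                    "Well": name,
                    "Well_Type": "experimental",
                    "Vendor": "ACME",
                    "Vendor_ID": f"SM-{spec.seed}-{counter:06d}",
                    "Smiles": smiles,
                    "Molecular_Mass": mass,
                    "Chemical_Names": f"compound-{counter}",
                    "PubChem_CIDs": str(rng.randrange(1, 10_000_000)),
                }
            body = "".join(f">  <{k}>\n{v}\n\n" for k, v in fields.items())
            chunks.append(
                "\n  screenkit\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n"
                + body
                + "$$$$\n"
            )
    return "".join(chunks), meta


def _workbook_from_rows(header: list[str], rows: list[list]) -> bytes:
    wb = Workbook()
    ws = wb.active
    ws.title = "Contents"
    ws.append(header)
    for row in rows:
        ws.append(row)
    return deterministic_xlsx(wb)


def generate_rnai_workbooks(
    spec: FixtureSpec,
) -> tuple[tuple[bytes, LibraryMeta], tuple[bytes, LibraryMeta]]:
    """Synthesise a pool library workbook and its matching duplex library.

    Each experimental pool well references four consecutive duplex wells
    (row-major across the duplex plates, which follow the pool plate range).
    """
    rng = random.Random(spec.seed)
    pool_meta = LibraryMeta(
        short_name=f"{spec.short_name}-POOL",
        screen_type=ScreenType.RNAI,
        plate_format=spec.plate_format,
        start_plate=spec.start_plate,
        end_plate=spec.start_plate + spec.n_plates - 1,
    )
    well_names = list(iter_well_names(spec.plate_format))
    experimental = [n for n in well_names if n not in spec.control_layout]
    n_pools = spec.n_plates * len(experimental)
    n_duplex_plates = -(-n_pools * DUPLEXES_PER_POOL // spec.plate_format.wells_per_plate)
    duplex_meta = LibraryMeta(
        short_name=f"{spec.short_name}-DUP",
        screen_type=ScreenType.RNAI,
        plate_format=spec.plate_format,
        start_plate=pool_meta.end_plate + 1,
        end_plate=pool_meta.end_plate + n_duplex_plates,
    )
    duplex_slots = [
        WellKey(plate, name)
        for plate in range(duplex_meta.start_plate, duplex_meta.end_plate + 1)
        for name in well_names
    ]

    header = [
        "Plate", "Well", "Well_Type", "Vendor", "Vendor_ID", "Silencing_Type",
        "Entrez_Gene_ID", "Gene_Symbol", "GenBank", "Species", "Sequence",
        "Duplex_Wells",
    ]
    pool_rows, duplex_rows = [], []
    gene_no = 0
    for plate in range(pool_meta.start_plate, pool_meta.end_plate + 1):
        for name in well_names:
            if name in spec.control_layout:
                pool_rows.append([plate, name, spec.control_type(name)] + [None] * 9)
                continue
            gene_no += 1
            entrez = 10_000 + gene_no
            symbol = f"GENE{gene_no}"
            dkeys = duplex_slots[
                (gene_no - 1) * DUPLEXES_PER_POOL : gene_no * DUPLEXES_PER_POOL
            ]
            sequences = [
                "".join(rng.choice(_NUCLEOTIDES) for _ in range(rng.randint(19, 21)))
                for _ in range(DUPLEXES_PER_POOL)
            ]
            pool_rows.append(
                [
                    plate, name, "experimental", "RNACo",
                    f"POOL-{spec.seed}-{gene_no:06d}", "pool", entrez, symbol,
                    f"NM_{entrez:06d}", "human", ";".join(sequences),
                    ";".join(str(k) for k in dkeys),
                ]
            )
            for j, (dkey, seq) in enumerate(zip(dkeys, sequences), start=1):
                duplex_rows.append(
                    [
                        dkey.plate_number, dkey.well_name, "experimental", "RNACo",
                        f"DUP-{spec.seed}-{gene_no:06d}-{j}", "duplex", entrez,
                        symbol, f"NM_{entrez:06d}", "human", seq, None,
                    ]
                )
    return (
        (_workbook_from_rows(header, pool_rows), pool_meta),
        (_workbook_from_rows(header, duplex_rows), duplex_meta),
    )


def generate_library(spec: FixtureSpec) -> list[Library]:
    """Generate and import fixture libraries, returning the library objects.

    Small-molecule specs yield one library; RNAi specs yield the pool
    library followed by its duplex library.
    """
    if spec.library_type is ScreenType.SMALL_MOLECULE:
        sdf, meta = generate_small_molecule_sdf(spec)
        return [import_small_molecule_library(sdf, meta)]
    (pool_bytes, pool_meta), (dup_bytes, dup_meta) = generate_rnai_workbooks(spec)
    duplex_lib = import_rnai_library(dup_bytes, dup_meta)
    pool_lib = import_rnai_library(pool_bytes, pool_meta, duplex_library=duplex_lib)
    return [pool_lib, duplex_lib]


# ---------------------------------------------------------------------------
# Screen results
# ---------------------------------------------------------------------------

_SIGNAL_SHIFT = 5.0  # assay signal of a true active, in noise SD units
_CUTOFF = 2.5


def generate_screen_result(library: Library, spec: FixtureSpec) -> bytes:
    """Synthesise a screen-result workbook over a library's plates.

    Two replicate raw columns carry unit-scale Gaussian noise; true actives
    (drawn per experimental well at ``positives_rate``) are shifted well
    clear of the cutoff.  The derived ``score`` column is the replicate
    mean, and the ``positives`` column repeats the score under a
    ``threshold`` positive indicator, so the realised positive fraction is
    binomial around the requested rate.
    """
    rng = random.Random(spec.seed + 1)
    wb = Workbook()
    hdr = wb.active
    hdr.title = DATA_HEADERS_SHEET
    hdr.append(list(HEADER_COLUMNS))
    hdr.append(["rep1", "numeric", 1, None, "luminescence", None, None, None, "raw replicate 1"])
    hdr.append(["rep2", "numeric", 2, None, "luminescence", None, None, None, "raw replicate 2"])
    hdr.append(["score", "numeric", None, None, None, "true", "rep1;rep2", None, "replicate mean"])
    hdr.append(
        [
            "positives", "numeric", None, None, None, "true", "score",
            f"threshold:{_CUTOFF}:above", "screener positive calls",
        ]
    )
    data = wb.create_sheet("Data")
    data.append(["Plate", "Well", "Assay_Well_Type", "rep1", "rep2", "score", "positives"])
    for plate in library.plate_numbers:
        for name in iter_well_names(library.plate_format):
            well = library.wells[WellKey(plate, name)]
            if well.well_type is WellType.EMPTY:
                continue
            is_experimental = well.well_type is WellType.EXPERIMENTAL
            active = is_experimental and rng.random() < spec.positives_rate
            shift = _SIGNAL_SHIFT if active else 0.0
            r1 = round(rng.gauss(shift, 1.0), 4)
            r2 = round(rng.gauss(shift, 1.0), 4)
            score = round((r1 + r2) / 2, 4)
            # the positives column is the screener's curated call: wells not
            # drawn as active are clipped to the cutoff (never strictly above)
            called = score if active else min(score, _CUTOFF)
            data.append([plate, name, well.well_type.value, r1, r2, score, called])
    return deterministic_xlsx(wb)


def sample_cherry_picks(library: Library, spec: FixtureSpec) -> list[WellKey]:
    """Draw a follow-up pick list from a library's experimental wells."""
    rng = random.Random(spec.seed + 2)
    candidates = sorted(
        k for k, w in library.wells.items() if w.well_type is WellType.EXPERIMENTAL
    )
    n = max(1, round(len(candidates) * spec.cherry_pick_fraction))
    return sorted(rng.sample(candidates, n))
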