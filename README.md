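# screenkit

Core data management for shared high-throughput screening (HTS) facilities,
as a Python library with a thin CLI.

An academic screening facility hosts many interleaved small-molecule and
RNAi screens run by independent research groups against shared compound and
siRNA libraries. The informatics problem is not the assay statistics — those
are done by the screeners' analysis software — but the bookkeeping that has
to be exactly right across hundreds of screens: which reagent sits in which
well of which plate, how many microlitres remain in every well of every
physical library copy, which wells a screener called positive, and how a
follow-up "cherry pick" list turns into instructions for a liquid-handling
robot. `screenkit` implements that bookkeeping for facility staff and the
developers who build tooling for them.

## What it covers

- **Plate/well coordinates** (`core_model`) — 96/384/1536-well formats, the
  `A01`…`AF48` naming convention (zero-padded canonical form; unpadded and
  lower-case dialects accepted), exact parse/format round-trips.
- **Libraries** (`library_io`) — small-molecule contents from SD files
  (per-record `Plate`/`Well`/vendor/SMILES/InChI data fields; molblocks are
  tolerated and ignored), RNAi contents from workbooks with pool → duplex
  references; versioned re-imports that keep every prior contents revision;
  batch search by `plate:well` or vendor id; export to SD file or workbook
  with exact round-trip.
- **Inventory** (`inventory`) — library copies with a per-well volume
  ledger held in integer nanolitres, so conservation
  `remaining = initial − Σ debits + Σ corrections` holds exactly. Screening
  debits whole plates and counts freeze/thaw cycles; corrections and well
  deprecation are role-guarded and audited; all debits are atomic.
- **Screen results** (`screen_results`) — the two-part result workbook
  (a "Data Headers" sheet describing raw/derived columns, then data
  sheets), positives via boolean / partitioned (strong, medium, weak) /
  strict-threshold indicators, positives counts and percentages,
  outer-joined cross-screen comparison tables with per-reagent study
  annotations, multi-criteria filtering, and plate-shaped heat-map
  matrices.
- **Cherry picks** (`cherrypick`) — pick validation (duplicates,
  deprecated and control wells, pick-count policy), automatic
  deconvolution of siRNA pools into duplexes, deterministic volume
  reservation (smallest sufficient copy first), destination-plate mapping
  with required-empty wells and seeded randomised layouts, the CSV robot
  mapping file, and plated/failed/canceled outcomes with exact ledger
  semantics (cancel refunds, failure double-debits and respawns onto an
  attempt-2 successor plate).
- **Access policy** (`access_policy`) — reciprocal tiered data sharing:
  level 0 (share everything) … 3 (private); a user at level *u* gets full
  access to a level-*s* screen iff *u ≤ s* (neither private), metadata
  only otherwise; owners, collaborators and read-everything administrators
  always see everything. The policy object is pluggable.
- **Activities** (`activities`) — an append-only audit log of lab and
  administrative events with an extensible kind registry.
- **Fixtures + CLI** (`fixtures`, `cli`, `workspace`) — a seeded,
  byte-deterministic synthetic-data generator and a `screenkit` command
  operating on a persistent workspace directory.

## Worked example

```python
from datetime import date
import screenkit as sk
from screenkit.fixtures import FixtureSpec, generate_screen_result

# a 2-plate 384-well small-molecule library with column-1 control wells
spec = FixtureSpec(seed=1, n_plates=2, positives_rate=0.02)
library = sk.generate_library(spec)[0]
n_exp = sum(1 for w in library.wells.values() if w.well_type is sk.WellType.EXPERIMENTAL)
print(f"library: {len(library.wells)} wells, {n_exp} experimental")

# aliquot a cherry-pick source copy at 10 µL/well
copy = sk.create_copy(library, "C", "cherry_pick_source", 10.0)

# import a screen result and summarise the positives
screen = sk.Screen("S100", sk.ScreenType.SMALL_MOLECULE, libraries=[library])
result = sk.import_screen_result(screen, generate_screen_result(library, spec))
count, percent = sk.positives_summary(result, "positives")
print(f"positives: {count} of {n_exp} experimental wells ({percent:.2f}%)")

# cherry-pick the positives and map them onto a destination plate
log = sk.ActivityLog()
hits = sorted(w for w, hit in sk.classify_positives(result, "positives").items() if hit)
request = sk.create_request(screen, hits, 2.0, [library], sk.User(id="alice"),
                            date(2024, 6, 1), log=log)
sk.deconvolute(request, [library])
print(f"reserved: {sk.reserve_reagent(request)} picks")
plates = sk.map_to_plates(request)
print(f"plates: {[(p.ordinal, len(p.picks)) for p in plates]}")
print("\n".join(sk.export_plate_mapping(request).splitlines()[:2]))
print(f"ledger after reservation: {copy.remaining_ul(hits[0])} uL remaining in {hits[0]}")
```

Output:

```
library: 768 wells, 736 experimental
positives: 15 of 736 experimental wells (2.04%)
reserved: 15 picks
plates: [(1, 15)]
source_plate,source_copy,source_well,destination_plate_ordinal,destination_well,volume_uL
1,C,C22,1,A01,2
ledger after reservation: 8.0 uL remaining in 1:C22
```

Reading it: of 736 experimental wells, 15 scored above the screener's
cutoff (2.04%, binomial around the 2% generating rate). All 15 picks found
sufficient volume in copy `C`, fit on one destination plate, and the first
mapping-file row tells the robot to move 2 µL from plate 1 well C22 of copy
`C` to well A01 of cherry-pick plate 1 — leaving 8 µL of the original 10 in
the source well, which the ledger confirms.

The same workflow is available from the shell:

```sh
screenkit -w ws fixture library --seed 1 --plates 1 --out-dir fx
screenkit -w ws library import --name L1 --type sm --start-plate 1 --end-plate 1 fx/FIX.sdf
screenkit -w ws copy create --library L1 --name C --usage cherry_pick_source --volume 20
screenkit -w ws screen create --id S1 --type sm --library L1
screenkit -w ws fixture screen-result --library L1 --seed 2 --out fx/result.xlsx
screenkit -w ws screen import --screen S1 fx/result.xlsx
screenkit -w ws cpr create --screen S1 --volume 2 --picks picks.txt --user staff
screenkit -w ws cpr reserve --id 1 && screenkit -w ws cpr map --id 1
screenkit -w ws cpr export --id 1 --out mapping.csv
```

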