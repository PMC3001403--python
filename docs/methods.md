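# Methods

This note records the model behind `screenkit`, the parameters that matter,
the numerical and design choices that were genuinely open, what the
synthetic-data generator does and does not emulate, and known limitations.

## The domain model

The package is organised around the entities a screening facility actually
tracks. A **library** is a contiguous range of plates in one of the
standard microplate densities (96 = 8×12, 384 = 16×24, 1536 = 32×48) whose
wells hold either small-molecule reagents (vendor id, SMILES/InChI,
molecular mass, external ids) or RNAi silencing reagents (gene annotation,
sequences, and — for pool-format wells — references to the constituent
duplex wells of a companion duplex library). A **copy** is a physical
aliquoted instance of a library with its own per-well volume ledger. A
**screen** owns at most one **screen result**: typed per-well values in
named raw or derived columns. A **cherry-pick request** carries the
follow-up workflow state. **Activities** are the append-only audit trail
that every volume-mutating or policy-relevant operation writes to.

Coordinates are 0-based `(row, col)` pairs internally; every user-facing
string uses the letter+1-based-column dialect, giving a single convention
boundary. Well names are stored zero-padded (`A01`); parsers accept
unpadded and lower-case forms because vendor SD files and robot exports
disagree on the dialect. Rows past `Z` in the 1536 format use the
conventional two-letter extension `AA..AF`.

## Exact volume accounting

All volumes are integers in nanolitres; the public API speaks microlitres
and converts by `round(µL × 1000)`. This makes the ledger invariant —
remaining = initial − Σ debits + Σ correction deltas, per well — exact
rather than approximate, which is what the conservation tests assert
(equality, not tolerance). Debits are atomic: a library screening that
would drive any well of any listed plate negative is rejected before
anything is touched. Library screening debits every well of a plate
uniformly (including control wells — the assay-plate stamp draws from all
wells) and increments the plate's freeze/thaw count; per-well debits arise
only from cherry-pick reservation and manual corrections. The freeze/thaw
count is materialised on the plate and always equals the number of
library-screening activities that touched it.

## Positives

A data column may carry a positive indicator of one of three kinds:

- **boolean** — the value itself is the call;
- **partition** — values in {strong, medium, weak, none}; any non-none
  partition is a positive (the three non-none grades are vocabulary for
  the screener, not computationally distinct);
- **threshold** — numeric values with a screener-chosen cutoff that must
  be *strictly* exceeded, in an explicit direction (`above` for activation
  readouts, `below` for inhibition).

Only experimental wells enter classification; control wells can carry
values but never count. The positives percentage divides by the number of
experimental wells holding a value in that column, and is undefined (an
error, not 0) when there are none.

Derived-column values are imported, never computed: analysis happens in the
screeners' external software, and this package only validates the
derivation graph (each derived column must reference strictly earlier
columns, which also excludes cycles).

## Cross-screen comparison

`merge_comparison_table` outer-joins sources so that a reagent scored in
one screen but missing from another still appears, with genuinely empty
(NA, never zero) cells. Keys are `plate:well` strings or reagent vendor
ids; study annotations always join by reagent, in well mode via the well →
reagent lookup through the screened libraries. Filtering is a conjunction
of typed criteria; empty cells satisfy nothing. The heat-map operation is
deliberately just a plate-shaped matrix pivot — rendering belongs to
plotting tools, and comparing normalisation methods side by side is done
by requesting one matrix per column.

## The cherry-pick workflow

Validation runs in submission order: unknown wells, duplicates of an
earlier pick, deprecated wells and non-experimental wells are rejected
with per-pick reasons, and picks beyond the facility's pick-count policy
are rejected as over the limit. Pool-format siRNA picks deconvolute into
one lab pick per referenced duplex well.

**Reservation** must be deterministic and auditable, so where several
copies could satisfy a pick the rule is: among eligible cherry-pick-source
copies (not retired, well volume ≥ the effective request volume), take the
copy with the smallest sufficient remaining volume, breaking ties on copy
name. This depletes nearly-empty copies first, preserving full copies for
large future requests. The effective volume is the facility-approved
volume when one is set, else the requested volume. Insufficiency is
per-pick, not fatal; unfulfilled picks can be rolled over into a fresh
request exactly once, re-collapsed to screener-pick level.

**Mapping** sorts reserved picks by (source plate, source well row-major,
copy name) so each source plate's transfers are batched for the liquid
handler, then fills consecutive available destination wells — the
destination format (384-well by default, configurable per call) minus the
request's required-empty set (controls, edge-effect borders) — overflowing
onto further plates; the plate count is `ceil(n / available)`. Randomised
layouts permute destination wells within each plate using a generator
seeded by the request's persisted seed: randomisation is confined within a
plate so source-plate batching, and hence robot efficiency, is preserved,
and the same request and seed always reproduce a byte-identical mapping
file. A source plate's picks split across destination plates only at
capacity overflow.

**Outcomes**: `plated` finalises the picks and logs a lab liquid-transfer
activity. `canceled` credits every reservation back to its source well.
`failed` keeps the debits — the reagent was physically consumed in the
failed attempt — and respawns the plate's picks as fresh unfulfilled picks;
when those are re-reserved and remapped onto a single plate it becomes the
failed plate's successor, reusing its ordinal with the attempt number
incremented. The package-wide conservation law is then: total debits minus
credits = effective volume × (picks ever reserved − picks canceled).

## Access policy

The sharing tiers are 0 (everything shared) to 3 (private). The default
reciprocity rule grants, for user level *u* against screen level *s*:
full access to the screen's own people and read-everything administrators;
none when *u* = 3 or *s* = 3; full when *u ≤ s*; metadata only when
*u > s*. Two points were genuinely open and decided here: mutual-level
peers see *full* columns (not just positives) at *u ≤ s*, and reciprocity
is partitioned by screen type, so small-molecule generosity does not
unlock RNAi data. The intermediate positives-and-protocol access grade
exists in the vocabulary and in `visible_columns` so that substituted
policies can grant it; the default matrix does not. The policy is a
pluggable object because facilities differ.

This rule is monotone (sharing more never reduces access anywhere) and a
pure function of the level pair once ownership/admin edges are removed;
both properties are tested, the latter over the exhaustive 4×4 matrix.

## Synthetic data

The generator emulates the facility's study conditions at configurable
scale. Defaults: 384-well plates; column 1 of every plate as alternating
DMSO/library controls (a common control stripe); four duplexes per siRNA
pool (the dominant commercial pool format); 19–21-nt duplex sequences;
a 1% true-active rate in generated screen results; cherry-pick lists of
0.4% of experimental wells for small-molecule fixtures (facility practice
runs 0.3–0.5%, and 1–3% of genes for RNAi screens). Screen results carry
two replicate columns of unit-variance Gaussian noise; true actives are
shifted by +5 SD, the derived score is the replicate mean, and the
positives column holds the screener's *curated* calls: the score for drawn
actives, clipped at the 2.5 cutoff otherwise, so the realised positive
count is exactly binomial in the requested rate (emulating a screener who
removes noise-only threshold crossings during curation).

Workbook bytes are made seed-deterministic by pinning the zip member
timestamps and the document-properties dates after serialisation.

What the generator does not emulate — and hence what passing tests do not
show about real data: plate-position (edge/row/column) effects, replicate
correlation structure, batch drift between plates, real chemical diversity
(structures come from a small template set and are never interpreted), or
vendor file dialect quirks beyond name padding and case. Tests passing on
these fixtures certify the bookkeeping, not any statistical property of
real assays.

## Problem sizes

The randomized verification workloads are sized to be decisive yet quick:
1,000 operation sequences on a 3-plate 96-well fixture for ledger
conservation (exact equality, so sequence count buys breadth, not
precision), cherry-pick requests up to 2,000 picks over a 6-plate library,
and a 30-plate × 384-well × 4-column (~46,000-value) import/classify/
compare smoke run — a 1/1000-scale analogue of a mature facility database.

## Numerical and degenerate-input choices

- Volume µL→nL conversion rounds to the nearest nanolitre; all subsequent
  arithmetic is integral.
- A correction may set a well to exactly 0 µL; reservation treats
  remaining exactly equal to the needed volume as sufficient (≥).
- Re-deprecating a well is idempotent and updates the reason.
- An import file listing only filled wells is the norm: absent wells are
  created as `empty`, not errors.
- Ties in reservation and mapping break lexicographically/row-major so
  every operation is deterministic without hidden state.
- The workspace store is a pickled object graph inside the workspace
  directory; the domain objects are plain dataclasses, and a document
  store keeps them faithful without an object-relational mapping layer.
  Multi-user concurrency is last-writer-wins; the audit trail, not the
  store, is the arbiter of history.

## Known limitations

- No plate barcodes, freezer locations, or instrument integration.
- No chemical registration or canonicalisation; structure strings are
  stored verbatim (a validation hook can be layered on by callers).
- No normalisation/scoring of raw data; derived values are import-only.
- External-database enrichment (PubChem, Entrez, ChemBank) is out of
  scope; external ids are import-file fields.
- Screen-result re-imports are logged as screen comments rather than a
  dedicated activity kind.
- The mapping-file column set is a minimal robot-neutral reconstruction;
  vendor-specific dialects are out of scope.
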