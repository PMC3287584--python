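# Methods

## The problem

A proteomics study is rarely one measurement. A typical workflow starts with
a preparative step (protein extraction from a parasite homogenate, a venom
pool, a tissue lysate), separates the material by two-dimensional
electrophoresis (2D-PAGE) and/or liquid chromatography (LC), digests
features of interest, acquires mass spectra (MS) and finally submits the
peak lists to a database-search engine. Each instrument emits its own file
formats, and the scientific question — *which sample, prepared how, produced
this identification?* — can only be answered if the chain of experiments is
recorded as data, not folklore.

`protrack` is a desk-scale engine for that record. It models the experiment
as the central entity: a typed record (PREP, LC, GEL2D, MS) with samples, a
protocol, instrument conditions matching its type, and file attachments.
Experiments are cross-linked by their internal IDs into a provenance graph,
the *experiment tree* of a record being the rendered expansion of that graph
below its first (parentless) ancestor.

## The provenance model

Links are directed parent→child edges meaning "material or results of the
parent entered the child". Design points, and why:

* **DAG, not tree.** An MS run may pool spots from several gels, so an
  experiment can have several parents. The rendered tree duplicates shared
  nodes per branch, which is the conventional way to display provenance as
  a tree.
* **Acyclicity is enforced eagerly.** A link is rejected at insertion time
  if the parent is already reachable from the child (breadth-first search
  over the edge table). Rejection classes: self-link, duplicate edge,
  cross-project link, cycle.
* **Temporal order is advisory.** A child dated before its parent warns but
  is stored; instrument clocks drift and dates are hand-entered.
* **Cross-project links are forbidden** so that project-scoped permissions
  have a coherent object to protect.

Derived queries — `parents`, `children`, `ancestors`, `descendants`
(transitive closures), `build_tree` (depth-first, children ordered by
internal ID), `trace_origin` (the parentless ancestors paired with their
samples) — are all defined purely in terms of the edge set, and are tested
against an independent graph library's reachability on random DAGs.

## Storage

Persistence is a single SQLite database plus a sibling `files/` directory.
Heavy artefacts (gel images, chromatogram traces, peak lists) are stored
outside the database at `files/<experiment id>/<file_id>_<name>` — the
file_id prefix makes paths collision-free — with a SHA-256 checksum recorded
in the database so every attachment is re-verifiable after any copy or
reopen. Internal IDs are a store-global strictly increasing sequence
(SQLite `AUTOINCREMENT`), never reused. Conditions are stored as a tagged
JSON column; the schema is normalized around the domain types rather than
reproducing any particular production system's table census. Dates are
ISO-8601 strings without timezone handling. Single writer; no migrations.

## Instrument dialects

Five MS peak-list dialects normalize to one in-memory model (spectra with
optional precursor m/z/charge and m/z-sorted peaks):

* **pkl** — per spectrum a `precursor_mz intensity charge` header then
  `mz intensity` lines, blank-line separated. The flavour is declared
  normative for this package (vendor variants differ in whitespace only).
* **MGF** — `BEGIN IONS`/`END IONS` blocks. The writer is bit-exact by
  contract: m/z with 4 decimal places, intensity with 1; unknown headers
  are preserved as instrument metadata.
* **mzML / mzXML / mzData** — base64-encoded uncompressed IEEE-754 arrays;
  mzML uses separate little-endian m/z and intensity arrays, mzXML
  interleaved pairs in network byte order, mzData separate arrays with
  explicit endian attributes. Both 32- and 64-bit precisions are accepted;
  compressed arrays raise an unsupported-feature error naming the feature
  (keeping the dialect surface small and fully testable); m/z-vs-intensity
  length mismatches are format errors.

Spectrum identity is normalized to `spectrum_<n>` in the dialects whose
native identifier is a bare scan number, so the same ground truth renders
and re-parses identically through every dialect (exactly, at 64-bit; to
float32 rounding at 32-bit).

Tabular dialects: tab-delimited 2D-gel spot quantitation tables (required
columns Spot/X/Y/Intensity/Volume/Area, optional %Vol/pI/MW,
case-insensitive), CSV LC peak tables (Peak/RetentionTime/Height/Area,
returned sorted by retention time), and the three identification-engine
CSV exports. Engine scores are normalized to "larger is better": Mascot
ion scores pass through; X!Tandem and OMSSA expectation values become
−log10(e-value). Gel images and chromatogram traces are opaque
attachments, never decoded.

## Access control

Three per-project roles, totally ordered GUEST < RESEARCHER < COORDINATOR.
The matrix: guests see only id/type/title stubs, and only in projects
flagged guest-visible; researchers see every experiment of their projects
but edit only their own; coordinators view and edit everything in their
projects and are the only readers of the project audit trail; non-members
see nothing. One intermediate level (RESEARCHER) concretizes the
guest-to-coordinator range. Passwords are stored only as salted PBKDF2-SHA256
hashes (50 000 iterations — ample for a desk-scale tool); authentication
failure is deliberately opaque about login-vs-password. Every mutating
operation appends an immutable, strictly sequenced audit entry; denied
views are audited too. Library calls accept `actor=None` as an embedded
no-auth mode; the CLI requires credentials unless `--local` is given.

## Plate mapping

A MALDI plate binds wells (row letters × column numbers; 96- and 384-well
layouts plus arbitrary geometries up to 26 rows) of an MS experiment to gel
spots, samples or calibrants. One well holds one source; one spot may
occupy replicate wells. Spot sources are validated against the gel
experiment's parsed spot table, and induce the gel→MS provenance edge when
absent — this is what makes "which spot generated this m/z list?" a pure
graph query. `find_spot` is the exact inverse image of `assign`.

## Completeness checking and reports

The minimum-information field lists (per experiment type, dotted paths into
the record) are data, editable at `miape.MIAPE_REQUIRED`, versioned by
`MIAPE_VERSION`: all types require performer, date, samples and protocol;
MS adds instrument/ionization/analyzer mode; GEL2D adds the strip pI range,
gel %T and stain; LC adds instrument, column and solvent A. The check is
monotone by construction — `missing` is a filter over a fixed list — so
populating a field can only shrink it, and `complete ⇔ missing = ∅`.

Reports (text, HTML, XML) render metadata, conditions, attachments with
checksums, identifications and the experiment tree(s) rooted at the
record's parentless ancestor(s) (one tree per root, sorted by root id);
output is deterministic given an identical store. The XML export excludes
store-local identifiers precisely so that export → import → export is
byte-identical; attachment bytes are recovered content-addressed (by
SHA-256) from the source file store on import. PDF output is deliberately
absent — print-ready HTML covers the use case without presentation
plumbing.

## Search gateway

`prepare_submission` merges an MS experiment's parsed peak-list attachments,
writes the bit-exact MGF, and records a manifest (engine, free-form
parameter map, MGF checksum) — it never runs an engine; a pluggable runner
hook ships as a no-op. `ingest_result` parses an engine's CSV export and
attaches normalized identification records; a missing or mismatched
manifest warns rather than fails.

## Synthetic fixtures

Generators are pure functions of their arguments: a named pseudorandom
stream per generator (`Random("<name>:<seed>")`) means adding a generator
never perturbs another's output and the same seed is byte-identical. Values
are structural, not physico-chemical — m/z uniform in [100, 2000] Th at 4
decimals, intensities in [1, 10⁵] at 1 decimal, precursors in [400, 1200]
with charge 1–3, spot %Vol scaled to sum below 100 — so passing round-trip
tests demonstrates parser/renderer correctness, *not* robustness to real
instrument quirks (vendor header variants, compressed arrays, profile
data), which are out of scope by design. `random_dag` emits edges only from
lower to higher node index, hence acyclic by construction.

The demo store pins internal IDs 1 (PREP protein extraction), 100/146/174
(its children: two gels and an LC run) and 101/148 (MS runs fed by 100 and
146 respectively — which gel fed which MS run is an arbitrary but fixed
convention of the fixture). The pinning uses a fixture-only id-override
hook on experiment creation; production assignment stays sequential, and
IDs created after the fixture continue above the pinned maximum. A
deterministic counter clock makes audit timestamps, and hence all rendered
reports, reproducible.

## Problem sizes and numerical choices

The verification scripts exercise: 200 random DAGs of up to 50 nodes
(closures checked on 10 sampled nodes each, plus a 20-edge candidate
stream per DAG against an independent cycle detector); 100 seeded spectrum
sets round-tripped through all five dialects at 64-bit and the three XML
dialects at 32-bit; the full 9-cell role×ownership permission matrix; 100
random partial experiments for completeness monotonicity; 50 random
plates for inverse mapping. These sizes keep the whole run to well under a
minute per section on one CPU while covering every branch of interest.
Float equality in round-trip tests is exact by design: ground-truth values
are decimal-rounded at generation, and the 4/1-decimal text renderings and
IEEE-754 binary encodings both reproduce those doubles bit-for-bit (32-bit
encodings are compared after an explicit float32 round).

## Known limitations

No schema migrations, no concurrent writers, no spectral processing
(centroiding, deisotoping), no mzIdentML/mzTab, no vendor raw formats, no
compressed binary arrays, no actual search-engine execution, no on-line
LC-MS acquisition workflows. The completeness field lists are a pragmatic
concretization of reporting minima, not a certified implementation of any
guideline document.
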