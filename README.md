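# protrack

A desk-scale proteomics experiment store with provenance tracking.

Proteomics workflows chain many experiments — a protein extraction, 2D-gel
and LC separations, MALDI plate spotting, MS acquisition, database-search
identification — each with its own instrument files, conditions and
operators. `protrack` keeps that chain as data: a multi-project relational
store whose central entity is the typed experiment (PREP, LC, GEL2D, MS),
cross-linked by internal IDs into a provenance DAG. From any record you can
walk to its first (parentless) ancestor to recover the originating sample,
or forward to every downstream result; the rendered **experiment tree** is
the depth-first expansion of those links. Around the core store sit parsers
for the common instrument dialects (pkl, MGF, mzML, mzXML, mzData peak
lists; 2D-gel spot tables; LC peak tables; Mascot/X!Tandem/OMSSA result
exports), MALDI plate mapping back to gel spots, minimum-information
(MIAPE-style) completeness checking, deterministic text/HTML/XML reports,
search-submission manifests, and per-project role-based access control
(guest < researcher < coordinator) with a full audit trail.

It is aimed at small facilities and single labs: one SQLite file plus a
managed `files/` directory, a Python library, and a thin CLI.

## The model in brief

An experiment *e* is a record `(id, type, project, performer, date,
samples, protocol, conditions(type), attachments)`. Provenance is a set of
edges `parent → child` over internal IDs, kept acyclic by construction;
`descendants`/`ancestors` are transitive closures, and
`trace_origin(e) = { a ∈ ancestors(e) ∪ {e} : parents(a) = ∅ }`, each
paired with its samples. Peak lists normalize to spectra of m/z-sorted
`(m/z, intensity)` pairs regardless of source dialect; search-engine scores
normalize to "larger is better" (Mascot ion score as-is, −log10 of the
X!Tandem/OMSSA expectation values). Completeness of a record is checked
against per-type required-field lists resolved as dotted paths, so the
missing list shrinks monotonically as fields are populated.

## Worked example

Materialize the built-in demo project — a *Schistosoma mansoni* extraction
(experiment 1) feeding two gels (100, 146) and an LC run (174), with MS
runs 101 and 148 downstream of the gels — then walk it:

```sh
$ protrack demo --seed 1 --out .
demo store written to protrack.db

$ protrack --store protrack.db --user guest --password guest tree 1
1 [PREP] Protein extraction
  100 [GEL2D] 2D-PAGE pH 3-10
    101 [MS] MALDI-TOF of gel spots (pH 3-10)
  146 [GEL2D] 2D-PAGE pH 4-7
    148 [MS] MALDI-TOF of gel spots (pH 4-7)
  174 [LC] RP-HPLC fractionation
```

Six lines, one per experiment: the root's three direct children and the
two grandchildren, indented by provenance depth. Viewing a record shows
its neighbours in the graph:

```sh
$ protrack --store protrack.db --local experiment view 148
Experiment 148 [MS] MALDI-TOF of gel spots (pH 4-7)
  performed by: herbert  date: 2011-05-17
  attachment: spots_pH4-7.mzML [peak_list]
Parents:  146
Children: (none)
```

Completeness checking, search submission and result ingestion:

```sh
$ protrack --store protrack.db --local miape-check 101 --json
{"complete": true, "experiment": 101, "missing": []}

$ protrack --store protrack.db --local submit 101 mascot --param db=SwissProt
manifest 1: mascot submission for experiment 101

$ protrack --store protrack.db --local ingest 101 mascot idents_mascot.csv
ingested 6 identifications
```

`submit` wrote a bit-exact MGF of experiment 101's five stored spectra plus
a JSON manifest (no engine is executed); `ingest` attached six normalized
identification records, which now appear in `protrack report 101` alongside
the conditions, checksummed attachments and the experiment tree.

The same operations are available as a library (`protrack.Store`,
`protrack.tracking`, `protrack.formats`, `protrack.plates`,
`protrack.miape`, `protrack.gateway`, `protrack.synth`); the CLI contains
no logic of its own. Exit statuses are stable: 0 success, 1 usage error,
2 permission denied, 3 data/format error, 4 not found.

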