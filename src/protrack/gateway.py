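"""Identification-engine gateway.

Prepares search submissions from an MS experiment's stored m/z lists —
a bit-exact MGF plus a JSON manifest recording the engine and search
parameters — and ingests the engines' CSV result exports back onto the
experiment.  No engine is ever invoked here: the contract ends at the
manifest (a pluggable runner hook is declared for deployments that wire
one in, and ships as a no-op).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable
import warnings

from .errors import NotFoundError, ValidationError
from .formats import (IdentRecord, MzList, detect_format, parse_ident_table,
                      parse_mgf, parse_mzdata, parse_mzml, parse_mzxml,
                      parse_pkl, write_mgf)
from .formats.tables import ENGINES

_PARSERS: dict[str, Callable] = {
    "pkl": lambda data: parse_pkl(data.decode()),
    "mgf": lambda data: parse_mgf(data.decode()),
    "mzml": parse_mzml,
    "mzxml": parse_mzxml,
    "mzdata": parse_mzdata,
}


@dataclass(frozen=True)
class SubmissionManifest:
    manifest_id: int
    ms_experiment: int
    engine: str
    params: dict[str, str]
    mgf_file_id: int
    created: str


#: hook point for deployments that actually run an engine; receives the
#: manifest and the MGF text, returns None.  The default does nothing.
runner: Callable[[SubmissionManifest, str], None] = lambda manifest, mgf: None


def experiment_spectra(store, exp_id: int) -> MzList:
    """Merge every parsed peak-list attachment of an experiment into one
    normalized m/z list."""
    merged = MzList("mgf")
    for ref in store.attachments(exp_id, kind="peak_list"):
        data = store.read_attachment(ref)
        fmt = detect_format(data)
        parser = _PARSERS.get(fmt)
        if parser is None:
            continue
        parsed = parser(data)
        merged.spectra.extend(parsed.spectra)
        merged.instrument_meta.update(parsed.instrument_meta)
    return merged.normalized()


def prepare_submission(store, ms_experiment: int, engine: str,
                       params: dict[str, str] | None = None,
                       actor: str | None = None) -> SubmissionManifest:
    """Write the MGF + manifest for a search submission; the stored spectra
    are read, never mutated."""
    if engine not in ENGINES:
        raise ValidationError(f"unknown identification engine {engine!r}")
    row = store._experiment_row(ms_experiment)
    if row["type"] != "MS":
        raise ValidationError(
            f"experiment {ms_experiment} has type {row['type']};"
            " submissions come from MS experiments")
    spectra = experiment_spectra(store, ms_experiment)
    if not spectra.spectra:
        raise ValidationError(
            f"experiment {ms_experiment} has no parsed peak-list attachment")
    params = dict(params or {})
    mgf_text = write_mgf(spectra)
    mgf_ref = store.attach_bytes(
        ms_experiment, mgf_text.encode(),
        f"submission_{engine}.mgf", "peak_list", actor=actor)
    created = store.clock()
    with store.conn:
        cur = store.conn.execute(
            "INSERT INTO manifests(ms_experiment, engine, params,"
            " mgf_file_id, created) VALUES (?,?,?,?,?)",
            (ms_experiment, engine, json.dumps(params, sort_keys=True),
             mgf_ref.file_id, created))
    manifest = SubmissionManifest(cur.lastrowid, ms_experiment, engine,
                                  params, mgf_ref.file_id, created)
    store.attach_bytes(
        ms_experiment, json.dumps({
            "engine": engine, "params": params,
            "mgf": mgf_ref.original_name, "mgf_sha256": mgf_ref.checksum,
            "created": created}, indent=2, sort_keys=True).encode(),
        f"submission_{engine}.json", "other", actor=actor)
    runner(manifest, mgf_text)
    return manifest


def manifests_of(store, ms_experiment: int) -> list[SubmissionManifest]:
    rows = store.conn.execute(
        "SELECT * FROM manifests WHERE ms_experiment=? ORDER BY manifest_id",
        (ms_experiment,)).fetchall()
    return [SubmissionManifest(r["manifest_id"], r["ms_experiment"],
                               r["engine"], json.loads(r["params"]),
                               r["mgf_file_id"], r["created"]) for r in rows]


def ingest_result(store, ms_experiment: int, engine: str, text: str,
                  actor: str | None = None) -> list[IdentRecord]:
    """Attach a search engine's identifications to an MS experiment.

    A missing manifest, or a manifest prepared for a different engine,
    warns but does not fail — results are results.
    """
    store._experiment_row(ms_experiment)
    records = parse_ident_table(text, engine)
    known = manifests_of(store, ms_experiment)
    if not known:
        warnings.warn(f"experiment {ms_experiment} has no submission"
                      " manifest; ingesting anyway")
    elif engine not in {m.engine for m in known}:
        warnings.warn(f"experiment {ms_experiment} has manifests for"
                      f" {sorted({m.engine for m in known})},"
                      f" not {engine!r}; ingesting anyway")
    with store.conn:
        for r in records:
            store.conn.execute(
                "INSERT INTO idents(experiment_id, engine, spectrum_ref,"
                " accession, description, score) VALUES (?,?,?,?,?,?)",
                (ms_experiment, r.engine, r.spectrum_ref, r.accession,
                 r.description, r.score))
    store.record_action(actor, "update", ms_experiment)
    return records


def identifications(store, exp_id: int) -> list[IdentRecord]:
    rows = store.conn.execute(
        "SELECT * FROM idents WHERE experiment_id=? ORDER BY rowid",
        (exp_id,)).fetchall()
    return [IdentRecord(r["engine"], r["spectrum_ref"], r["accession"],
                        r["description"], r["score"]) for r in rows]
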