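"""Embedded relational store for projects, users, samples, protocols and
experiments.

Persistence is a single SQLite database file plus a sibling ``files/``
directory holding attached instrument files (gel images, chromatograms,
peak lists) outside the database, content-addressed with SHA-256 checksums.
Every experiment receives a store-global internal ID, strictly increasing
over creation order, which is the handle used for provenance cross-links.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import shutil
import sqlite3
from pathlib import Path
from typing import Callable, Iterable

from . import models
from .errors import (DuplicateError, NotFoundError, PermissionDenied,
                     ValidationError)
from .models import (Experiment, ExperimentSummary, FileRef, Project,
                     Protocol, Sample)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta(
    key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS users(
    login TEXT PRIMARY KEY,
    password_hash TEXT NOT NULL,
    display_name TEXT NOT NULL DEFAULT '');
CREATE TABLE IF NOT EXISTS projects(
    project_id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL UNIQUE,
    description TEXT NOT NULL DEFAULT '',
    coordinator TEXT NOT NULL REFERENCES users(login),
    guest_visible INTEGER NOT NULL DEFAULT 0);
CREATE TABLE IF NOT EXISTS publications(
    project_id INTEGER NOT NULL REFERENCES projects(project_id),
    citation TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS memberships(
    user TEXT NOT NULL REFERENCES users(login),
    project_id INTEGER NOT NULL REFERENCES projects(project_id),
    role TEXT NOT NULL,
    UNIQUE(user, project_id));
CREATE TABLE IF NOT EXISTS protocols(
    protocol_id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL,
    body TEXT NOT NULL DEFAULT '',
    applies_to TEXT NOT NULL DEFAULT '');
CREATE TABLE IF NOT EXISTS experiments(
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    project_id INTEGER NOT NULL REFERENCES projects(project_id),
    type TEXT NOT NULL,
    title TEXT NOT NULL DEFAULT '',
    performed_by TEXT NOT NULL REFERENCES users(login),
    date TEXT NOT NULL DEFAULT '',
    protocol_id INTEGER REFERENCES protocols(protocol_id),
    notes TEXT NOT NULL DEFAULT '',
    conditions TEXT);
CREATE TABLE IF NOT EXISTS samples(
    sample_id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL,
    organism TEXT NOT NULL DEFAULT '',
    description TEXT NOT NULL DEFAULT '',
    origin_experiment INTEGER REFERENCES experiments(id));
CREATE TABLE IF NOT EXISTS experiment_samples(
    experiment_id INTEGER NOT NULL REFERENCES experiments(id),
    sample_id INTEGER NOT NULL REFERENCES samples(sample_id));
CREATE TABLE IF NOT EXISTS files(
    file_id INTEGER PRIMARY KEY AUTOINCREMENT,
    experiment_id INTEGER NOT NULL REFERENCES experiments(id),
    relative_path TEXT NOT NULL,
    original_name TEXT NOT NULL,
    byte_size INTEGER NOT NULL,
    checksum TEXT NOT NULL,
    kind TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS edges(
    parent INTEGER NOT NULL REFERENCES experiments(id),
    child INTEGER NOT NULL REFERENCES experiments(id),
    created_order INTEGER NOT NULL,
    UNIQUE(parent, child));
CREATE TABLE IF NOT EXISTS plates(
    plate_id INTEGER PRIMARY KEY AUTOINCREMENT,
    ms_experiment INTEGER NOT NULL REFERENCES experiments(id),
    rows INTEGER NOT NULL,
    cols INTEGER NOT NULL);
CREATE TABLE IF NOT EXISTS wells(
    plate_id INTEGER NOT NULL REFERENCES plates(plate_id),
    well TEXT NOT NULL,
    source_type TEXT NOT NULL,
    experiment_id INTEGER,
    spot_or_sample TEXT,
    UNIQUE(plate_id, well));
CREATE TABLE IF NOT EXISTS idents(
    experiment_id INTEGER NOT NULL REFERENCES experiments(id),
    engine TEXT NOT NULL,
    spectrum_ref TEXT NOT NULL,
    accession TEXT NOT NULL,
    description TEXT NOT NULL,
    score REAL NOT NULL);
CREATE TABLE IF NOT EXISTS manifests(
    manifest_id INTEGER PRIMARY KEY AUTOINCREMENT,
    ms_experiment INTEGER NOT NULL REFERENCES experiments(id),
    engine TEXT NOT NULL,
    params TEXT NOT NULL,
    mgf_file_id INTEGER NOT NULL REFERENCES files(file_id),
    created TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS audit(
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    user TEXT NOT NULL,
    action TEXT NOT NULL,
    experiment_id INTEGER,
    timestamp TEXT NOT NULL);
"""


def sha256_hex(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _default_clock() -> str:
    return datetime.datetime.now().isoformat(timespec="seconds")


class Store:
    """Single-writer store bound to one database file and one file root.

    ``clock`` is injectable (a callable returning an ISO-8601 timestamp
    string) so fixture builds and audit trails can be made deterministic.
    """

    def __init__(self, db_path: str | Path, files_root: str | Path | None = None,
                 clock: Callable[[], str] | None = None):
        self.db_path = str(db_path)
        if files_root is None:
            if self.db_path == ":memory:":
                raise ValidationError(
                    "files_root is required for in-memory stores")
            files_root = Path(self.db_path).resolve().parent / "files"
        self.files_root = Path(files_root)
        self.files_root.mkdir(parents=True, exist_ok=True)
        self.clock = clock or _default_clock
        self._conn = sqlite3.connect(self.db_path)
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA foreign_keys = ON")
        with self._conn:
            self._conn.executescript(_SCHEMA)
            self._conn.execute(
                "INSERT OR IGNORE INTO meta(key, value) VALUES ('schema_version', ?)",
                (str(SCHEMA_VERSION),))

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def conn(self) -> sqlite3.Connection:
        return self._conn

    def is_empty(self) -> bool:
        n = self._conn.execute(
            "SELECT (SELECT COUNT(*) FROM users) + (SELECT COUNT(*) FROM projects)"
            " + (SELECT COUNT(*) FROM experiments)").fetchone()[0]
        return n == 0

    # -- audit -------------------------------------------------------------

    def record_action(self, user: str | None, action: str,
                      experiment_id: int | None = None) -> int:
        """Append an immutable audit entry; returns its sequence number."""
        cur = self._conn.execute(
            "INSERT INTO audit(user, action, experiment_id, timestamp) "
            "VALUES (?,?,?,?)",
            (user or "local", action, experiment_id, self.clock()))
        self._conn.commit()
        return cur.lastrowid

    # -- users / memberships (queries; registration lives in access) ------

    def user_exists(self, login: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM users WHERE login=?", (login,)).fetchone() is not None

    def membership_role(self, user: str, project_id: int) -> str | None:
        row = self._conn.execute(
            "SELECT role FROM memberships WHERE user=? AND project_id=?",
            (user, project_id)).fetchone()
        return row["role"] if row else None

    def memberships_of(self, user: str) -> dict[int, str]:
        return {r["project_id"]: r["role"] for r in self._conn.execute(
            "SELECT project_id, role FROM memberships WHERE user=?", (user,))}

    def add_member(self, project_id: int, user: str, role: str) -> None:
        from .access import ROLE_ORDER
        if role not in ROLE_ORDER:
            raise ValidationError(f"unknown role {role!r}")
        self.get_project(project_id)
        if not self.user_exists(user):
            raise NotFoundError(f"unknown user {user!r}")
        try:
            with self._conn:
                self._conn.execute(
                    "INSERT INTO memberships(user, project_id, role) VALUES (?,?,?)",
                    (user, project_id, role))
        except sqlite3.IntegrityError:
            raise DuplicateError(
                f"user {user!r} already a member of project {project_id}")

    # -- projects ----------------------------------------------------------

    def create_project(self, name: str, description: str, coordinator: str,
                       guest_visible: bool = False,
                       publications: Iterable[str] = ()) -> Project:
        if not name:
            raise ValidationError("project name must be nonempty")
        if not self.user_exists(coordinator):
            raise NotFoundError(f"unknown coordinator {coordinator!r}")
        try:
            with self._conn:
                cur = self._conn.execute(
                    "INSERT INTO projects(name, description, coordinator,"
                    " guest_visible) VALUES (?,?,?,?)",
                    (name, description, coordinator, int(guest_visible)))
                project_id = cur.lastrowid
                self._conn.execute(
                    "INSERT INTO memberships(user, project_id, role)"
                    " VALUES (?,?,'COORDINATOR')", (coordinator, project_id))
                for citation in publications:
                    self._conn.execute(
                        "INSERT INTO publications(project_id, citation)"
                        " VALUES (?,?)", (project_id, citation))
        except sqlite3.IntegrityError:
            raise DuplicateError(f"project name {name!r} already in use")
        return self.get_project(project_id)

    def get_project(self, project_id: int) -> Project:
        row = self._conn.execute(
            "SELECT * FROM projects WHERE project_id=?", (project_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown project {project_id}")
        pubs = tuple(r["citation"] for r in self._conn.execute(
            "SELECT citation FROM publications WHERE project_id=?", (project_id,)))
        return Project(row["project_id"], row["name"], row["description"],
                       row["coordinator"], pubs, bool(row["guest_visible"]))

    def get_project_by_name(self, name: str) -> Project:
        row = self._conn.execute(
            "SELECT project_id FROM projects WHERE name=?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown project {name!r}")
        return self.get_project(row["project_id"])

    # -- samples / protocols ----------------------------------------------

    def create_sample(self, name: str, organism: str = "", description: str = "",
                      origin_experiment: int | None = None) -> Sample:
        if origin_experiment is not None:
            self._experiment_row(origin_experiment)
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO samples(name, organism, description,"
                " origin_experiment) VALUES (?,?,?,?)",
                (name, organism, description, origin_experiment))
        return Sample(cur.lastrowid, name, organism, description,
                      origin_experiment)

    def get_sample(self, sample_id: int) -> Sample:
        row = self._conn.execute(
            "SELECT * FROM samples WHERE sample_id=?", (sample_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown sample {sample_id}")
        return Sample(row["sample_id"], row["name"], row["organism"],
                      row["description"], row["origin_experiment"])

    def create_protocol(self, name: str, body: str = "",
                        applies_to: str = "") -> Protocol:
        if not name:
            raise ValidationError("protocol name must be nonempty")
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO protocols(name, body, applies_to) VALUES (?,?,?)",
                (name, body, applies_to))
        return Protocol(cur.lastrowid, name, body, applies_to)

    def get_protocol(self, protocol_id: int) -> Protocol:
        row = self._conn.execute(
            "SELECT * FROM protocols WHERE protocol_id=?", (protocol_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown protocol {protocol_id}")
        return Protocol(row["protocol_id"], row["name"], row["body"],
                        row["applies_to"])

    # -- experiments -------------------------------------------------------

    def create_experiment(self, project_id: int, exp_type: str, title: str,
                          performed_by: str, date: str,
                          conditions: models.Conditions | None = None,
                          samples: Iterable[int] = (),
                          protocol_id: int | None = None,
                          notes: str = "",
                          actor: str | None = None,
                          _force_id: int | None = None) -> Experiment:
        """Persist a new experiment under a fresh internal ID.

        ``_force_id`` is a fixture-only hook letting demo builders pin
        specific internal IDs; production assignment is the sequential
        default.
        """
        self.get_project(project_id)
        if self.membership_role(performed_by, project_id) is None:
            raise ValidationError(
                f"performer {performed_by!r} is not a member of project"
                f" {project_id}")
        models.check_conditions(exp_type, conditions)
        if protocol_id is not None:
            self.get_protocol(protocol_id)
        sample_ids = list(samples)
        for sid in sample_ids:
            self.get_sample(sid)
        if actor is not None:
            from .access import require_project_write
            require_project_write(self, actor, project_id)
        cond_json = models.conditions_to_json(conditions)
        with self._conn:
            if _force_id is not None:
                cur = self._conn.execute(
                    "INSERT INTO experiments(id, project_id, type, title,"
                    " performed_by, date, protocol_id, notes, conditions)"
                    " VALUES (?,?,?,?,?,?,?,?,?)",
                    (_force_id, project_id, exp_type, title, performed_by,
                     date, protocol_id, notes,
                     json.dumps(cond_json) if cond_json else None))
            else:
                cur = self._conn.execute(
                    "INSERT INTO experiments(project_id, type, title,"
                    " performed_by, date, protocol_id, notes, conditions)"
                    " VALUES (?,?,?,?,?,?,?,?)",
                    (project_id, exp_type, title, performed_by, date,
                     protocol_id, notes,
                     json.dumps(cond_json) if cond_json else None))
            exp_id = cur.lastrowid
            for sid in sample_ids:
                self._conn.execute(
                    "INSERT INTO experiment_samples(experiment_id, sample_id)"
                    " VALUES (?,?)", (exp_id, sid))
        self.record_action(actor or performed_by, "create", exp_id)
        return self.get_experiment(exp_id)

    def _experiment_row(self, exp_id: int) -> sqlite3.Row:
        row = self._conn.execute(
            "SELECT * FROM experiments WHERE id=?", (exp_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown experiment {exp_id}")
        return row

    def experiment_exists(self, exp_id: int) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM experiments WHERE id=?", (exp_id,)).fetchone() is not None

    def get_experiment(self, exp_id: int, actor: str | None = None) -> Experiment:
        """Return the full record; with an acting user, the access-control
        matrix applies and guest-level access yields an id/type/title stub."""
        row = self._experiment_row(exp_id)
        if actor is not None:
            from .access import can_view
            decision = can_view(self, actor, exp_id)
            if not decision.allowed:
                self.record_action(actor, "view-denied", exp_id)
                raise PermissionDenied(decision.reason)
            if decision.scope == "stub":
                return Experiment(row["id"], row["project_id"], row["type"],
                                  row["title"], "", "")
        protocol = (self.get_protocol(row["protocol_id"])
                    if row["protocol_id"] is not None else None)
        sample_rows = self._conn.execute(
            "SELECT sample_id FROM experiment_samples WHERE experiment_id=?"
            " ORDER BY sample_id", (exp_id,)).fetchall()
        samples = [self.get_sample(r["sample_id"]) for r in sample_rows]
        conditions = models.conditions_from_json(
            json.loads(row["conditions"]) if row["conditions"] else None)
        return Experiment(
            id=row["id"], project_id=row["project_id"], type=row["type"],
            title=row["title"], performed_by=row["performed_by"],
            date=row["date"], protocol=protocol, samples=samples,
            conditions=conditions, attachments=self.attachments(exp_id),
            notes=row["notes"])

    def list_experiments(self, project_id: int,
                         type_filter: str | None = None
                         ) -> list[ExperimentSummary]:
        self.get_project(project_id)
        if type_filter is not None and type_filter not in models.EXPERIMENT_TYPES:
            raise ValidationError(f"unknown experiment type {type_filter!r}")
        sql = ("SELECT id, type, title, performed_by, date FROM experiments"
               " WHERE project_id=?")
        args: list = [project_id]
        if type_filter is not None:
            sql += " AND type=?"
            args.append(type_filter)
        sql += " ORDER BY id ASC"
        return [ExperimentSummary(r["id"], r["type"], r["title"],
                                  r["performed_by"], r["date"])
                for r in self._conn.execute(sql, args)]

    # -- file attachments --------------------------------------------------

    def attach_file(self, exp_id: int, source_path: str | Path, kind: str,
                    actor: str | None = None) -> FileRef:
        source = Path(source_path)
        try:
            data = source.read_bytes()
        except OSError as exc:
            raise ValidationError(f"unreadable file {source}: {exc}")
        return self.attach_bytes(exp_id, data, source.name, kind, actor=actor)

    def attach_bytes(self, exp_id: int, data: bytes, original_name: str,
                     kind: str, actor: str | None = None) -> FileRef:
        """Copy bytes into the managed store under
        ``files/<experiment id>/<file_id>_<original_name>``; the file_id
        prefix makes paths collision-free."""
        self._experiment_row(exp_id)
        if kind not in models.FILE_KINDS:
            raise ValidationError(f"unknown file kind {kind!r}")
        if actor is not None:
            from .access import require_edit
            require_edit(self, actor, exp_id)
        checksum = sha256_hex(data)
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO files(experiment_id, relative_path, original_name,"
                " byte_size, checksum, kind) VALUES (?,'',?,?,?,?)",
                (exp_id, original_name, len(data), checksum, kind))
            file_id = cur.lastrowid
            relative = f"{exp_id}/{file_id}_{original_name}"
            self._conn.execute(
                "UPDATE files SET relative_path=? WHERE file_id=?",
                (relative, file_id))
        target = self.files_root / relative
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(data)
        self.record_action(actor, "attach", exp_id)
        return FileRef(file_id, relative, original_name, len(data),
                       checksum, kind)

    def attachments(self, exp_id: int, kind: str | None = None) -> list[FileRef]:
        sql = "SELECT * FROM files WHERE experiment_id=?"
        args: list = [exp_id]
        if kind is not None:
            sql += " AND kind=?"
            args.append(kind)
        sql += " ORDER BY file_id"
        return [FileRef(r["file_id"], r["relative_path"], r["original_name"],
                        r["byte_size"], r["checksum"], r["kind"])
                for r in self._conn.execute(sql, args)]

    def read_attachment(self, ref: FileRef) -> bytes:
        path = (self.files_root / ref.relative_path).resolve()
        if self.files_root.resolve() not in path.parents:
            raise ValidationError(
                f"attachment path {ref.relative_path!r} escapes the file store")
        return path.read_bytes()

    def verify_attachments(self) -> list[FileRef]:
        """Re-hash every stored file; returns the refs whose bytes no longer
        match their recorded checksum (empty list means all verified)."""
        bad = []
        for r in self._conn.execute("SELECT * FROM files"):
            ref = FileRef(r["file_id"], r["relative_path"], r["original_name"],
                          r["byte_size"], r["checksum"], r["kind"])
            try:
                data = self.read_attachment(ref)
            except OSError:
                bad.append(ref)
                continue
            if sha256_hex(data) != ref.checksum or len(data) != ref.byte_size:
                bad.append(ref)
        return bad
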