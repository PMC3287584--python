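"""MALDI target-plate mapping.

A plate binds wells (named row letter + column number: 96-well = A1..H12,
384-well = A1..P24) of an MS experiment to the material spotted in each
well: a gel spot from an earlier 2D-PAGE experiment, a sample, or a
calibrant.  One well holds one source, but one spot may occupy several
wells (technical replicates), so the well→source map is a function and its
inverse image is one-to-many.  Assigning a gel spot also records the
provenance edge gel-experiment → MS-experiment if it is not already there,
which is what later lets a researcher ask which spot generated a given
m/z list.
"""

from __future__ import annotations

import csv
import io
import re
import string
from dataclasses import dataclass

from . import tracking
from .errors import (DuplicateError, NotFoundError, ValidationError)
from .formats import parse_spot_table

CALIBRANT = "calibrant"


@dataclass(frozen=True)
class PlateSpec:
    """Plate geometry; rows are lettered A.. (at most 26), columns numbered
    from 1."""

    rows: int
    cols: int

    def __post_init__(self):
        if not 1 <= self.rows <= 26:
            raise ValidationError(f"rows must be in 1..26, got {self.rows}")
        if self.cols < 1:
            raise ValidationError(f"cols must be >= 1, got {self.cols}")

    def well_names(self) -> list[str]:
        """All well names in row-major order (A1, A2, ..)."""
        return [f"{string.ascii_uppercase[r]}{c + 1}"
                for r in range(self.rows) for c in range(self.cols)]

    def is_valid(self, well: str) -> bool:
        m = re.fullmatch(r"([A-Z])([0-9]+)", well)
        if not m:
            return False
        row = string.ascii_uppercase.index(m.group(1))
        col = int(m.group(2))
        return row < self.rows and 1 <= col <= self.cols

    def sort_key(self, well: str):
        m = re.fullmatch(r"([A-Z])([0-9]+)", well)
        return (m.group(1), int(m.group(2)))


@dataclass(frozen=True)
class WellAssignment:
    well: str
    source_type: str           # "spot" | "sample" | "calibrant"
    experiment_id: int | None  # gel experiment for spot sources
    spot_or_sample: str | None


@dataclass(frozen=True)
class PlateMap:
    plate_id: int
    ms_experiment: int
    spec: PlateSpec


def new_plate(store, ms_experiment: int, spec: PlateSpec,
              actor: str | None = None) -> PlateMap:
    row = store._experiment_row(ms_experiment)
    if row["type"] != "MS":
        raise ValidationError(
            f"experiment {ms_experiment} has type {row['type']};"
            " plates attach to MS experiments only")
    with store.conn:
        cur = store.conn.execute(
            "INSERT INTO plates(ms_experiment, rows, cols) VALUES (?,?,?)",
            (ms_experiment, spec.rows, spec.cols))
    store.record_action(actor, "update", ms_experiment)
    return PlateMap(cur.lastrowid, ms_experiment, spec)


def get_plate(store, plate_id: int) -> PlateMap:
    row = store.conn.execute(
        "SELECT * FROM plates WHERE plate_id=?", (plate_id,)).fetchone()
    if row is None:
        raise NotFoundError(f"unknown plate {plate_id}")
    return PlateMap(row["plate_id"], row["ms_experiment"],
                    PlateSpec(row["rows"], row["cols"]))


def _spot_ids_of(store, gel_experiment: int) -> set[str]:
    spot_ids: set[str] = set()
    for ref in store.attachments(gel_experiment, kind="spot_table"):
        text = store.read_attachment(ref).decode()
        spot_ids |= {r.spot_id for r in parse_spot_table(text)}
    return spot_ids


def assign(store, plate_id: int, well: str, source_type: str,
           experiment_id: int | None = None,
           spot_or_sample: str | None = None,
           actor: str | None = None) -> WellAssignment:
    """Assign one well to one source.

    Spot sources are checked against the gel experiment's parsed spot
    table, and induce the gel→MS provenance edge when missing.
    """
    plate = get_plate(store, plate_id)
    if not plate.spec.is_valid(well):
        raise ValidationError(
            f"well {well!r} invalid for a {plate.spec.rows}x"
            f"{plate.spec.cols} plate")
    if source_type == "spot":
        if experiment_id is None or spot_or_sample is None:
            raise ValidationError(
                "spot sources need a gel experiment id and a spot id")
        grow = store._experiment_row(experiment_id)
        if grow["type"] != "GEL2D":
            raise ValidationError(
                f"experiment {experiment_id} is {grow['type']}, not GEL2D")
        if spot_or_sample not in _spot_ids_of(store, experiment_id):
            raise NotFoundError(
                f"spot {spot_or_sample!r} not found in the spot tables of"
                f" experiment {experiment_id}")
    elif source_type == "sample":
        if spot_or_sample is None:
            raise ValidationError("sample sources need a sample id")
        store.get_sample(int(spot_or_sample))
        experiment_id = None
    elif source_type == CALIBRANT:
        experiment_id = None
        spot_or_sample = None
    else:
        raise ValidationError(f"unknown source type {source_type!r}")
    try:
        with store.conn:
            store.conn.execute(
                "INSERT INTO wells(plate_id, well, source_type,"
                " experiment_id, spot_or_sample) VALUES (?,?,?,?,?)",
                (plate_id, well, source_type, experiment_id, spot_or_sample))
    except Exception as exc:
        if "UNIQUE" in str(exc):
            raise DuplicateError(
                f"well {well} of plate {plate_id} is already assigned")
        raise
    if source_type == "spot" and \
            plate.ms_experiment not in tracking.children(store, experiment_id):
        tracking.link(store, experiment_id, plate.ms_experiment, actor=actor)
    store.record_action(actor, "update", plate.ms_experiment)
    return WellAssignment(well, source_type, experiment_id, spot_or_sample)


def lookup(store, plate_id: int, well: str) -> WellAssignment | None:
    plate = get_plate(store, plate_id)
    if not plate.spec.is_valid(well):
        raise ValidationError(f"well {well!r} invalid for this plate")
    row = store.conn.execute(
        "SELECT * FROM wells WHERE plate_id=? AND well=?",
        (plate_id, well)).fetchone()
    if row is None:
        return None
    return WellAssignment(row["well"], row["source_type"],
                          row["experiment_id"], row["spot_or_sample"])


def assignments(store, plate_id: int) -> list[WellAssignment]:
    plate = get_plate(store, plate_id)
    rows = store.conn.execute(
        "SELECT * FROM wells WHERE plate_id=?", (plate_id,)).fetchall()
    out = [WellAssignment(r["well"], r["source_type"], r["experiment_id"],
                          r["spot_or_sample"]) for r in rows]
    return sorted(out, key=lambda a: plate.spec.sort_key(a.well))


def find_spot(store, plate_id: int, gel_experiment: int,
              spot_id: str) -> list[str]:
    """All wells (row-major order) carrying the given gel spot; a spot may
    be spotted in replicate wells, and an unassigned spot yields []."""
    return [a.well for a in assignments(store, plate_id)
            if a.source_type == "spot"
            and a.experiment_id == gel_experiment
            and a.spot_or_sample == spot_id]


def export_csv(store, plate_id: int) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["Well", "SourceType", "ExperimentId", "SpotOrSampleId"])
    for a in assignments(store, plate_id):
        writer.writerow([a.well, a.source_type,
                         "" if a.experiment_id is None else a.experiment_id,
                         "" if a.spot_or_sample is None else a.spot_or_sample])
    return buf.getvalue()


def import_csv(store, plate_id: int, text: str,
               actor: str | None = None) -> list[WellAssignment]:
    reader = csv.DictReader(io.StringIO(text))
    out = []
    for row in reader:
        out.append(assign(
            store, plate_id, row["Well"], row["SourceType"],
            experiment_id=int(row["ExperimentId"])
            if row.get("ExperimentId") else None,
            spot_or_sample=row["SpotOrSampleId"]
            if row.get("SpotOrSampleId") else None,
            actor=actor))
    return out
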