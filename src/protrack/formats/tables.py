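"""Tabular instrument exports: 2D-gel spot quantitation tables, LC peak
tables and search-engine identification tables.

The spot-table dialect is a tab-delimited export with one row per detected
spot (position, intensity, volume, area, optionally %volume and the pI/MW
estimates).  LC peak tables are plain CSV.  Identification exports from the
three supported engines normalize to a shared record whose score is always
"larger is better": Mascot ion scores pass through, X!Tandem and OMSSA
expectation values become -log10(e-value).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass

from ..errors import FormatError, ValidationError

ENGINES = ("mascot", "xtandem", "omssa")


@dataclass(frozen=True)
class SpotRecord:
    spot_id: str
    x: float
    y: float
    intensity: float
    volume: float
    area: float
    percent_volume: float | None = None
    pi: float | None = None
    mw: float | None = None

    def validate(self) -> None:
        if self.x < 0 or self.y < 0 or self.area < 0:
            raise FormatError(
                f"spot {self.spot_id}: x, y and area must be non-negative")
        if self.percent_volume is not None and not \
                0 <= self.percent_volume <= 100:
            raise FormatError(
                f"spot {self.spot_id}: %Vol {self.percent_volume} outside"
                " [0, 100]")


@dataclass(frozen=True)
class LCPeakRow:
    peak_no: int
    retention_time: float
    height: float
    area: float


@dataclass(frozen=True)
class IdentRecord:
    engine: str
    spectrum_ref: str
    accession: str
    description: str
    score: float


_SPOT_REQUIRED = ("spot", "x", "y", "intensity", "volume", "area")
_SPOT_OPTIONAL = {"%vol": "percent_volume", "pi": "pi", "mw": "mw"}


def parse_spot_table(text: str) -> list[SpotRecord]:
    """Parse a tab-delimited spot quantitation table (header row required;
    column names matched case-insensitively)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("spot table is empty (no header row)")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    index = {name: i for i, name in enumerate(header)}
    for col in _SPOT_REQUIRED:
        if col not in index:
            raise FormatError(f"spot table missing required column {col!r}")
    records = []
    for rowno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")

        def cell(col: str, optional: bool = False) -> float | None:
            i = index.get(col)
            if i is None or i >= len(cells) or not cells[i].strip():
                if optional:
                    return None
                raise FormatError(f"row {rowno}: missing value for {col!r}")
            try:
                return float(cells[i])
            except ValueError:
                raise FormatError(
                    f"row {rowno}, column {col!r}: non-numeric value"
                    f" {cells[i]!r}")

        record = SpotRecord(
            spot_id=cells[index["spot"]].strip(),
            x=cell("x"), y=cell("y"), intensity=cell("intensity"),
            volume=cell("volume"), area=cell("area"),
            percent_volume=cell("%vol", optional=True),
            pi=cell("pi", optional=True), mw=cell("mw", optional=True))
        record.validate()
        records.append(record)
    return records


def parse_lc_peak_table(text: str) -> list[LCPeakRow]:
    """Parse a CSV LC peak table with columns Peak, RetentionTime, Height,
    Area (case-insensitive); rows are returned sorted by retention time."""
    reader = csv.reader(io.StringIO(text))
    rows = [r for r in reader if any(c.strip() for c in r)]
    if not rows:
        raise FormatError("LC peak table is empty (no header row)")
    header = [h.strip().lower() for h in rows[0]]
    index = {}
    for col in ("peak", "retentiontime", "height", "area"):
        if col not in header:
            raise FormatError(f"LC peak table missing column {col!r}")
        index[col] = header.index(col)
    out = []
    for rowno, cells in enumerate(rows[1:], start=2):
        try:
            rt = float(cells[index["retentiontime"]])
            row = LCPeakRow(peak_no=int(float(cells[index["peak"]])),
                            retention_time=rt,
                            height=float(cells[index["height"]]),
                            area=float(cells[index["area"]]))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"row {rowno}: {exc}")
        if row.retention_time < 0:
            raise ValidationError(
                f"row {rowno}: negative retention time {row.retention_time}")
        out.append(row)
    return sorted(out, key=lambda r: r.retention_time)


# engine → (spectrum-ref, accession, description, score) column names
_IDENT_COLUMNS = {
    "mascot": ("pep_query", "prot_acc", "prot_desc", "pep_score"),
    "xtandem": ("id", "label", "description", "expect"),
    "omssa": ("Spectrum number", "Accession", "Defline", "E-value"),
}


def parse_ident_table(text: str, engine: str) -> list[IdentRecord]:
    """Parse an engine-specific CSV identification export into normalized
    records.  Mascot scores are used as-is; X!Tandem and OMSSA report
    expectation values, transformed to -log10 so that across all three
    engines a larger score is better."""
    if engine not in _IDENT_COLUMNS:
        raise ValidationError(f"unknown identification engine {engine!r}")
    ref_col, acc_col, desc_col, score_col = _IDENT_COLUMNS[engine]
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise FormatError("identification table is empty")
    fields = {f.strip().lower(): f for f in reader.fieldnames}
    for col in (ref_col, acc_col, desc_col, score_col):
        if col.lower() not in fields:
            raise FormatError(
                f"{engine} table missing mapped column {col!r}")
    out = []
    for rowno, row in enumerate(reader, start=2):
        try:
            raw_score = float(row[fields[score_col.lower()]])
        except (TypeError, ValueError):
            raise FormatError(f"row {rowno}: non-numeric score")
        if engine in ("xtandem", "omssa"):
            if raw_score <= 0:
                raise FormatError(
                    f"row {rowno}: expectation value must be positive")
            score = -math.log10(raw_score)
        else:
            score = raw_score
        out.append(IdentRecord(
            engine=engine,
            spectrum_ref=str(row[fields[ref_col.lower()]]).strip(),
            accession=str(row[fields[acc_col.lower()]]).strip(),
            description=str(row[fields[desc_col.lower()]]).strip(),
            score=score))
    return out
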