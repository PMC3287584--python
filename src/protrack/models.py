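"""Core domain records.

The experiment is the central entity: a typed record (PREP, LC, GEL2D or MS)
carrying sample references, a protocol, instrument conditions matching its
type, and file attachments.  Exactly the three instrument types (LC, GEL2D,
MS) have condition structures; PREP experiments (e.g. a protein extraction)
carry sample and protocol information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

from .errors import ValidationError

EXPERIMENT_TYPES = ("PREP", "LC", "GEL2D", "MS")

#: the three experiment types that carry instrument condition structures
INSTRUMENT_TYPES = ("LC", "GEL2D", "MS")

FILE_KINDS = ("gel_image", "chromatogram", "peak_list", "spot_table",
              "ident_result", "other")


@dataclass
class LCConditions:
    """Liquid-chromatography run conditions.

    flow_rate is in mL/min, temperature in degrees Celsius and
    detection_wavelength in nm.
    """

    instrument: str | None = None
    column: str | None = None
    solvent_a: str | None = None
    solvent_b: str | None = None
    gradient: str | None = None
    flow_rate: float | None = None
    temperature: float | None = None
    detection_wavelength: float | None = None

    def validate(self) -> None:
        if self.flow_rate is not None and not self.flow_rate > 0:
            raise ValidationError("flow_rate must be > 0 when present")
        if self.temperature is not None and not math.isfinite(self.temperature):
            raise ValidationError("temperature must be finite")


@dataclass
class GelConditions:
    """2D-PAGE conditions: IEF strip pI range and volt-hours for the first
    dimension, gel %T and voltage/run time for the second, plus the stain."""

    strip_pi_low: float | None = None
    strip_pi_high: float | None = None
    focusing_volt_hours: float | None = None
    gel_percent: float | None = None
    second_dim_voltage: float | None = None
    run_time: float | None = None
    stain: str | None = None

    def validate(self) -> None:
        if (self.strip_pi_low is not None and self.strip_pi_high is not None
                and not self.strip_pi_low < self.strip_pi_high):
            raise ValidationError("strip_pi_low must be < strip_pi_high")


@dataclass
class MSConditions:
    """Mass-spectrometry acquisition conditions; mz_low/mz_high in Th."""

    instrument: str | None = None
    ionization: str | None = None
    analyzer_mode: str | None = None
    matrix: str | None = None
    mz_low: float | None = None
    mz_high: float | None = None

    def validate(self) -> None:
        if (self.mz_low is not None and self.mz_high is not None
                and not self.mz_low < self.mz_high):
            raise ValidationError("mz_low must be < mz_high")


CONDITIONS_BY_TYPE = {"LC": LCConditions, "GEL2D": GelConditions,
                      "MS": MSConditions, "PREP": type(None)}

Conditions = LCConditions | GelConditions | MSConditions


def check_conditions(exp_type: str, conditions: Conditions | None) -> None:
    """Raise unless the conditions variant matches the experiment type."""
    if exp_type not in EXPERIMENT_TYPES:
        raise ValidationError(f"unknown experiment type {exp_type!r}")
    expected = CONDITIONS_BY_TYPE[exp_type]
    if conditions is None:
        if exp_type != "PREP":
            raise ValidationError(
                f"{exp_type} experiments require {expected.__name__}")
        return
    if exp_type == "PREP":
        raise ValidationError("PREP experiments carry no instrument conditions")
    if not isinstance(conditions, expected):
        raise ValidationError(
            f"{exp_type} experiment given {type(conditions).__name__}, "
            f"expected {expected.__name__}")
    conditions.validate()


def conditions_to_json(conditions: Conditions | None) -> dict | None:
    if conditions is None:
        return None
    d = asdict(conditions)
    d["variant"] = type(conditions).__name__
    return d


def conditions_from_json(d: dict | None) -> Conditions | None:
    if d is None:
        return None
    d = dict(d)
    variant = d.pop("variant")
    cls = {"LCConditions": LCConditions, "GelConditions": GelConditions,
           "MSConditions": MSConditions}[variant]
    known = {f.name for f in fields(cls)}
    return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class Project:
    project_id: int
    name: str
    description: str
    coordinator: str
    publications: tuple[str, ...] = ()
    guest_visible: bool = False


@dataclass(frozen=True)
class Sample:
    sample_id: int
    name: str
    organism: str = ""
    description: str = ""
    origin_experiment: int | None = None


@dataclass(frozen=True)
class Protocol:
    protocol_id: int
    name: str
    body: str = ""
    applies_to: str = ""


@dataclass(frozen=True)
class FileRef:
    """Pointer to a managed-store file; heavy artefacts (gel images,
    chromatogram traces) live outside the database, content-addressed by a
    SHA-256 checksum that can be re-verified at any time."""

    file_id: int
    relative_path: str
    original_name: str
    byte_size: int
    checksum: str
    kind: str


@dataclass
class Experiment:
    id: int
    project_id: int
    type: str
    title: str
    performed_by: str
    date: str
    protocol: Protocol | None = None
    samples: list[Sample] = field(default_factory=list)
    conditions: Conditions | None = None
    attachments: list[FileRef] = field(default_factory=list)
    notes: str = ""


@dataclass(frozen=True)
class ExperimentSummary:
    id: int
    type: str
    title: str
    performed_by: str
    date: str
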