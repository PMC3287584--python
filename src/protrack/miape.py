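"""Minimum-information completeness checking and experiment reports.

The required-field lists below are this package's explicit, versioned
concretization of the MIAPE (Minimum Information About a Proteomics
Experiment) reporting minima for mass spectrometry, gel electrophoresis
and column chromatography.  They are data, not code: a deployment may edit
:data:`MIAPE_REQUIRED` to match its own reporting policy, and the checker
resolves the dotted field paths against the experiment record at run time.

Reports render an experiment's metadata, conditions, attachments and
identifications plus the experiment tree(s) rooted at its parentless
ancestor(s), in plain text, HTML or XML, deterministically: identical
stores yield byte-identical documents.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, fields as _dataclass_fields

from lxml import etree

from . import tracking
from .errors import NotFoundError, ValidationError
from .models import Experiment

MIAPE_VERSION = 1

#: experiment type -> ordered list of required dotted field paths
MIAPE_REQUIRED: dict[str, list[str]] = {
    "PREP": ["performed_by", "date", "samples", "protocol"],
    "MS": ["performed_by", "date", "samples", "protocol",
           "conditions.instrument", "conditions.ionization",
           "conditions.analyzer_mode"],
    "GEL2D": ["performed_by", "date", "samples", "protocol",
              "conditions.strip_pi_low", "conditions.strip_pi_high",
              "conditions.gel_percent", "conditions.stain"],
    "LC": ["performed_by", "date", "samples", "protocol",
           "conditions.instrument", "conditions.column",
           "conditions.solvent_a"],
}


@dataclass(frozen=True)
class CompletenessReport:
    experiment: int
    missing: tuple[str, ...]

    @property
    def complete(self) -> bool:
        return not self.missing


def _resolve(experiment: Experiment, path: str):
    obj = experiment
    for part in path.split("."):
        if obj is None:
            return None
        obj = getattr(obj, part, None)
    return obj


def _populated(value) -> bool:
    if value is None:
        return False
    if isinstance(value, str):
        return bool(value.strip())
    if isinstance(value, (list, tuple)):
        return len(value) > 0
    return True


def miape_check(store, exp_id: int) -> CompletenessReport:
    """Report the required fields still missing from an experiment, in the
    policy's order; complete iff the list is empty."""
    experiment = store.get_experiment(exp_id)
    required = MIAPE_REQUIRED[experiment.type]
    missing = tuple(path for path in required
                    if not _populated(_resolve(experiment, path)))
    return CompletenessReport(exp_id, missing)


# ---------------------------------------------------------------------------
# report rendering

def _condition_items(experiment: Experiment) -> list[tuple[str, str]]:
    if experiment.conditions is None:
        return []
    return [(f.name, str(getattr(experiment.conditions, f.name)))
            for f in _dataclass_fields(experiment.conditions)
            if getattr(experiment.conditions, f.name) is not None]


def _ident_rows(store, exp_id: int) -> list[tuple]:
    return store.conn.execute(
        "SELECT engine, spectrum_ref, accession, description, score"
        " FROM idents WHERE experiment_id=? ORDER BY rowid",
        (exp_id,)).fetchall()


def _trees(store, exp_id: int) -> list[tracking.ExperimentTreeNode]:
    return [tracking.build_tree(store, root)
            for root in tracking.roots_of(store, exp_id)]


def render_report(store, exp_id: int, fmt: str = "text",
                  actor: str | None = None) -> str:
    """Render a full experiment report; ``fmt`` is text, html or xml."""
    if fmt not in ("text", "html", "xml"):
        raise ValidationError(f"unknown report format {fmt!r}")
    if actor is not None:
        from .access import require_view
        require_view(store, actor, exp_id)
    experiment = store.get_experiment(exp_id, actor=actor)
    if fmt == "text":
        return _render_text(store, experiment)
    if fmt == "html":
        return _render_html(store, experiment)
    return export_record(store, exp_id, include_tree=True).decode()


def _render_text(store, e: Experiment) -> str:
    lines = [f"Experiment {e.id} [{e.type}] {e.title}",
             f"  project: {store.get_project(e.project_id).name}",
             f"  performed by: {e.performed_by}",
             f"  date: {e.date}"]
    if e.protocol:
        lines.append(f"  protocol: {e.protocol.name}")
    for s in e.samples:
        lines.append(f"  sample: {s.name} ({s.organism})")
    if e.notes:
        lines.append(f"  notes: {e.notes}")
    items = _condition_items(e)
    if items:
        lines.append("Conditions:")
        lines += [f"  {k}: {v}" for k, v in items]
    if e.attachments:
        lines.append("Attachments:")
        lines += [f"  {a.original_name} [{a.kind}] {a.byte_size} B"
                  f" sha256={a.checksum}" for a in e.attachments]
    idents = _ident_rows(store, e.id)
    if idents:
        lines.append("Identifications:")
        lines += [f"  {r['engine']}: {r['accession']} ({r['description']})"
                  f" score={r['score']:.2f} spectrum={r['spectrum_ref']}"
                  for r in idents]
    lines.append("Experiment tree:")
    for tree in _trees(store, e.id):
        lines.append(tree.to_text())
    return "\n".join(lines) + "\n"


def _render_html(store, e: Experiment) -> str:
    esc = _html.escape
    parts = ["<!DOCTYPE html>", "<html><head><title>"
             f"Experiment {e.id}</title></head><body>",
             f"<h1>Experiment {e.id} [{esc(e.type)}] {esc(e.title)}</h1>",
             "<dl>",
             f"<dt>Project</dt><dd>{esc(store.get_project(e.project_id).name)}</dd>",
             f"<dt>Performed by</dt><dd>{esc(e.performed_by)}</dd>",
             f"<dt>Date</dt><dd>{esc(e.date)}</dd>"]
    if e.protocol:
        parts.append(f"<dt>Protocol</dt><dd>{esc(e.protocol.name)}</dd>")
    for s in e.samples:
        parts.append(f"<dt>Sample</dt><dd>{esc(s.name)}"
                     f" ({esc(s.organism)})</dd>")
    parts.append("</dl>")
    items = _condition_items(e)
    if items:
        parts.append("<h2>Conditions</h2><table>")
        parts += [f"<tr><td>{esc(k)}</td><td>{esc(v)}</td></tr>"
                  for k, v in items]
        parts.append("</table>")
    if e.attachments:
        parts.append("<h2>Attachments</h2><ul>")
        parts += [f"<li>{esc(a.original_name)} [{esc(a.kind)}]"
                  f" {a.byte_size} B <code>{a.checksum}</code></li>"
                  for a in e.attachments]
        parts.append("</ul>")
    idents = _ident_rows(store, e.id)
    if idents:
        parts.append("<h2>Identifications</h2><ul>")
        parts += [f"<li>{esc(r['engine'])}: {esc(r['accession'])}"
                  f" ({esc(r['description'])}) score={r['score']:.2f}</li>"
                  for r in idents]
        parts.append("</ul>")
    parts.append("<h2>Experiment tree</h2>")
    for tree in _trees(store, e.id):
        parts.append(f"<pre>{esc(tree.to_text())}</pre>")
    parts.append("</body></html>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# XML export / import

def export_record(store, exp_id: int, include_tree: bool = False) -> bytes:
    """Stable XML export of one experiment: every populated MIAPE field,
    conditions, notes and the attachments' checksums.

    Store-local identifiers (internal id, project, file ids/paths) are
    deliberately excluded so export → import → export is byte-identical.
    """
    e = store.get_experiment(exp_id)
    root = etree.Element("experimentRecord", type=e.type)
    etree.SubElement(root, "title").text = e.title
    etree.SubElement(root, "performedBy").text = e.performed_by
    etree.SubElement(root, "date").text = e.date
    if e.notes:
        etree.SubElement(root, "notes").text = e.notes
    if e.protocol:
        protocol = etree.SubElement(root, "protocol")
        etree.SubElement(protocol, "name").text = e.protocol.name
        if e.protocol.body:
            etree.SubElement(protocol, "body").text = e.protocol.body
        if e.protocol.applies_to:
            etree.SubElement(protocol, "appliesTo").text = e.protocol.applies_to
    if e.samples:
        samples = etree.SubElement(root, "samples")
        for s in e.samples:
            sample = etree.SubElement(samples, "sample")
            etree.SubElement(sample, "name").text = s.name
            if s.organism:
                etree.SubElement(sample, "organism").text = s.organism
            if s.description:
                etree.SubElement(sample, "description").text = s.description
    items = _condition_items(e)
    if items:
        conditions = etree.SubElement(root, "conditions",
                                      variant=type(e.conditions).__name__)
        for key, value in items:
            etree.SubElement(conditions, key).text = value
    if e.attachments:
        attachments = etree.SubElement(root, "attachments")
        for a in e.attachments:
            etree.SubElement(attachments, "attachment", name=a.original_name,
                             kind=a.kind, byteSize=str(a.byte_size),
                             sha256=a.checksum)
    if include_tree:
        trees = etree.SubElement(root, "experimentTree")
        for tree in _trees(store, e.id):
            trees.append(_tree_xml(tree))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _tree_xml(node: tracking.ExperimentTreeNode) -> etree._Element:
    elem = etree.Element("node", id=str(node.id), type=node.type,
                         title=node.title)
    for child in node.children:
        elem.append(_tree_xml(child))
    return elem


def import_record(store, xml: bytes, project_id: int,
                  files_from=None, actor: str | None = None) -> Experiment:
    """Create a new experiment from an exported record.

    Attachment bytes are recovered by checksum from ``files_from`` (a
    directory tree, defaulting to this store's own file root); attachments
    whose bytes cannot be found are skipped with a warning.
    """
    import warnings
    from pathlib import Path

    from .models import (GelConditions, LCConditions, MSConditions,
                         conditions_from_json)

    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"not a well-formed record: {exc}")
    if root.tag != "experimentRecord":
        raise ValidationError(f"unexpected root element {root.tag!r}")

    def text(parent, tag, default=""):
        elem = parent.find(tag)
        return elem.text or default if elem is not None else default

    exp_type = root.get("type")
    protocol_id = None
    protocol_elem = root.find("protocol")
    if protocol_elem is not None:
        protocol_id = store.create_protocol(
            text(protocol_elem, "name"), text(protocol_elem, "body"),
            text(protocol_elem, "appliesTo")).protocol_id
    sample_ids = []
    for sample_elem in root.findall("samples/sample"):
        sample_ids.append(store.create_sample(
            text(sample_elem, "name"), text(sample_elem, "organism"),
            text(sample_elem, "description")).sample_id)
    conditions = None
    cond_elem = root.find("conditions")
    if cond_elem is not None:
        variant = cond_elem.get("variant")
        cls = {"LCConditions": LCConditions, "GelConditions": GelConditions,
               "MSConditions": MSConditions}.get(variant)
        if cls is None:
            raise ValidationError(f"unknown conditions variant {variant!r}")
        values = {}
        numeric = {f.name for f in _dataclass_fields(cls)
                   if f.type in ("float | None",)}
        for child in cond_elem:
            value = child.text or ""
            try:
                values[child.tag] = float(value) if child.tag in numeric \
                    else value
            except ValueError:
                values[child.tag] = value
        conditions = cls(**values)
    experiment = store.create_experiment(
        project_id, exp_type, text(root, "title"), text(root, "performedBy"),
        text(root, "date"), conditions=conditions, samples=sample_ids,
        protocol_id=protocol_id, notes=text(root, "notes"), actor=actor)
    by_checksum = {}
    source_root = Path(files_from) if files_from is not None \
        else store.files_root
    for attachment in root.findall("attachments/attachment"):
        want = attachment.get("sha256")
        if not by_checksum:
            from .store import sha256_hex
            for path in sorted(source_root.rglob("*")):
                if path.is_file():
                    by_checksum.setdefault(sha256_hex(path.read_bytes()), path)
        path = by_checksum.get(want)
        if path is None:
            warnings.warn(f"attachment {attachment.get('name')!r}"
                          f" (sha256 {want}) not found; skipped")
            continue
        store.attach_bytes(experiment.id, path.read_bytes(),
                           attachment.get("name"), attachment.get("kind"),
                           actor=actor)
    return store.get_experiment(experiment.id)
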