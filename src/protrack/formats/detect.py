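"""Best-effort detection of the supported instrument-export formats.

XML dialects are distinguished by their root element; text dialects by
cheap signatures (``BEGIN IONS`` for MGF, header columns for the tabular
formats, bare numeric columns for pkl).  ``unknown`` is a value, never an
error.
"""

from __future__ import annotations

from lxml import etree


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


_XML_ROOTS = {"mzml": "mzml", "indexedmzml": "mzml", "mzxml": "mzxml",
              "mzdata": "mzdata"}


def detect_format(content: bytes | str) -> str:
    """Return one of pkl / mzxml / mzdata / mzml / mgf / spot_table /
    lc_table / unknown."""
    if isinstance(content, str):
        data = content.encode("utf-8", errors="replace")
        text = content
    else:
        data = content
        text = content.decode("utf-8", errors="replace")
    stripped = text.lstrip()
    if not stripped:
        return "unknown"

    if stripped.startswith("<"):
        try:
            root = etree.fromstring(data)
        except etree.XMLSyntaxError:
            return "unknown"
        local = etree.QName(root.tag).localname.lower() \
            if isinstance(root.tag, str) else ""
        return _XML_ROOTS.get(local, "unknown")

    lines = [ln for ln in text.splitlines() if ln.strip()]
    head = lines[: 50]
    if any(ln.strip() == "BEGIN IONS" for ln in head):
        return "mgf"

    first = lines[0]
    if "\t" in first:
        columns = {c.strip().lower() for c in first.split("\t")}
        if {"spot", "x", "y"} <= columns:
            return "spot_table"
    if "," in first:
        columns = {c.strip().lower() for c in first.split(",")}
        if {"peak", "retentiontime"} <= columns:
            return "lc_table"

    tokens = first.split()
    if len(tokens) in (2, 3) and all(_is_number(t) for t in tokens):
        return "pkl"
    return "unknown"
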