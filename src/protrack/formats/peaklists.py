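"""Mass-spectrometry peak-list dialects.

Five dialects are supported: the plain-text ``pkl`` and MGF formats and the
three XML interchange standards mzML, mzXML and mzData.  Only the peak-list
content (m/z and intensity arrays, precursor, instrument description) is
extracted — the store keeps m/z lists, not raw profile runs.  Binary arrays
must be base64-encoded uncompressed IEEE-754 floats (32- or 64-bit);
compressed arrays raise an unsupported-feature error naming the feature.

Normalization rules shared by every parser:

* peaks are sorted by m/z ascending;
* spectrum identifiers map to the canonical ``spectrum_<n>`` form in the
  dialects whose native identifier is a bare scan number (pkl, mzXML,
  mzData); MGF titles and mzML ids are carried verbatim.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field

from lxml import etree

from ..errors import FormatError, UnsupportedFeatureError

SOURCE_FORMATS = ("pkl", "mzxml", "mzdata", "mzml", "mgf")


@dataclass(frozen=True)
class Peak:
    """One centroided peak: m/z in thomson (> 0), intensity in arbitrary
    units (>= 0)."""

    mz: float
    intensity: float

    def validate(self) -> None:
        if not self.mz > 0:
            raise FormatError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise FormatError(f"negative intensity {self.intensity}")


@dataclass
class Spectrum:
    scan_id: str
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    peaks: list[Peak] = field(default_factory=list)

    def normalized(self) -> "Spectrum":
        for p in self.peaks:
            p.validate()
        return Spectrum(self.scan_id, self.precursor_mz,
                        self.precursor_charge,
                        sorted(self.peaks, key=lambda p: p.mz))


@dataclass
class MzList:
    source_format: str
    instrument_meta: dict[str, str] = field(default_factory=dict)
    spectra: list[Spectrum] = field(default_factory=list)

    def normalized(self) -> "MzList":
        return MzList(self.source_format, dict(self.instrument_meta),
                      [s.normalized() for s in self.spectra])


def spectra_equal(a: MzList, b: MzList) -> bool:
    """Content equality of two normalized lists, ignoring source dialect
    and instrument description."""
    an, bn = a.normalized(), b.normalized()
    return an.spectra == bn.spectra


# ---------------------------------------------------------------------------
# pkl — per spectrum a `precursor_mz intensity charge` header line followed
# by `mz intensity` lines, blocks separated by blank lines.

def parse_pkl(text: str) -> MzList:
    mzlist = MzList("pkl")
    block: list[tuple[int, str]] = []
    lines = text.splitlines()
    for lineno, raw in enumerate(lines + [""], start=1):
        line = raw.strip()
        if line:
            block.append((lineno, line))
            continue
        if block:
            mzlist.spectra.append(_parse_pkl_block(block, len(mzlist.spectra)))
            block = []
    return mzlist.normalized()


def _parse_pkl_block(block: list[tuple[int, str]], index: int) -> Spectrum:
    lineno, header = block[0]
    fields = header.split()
    try:
        if len(fields) != 3:
            raise ValueError
        precursor_mz, _precursor_intensity = float(fields[0]), float(fields[1])
        charge = int(float(fields[2]))
    except ValueError:
        raise FormatError(
            f"line {lineno}: pkl header must be 3 numeric fields"
            f" (precursor m/z, intensity, charge), got {header!r}")
    spectrum = Spectrum(f"spectrum_{index + 1}", precursor_mz, charge)
    for lineno, line in block[1:]:
        parts = line.split()
        try:
            if len(parts) != 2:
                raise ValueError
            spectrum.peaks.append(Peak(float(parts[0]), float(parts[1])))
        except ValueError:
            raise FormatError(
                f"line {lineno}: expected `mz intensity`, got {line!r}")
    return spectrum


def render_pkl(mzlist: MzList) -> str:
    """Emit the pkl dialect; the precursor-intensity column (not kept in the
    model) is written as 1.0."""
    blocks = []
    for s in mzlist.normalized().spectra:
        if s.precursor_mz is None:
            raise FormatError(
                f"{s.scan_id}: pkl requires a precursor for every spectrum")
        lines = [f"{s.precursor_mz:.4f} 1.0 {s.precursor_charge or 1}"]
        lines += [f"{p.mz:.4f} {p.intensity:.1f}" for p in s.peaks]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# MGF — BEGIN IONS / END IONS blocks.

def parse_mgf(text: str) -> MzList:
    mzlist = MzList("mgf")
    spectrum: Spectrum | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if spectrum is not None:
                raise FormatError(f"line {lineno}: nested BEGIN IONS")
            spectrum = Spectrum(f"spectrum_{len(mzlist.spectra) + 1}")
            continue
        if line == "END IONS":
            if spectrum is None:
                raise FormatError(f"line {lineno}: END IONS outside a block")
            mzlist.spectra.append(spectrum)
            spectrum = None
            continue
        if "=" in line and not line[0].isdigit():
            key, value = line.split("=", 1)
            if spectrum is None:
                mzlist.instrument_meta[key] = value
            elif key == "TITLE":
                spectrum.scan_id = value
            elif key == "PEPMASS":
                spectrum.precursor_mz = float(value.split()[0])
            elif key == "CHARGE":
                spectrum.precursor_charge = _parse_charge(value)
            else:
                mzlist.instrument_meta[key] = value
            continue
        if spectrum is None:
            raise FormatError(f"line {lineno}: peak line outside BEGIN IONS")
        parts = line.split()
        try:
            if len(parts) < 2:
                raise ValueError
            spectrum.peaks.append(Peak(float(parts[0]), float(parts[1])))
        except ValueError:
            raise FormatError(
                f"line {lineno}: expected `mz intensity`, got {line!r}")
    if spectrum is not None:
        raise FormatError("unterminated BEGIN IONS block at end of file")
    return mzlist.normalized()


def _parse_charge(value: str) -> int:
    value = value.strip()
    sign = -1 if value.endswith("-") or value.startswith("-") else 1
    return sign * int(value.strip("+-"))


def write_mgf(mzlist: MzList) -> str:
    """Bit-exact MGF writer: m/z with 4 decimal places, intensity with 1;
    spectra without a precursor get no PEPMASS line."""
    out = []
    for key in sorted(mzlist.instrument_meta):
        out.append(f"{key}={mzlist.instrument_meta[key]}")
    if mzlist.instrument_meta:
        out.append("")
    for s in mzlist.normalized().spectra:
        out.append("BEGIN IONS")
        out.append(f"TITLE={s.scan_id}")
        if s.precursor_mz is not None:
            out.append(f"PEPMASS={s.precursor_mz:.4f}")
        if s.precursor_charge is not None:
            sign = "-" if s.precursor_charge < 0 else "+"
            out.append(f"CHARGE={abs(s.precursor_charge)}{sign}")
        for p in s.peaks:
            out.append(f"{p.mz:.4f} {p.intensity:.1f}")
        out.append("END IONS")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# binary array helpers (shared by the XML dialects)

_STRUCT_CODE = {32: "f", 64: "d"}


def _encode_array(values: list[float], precision: int, byte_order: str) -> str:
    prefix = ">" if byte_order == "big" else "<"
    packed = struct.pack(f"{prefix}{len(values)}{_STRUCT_CODE[precision]}",
                         *values)
    return base64.b64encode(packed).decode("ascii")


def _decode_array(b64: str, precision: int, byte_order: str) -> list[float]:
    try:
        raw = base64.b64decode(b64.strip().encode("ascii"), validate=True)
    except Exception as exc:
        raise FormatError(f"invalid base64 binary data: {exc}")
    code = _STRUCT_CODE[precision]
    width = precision // 8
    if len(raw) % width:
        raise FormatError(
            f"binary array length {len(raw)} not a multiple of {width} bytes")
    prefix = ">" if byte_order == "big" else "<"
    return list(struct.unpack(f"{prefix}{len(raw) // width}{code}", raw))


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _parse_xml(data: bytes | str) -> etree._Element:
    if isinstance(data, str):
        data = data.encode()
    try:
        return etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not well-formed XML: {exc}")


def _findall(elem, localname: str) -> list:
    return [e for e in elem.iter() if _local(e.tag) == localname]


# ---------------------------------------------------------------------------
# mzML — separate little-endian m/z and intensity arrays.

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def parse_mzml(data: bytes | str) -> MzList:
    root = _parse_xml(data)
    if _local(root.tag) == "indexedmzML":
        inner = _findall(root, "mzML")
        if not inner:
            raise FormatError("indexedmzML wrapper without an mzML element")
        root = inner[0]
    if _local(root.tag) != "mzML":
        raise FormatError(f"root element {_local(root.tag)!r} is not mzML")
    mzlist = MzList("mzml")
    for ic in _findall(root, "instrumentConfiguration"):
        for p in ic:
            if _local(p.tag) in ("cvParam", "userParam"):
                name = p.get("name")
                if name:
                    mzlist.instrument_meta[name] = p.get("value", "")
    for spec_elem in _findall(root, "spectrum"):
        scan_id = spec_elem.get("id") or f"spectrum_{len(mzlist.spectra) + 1}"
        spectrum = Spectrum(scan_id)
        for ion in _findall(spec_elem, "selectedIon"):
            for p in ion:
                if _local(p.tag) != "cvParam":
                    continue
                if p.get("accession") == "MS:1000744" or \
                        p.get("name") == "selected ion m/z":
                    spectrum.precursor_mz = float(p.get("value"))
                if p.get("accession") == "MS:1000041" or \
                        p.get("name") == "charge state":
                    spectrum.precursor_charge = int(p.get("value"))
        mz_vals = inten_vals = None
        for array in _findall(spec_elem, "binaryDataArray"):
            precision, kind = 64, None
            for p in array:
                if _local(p.tag) != "cvParam":
                    continue
                name = p.get("name", "")
                if "compression" in name and name != "no compression":
                    raise UnsupportedFeatureError(
                        f"unsupported binary-array feature: {name}")
                if name == "32-bit float":
                    precision = 32
                elif name == "64-bit float":
                    precision = 64
                elif name in ("m/z array", "intensity array"):
                    kind = name
            binaries = _findall(array, "binary")
            text = binaries[0].text or "" if binaries else ""
            values = _decode_array(text, precision, "little")
            if kind == "m/z array":
                mz_vals = values
            elif kind == "intensity array":
                inten_vals = values
        mz_vals = mz_vals if mz_vals is not None else []
        inten_vals = inten_vals if inten_vals is not None else []
        if len(mz_vals) != len(inten_vals):
            raise FormatError(
                f"{scan_id}: m/z array has {len(mz_vals)} values but"
                f" intensity array has {len(inten_vals)}")
        spectrum.peaks = [Peak(m, i) for m, i in zip(mz_vals, inten_vals)]
        mzlist.spectra.append(spectrum)
    return mzlist.normalized()


def render_mzml(mzlist: MzList, precision: int = 64) -> bytes:
    nsmap = {None: _MZML_NS}
    root = etree.Element(f"{{{_MZML_NS}}}mzML", nsmap=nsmap, version="1.1.0")
    norm = mzlist.normalized()
    if norm.instrument_meta:
        icl = etree.SubElement(root, f"{{{_MZML_NS}}}instrumentConfigurationList",
                               count="1")
        ic = etree.SubElement(icl, f"{{{_MZML_NS}}}instrumentConfiguration",
                              id="IC1")
        for key in sorted(norm.instrument_meta):
            etree.SubElement(ic, f"{{{_MZML_NS}}}userParam", name=key,
                             value=norm.instrument_meta[key])
    run = etree.SubElement(root, f"{{{_MZML_NS}}}run", id="run1")
    slist = etree.SubElement(run, f"{{{_MZML_NS}}}spectrumList",
                             count=str(len(norm.spectra)))
    for index, s in enumerate(norm.spectra):
        spec = etree.SubElement(slist, f"{{{_MZML_NS}}}spectrum",
                                index=str(index), id=s.scan_id,
                                defaultArrayLength=str(len(s.peaks)))
        if s.precursor_mz is not None or s.precursor_charge is not None:
            plist = etree.SubElement(spec, f"{{{_MZML_NS}}}precursorList",
                                     count="1")
            prec = etree.SubElement(plist, f"{{{_MZML_NS}}}precursor")
            ilist = etree.SubElement(prec, f"{{{_MZML_NS}}}selectedIonList",
                                     count="1")
            ion = etree.SubElement(ilist, f"{{{_MZML_NS}}}selectedIon")
            if s.precursor_mz is not None:
                etree.SubElement(ion, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                                 accession="MS:1000744",
                                 name="selected ion m/z",
                                 value=repr(s.precursor_mz))
            if s.precursor_charge is not None:
                etree.SubElement(ion, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                                 accession="MS:1000041", name="charge state",
                                 value=str(s.precursor_charge))
        alist = etree.SubElement(spec, f"{{{_MZML_NS}}}binaryDataArrayList",
                                 count="2")
        arrays = ((("MS:1000514", "m/z array"), [p.mz for p in s.peaks]),
                  (("MS:1000515", "intensity array"),
                   [p.intensity for p in s.peaks]))
        prec_cv = ("MS:1000523", "64-bit float") if precision == 64 else \
            ("MS:1000521", "32-bit float")
        for (acc, name), values in arrays:
            encoded = _encode_array(values, precision, "little")
            arr = etree.SubElement(alist, f"{{{_MZML_NS}}}binaryDataArray",
                                   encodedLength=str(len(encoded)))
            etree.SubElement(arr, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                             accession=prec_cv[0], name=prec_cv[1])
            etree.SubElement(arr, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                             accession="MS:1000576", name="no compression")
            etree.SubElement(arr, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                             accession=acc, name=name)
            etree.SubElement(arr, f"{{{_MZML_NS}}}binary").text = encoded
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---------------------------------------------------------------------------
# mzXML — interleaved m/z–intensity pairs in network (big-endian) byte order.

_MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


def parse_mzxml(data: bytes | str) -> MzList:
    root = _parse_xml(data)
    if _local(root.tag) != "mzXML":
        raise FormatError(f"root element {_local(root.tag)!r} is not mzXML")
    mzlist = MzList("mzxml")
    for instrument in _findall(root, "msInstrument"):
        for child in instrument:
            name = _local(child.tag)
            if name == "nameValue":
                mzlist.instrument_meta[child.get("name", "")] = \
                    child.get("value", "")
            elif child.get("value") is not None:
                mzlist.instrument_meta[name] = child.get("value")
    for scan in _findall(root, "scan"):
        num = scan.get("num") or str(len(mzlist.spectra) + 1)
        spectrum = Spectrum(f"spectrum_{num}")
        for prec in scan:
            if _local(prec.tag) != "precursorMz":
                continue
            if prec.text and prec.text.strip():
                spectrum.precursor_mz = float(prec.text.strip())
            if prec.get("precursorCharge"):
                spectrum.precursor_charge = int(prec.get("precursorCharge"))
        for peaks_elem in scan:
            if _local(peaks_elem.tag) != "peaks":
                continue
            compression = peaks_elem.get("compressionType", "none")
            if compression not in ("none", ""):
                raise UnsupportedFeatureError(
                    f"unsupported binary-array feature:"
                    f" {compression} compression")
            byte_order = peaks_elem.get("byteOrder", "network")
            if byte_order != "network":
                raise UnsupportedFeatureError(
                    f"unsupported byte order {byte_order!r}")
            precision = int(peaks_elem.get("precision", "32"))
            values = _decode_array(peaks_elem.text or "", precision, "big")
            if len(values) % 2:
                raise FormatError(
                    f"scan {num}: interleaved peak array has odd length"
                    f" {len(values)}")
            spectrum.peaks = [Peak(values[i], values[i + 1])
                              for i in range(0, len(values), 2)]
        mzlist.spectra.append(spectrum)
    return mzlist.normalized()


def render_mzxml(mzlist: MzList, precision: int = 64) -> bytes:
    nsmap = {None: _MZXML_NS}
    root = etree.Element(f"{{{_MZXML_NS}}}mzXML", nsmap=nsmap)
    norm = mzlist.normalized()
    run = etree.SubElement(root, f"{{{_MZXML_NS}}}msRun",
                           scanCount=str(len(norm.spectra)))
    if norm.instrument_meta:
        instrument = etree.SubElement(run, f"{{{_MZXML_NS}}}msInstrument")
        for key in sorted(norm.instrument_meta):
            etree.SubElement(instrument, f"{{{_MZXML_NS}}}nameValue",
                             name=key, value=norm.instrument_meta[key])
    for index, s in enumerate(norm.spectra, start=1):
        scan = etree.SubElement(run, f"{{{_MZXML_NS}}}scan", num=str(index),
                                msLevel="2", peaksCount=str(len(s.peaks)))
        if s.precursor_mz is not None:
            attrs = {}
            if s.precursor_charge is not None:
                attrs["precursorCharge"] = str(s.precursor_charge)
            prec = etree.SubElement(scan, f"{{{_MZXML_NS}}}precursorMz",
                                    **attrs)
            prec.text = repr(s.precursor_mz)
        interleaved: list[float] = []
        for p in s.peaks:
            interleaved += [p.mz, p.intensity]
        peaks = etree.SubElement(scan, f"{{{_MZXML_NS}}}peaks",
                                 precision=str(precision),
                                 byteOrder="network", contentType="m/z-int",
                                 compressionType="none")
        peaks.text = _encode_array(interleaved, precision, "big")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---------------------------------------------------------------------------
# mzData — separate arrays with explicit endianness attributes.

def parse_mzdata(data: bytes | str) -> MzList:
    root = _parse_xml(data)
    if _local(root.tag) != "mzData":
        raise FormatError(f"root element {_local(root.tag)!r} is not mzData")
    mzlist = MzList("mzdata")
    for instrument in _findall(root, "instrument"):
        for p in instrument.iter():
            if _local(p.tag) in ("cvParam", "userParam") and p.get("name"):
                mzlist.instrument_meta[p.get("name")] = p.get("value", "")
    for spec_elem in _findall(root, "spectrum"):
        sid = spec_elem.get("id") or str(len(mzlist.spectra) + 1)
        spectrum = Spectrum(f"spectrum_{sid}")
        for ion in _findall(spec_elem, "ionSelection"):
            for p in ion:
                if _local(p.tag) != "cvParam":
                    continue
                name = p.get("name", "")
                if name in ("MassToChargeRatio", "mz", "m/z"):
                    spectrum.precursor_mz = float(p.get("value"))
                elif name == "ChargeState":
                    spectrum.precursor_charge = int(p.get("value"))
        mz_vals = _read_mzdata_array(spec_elem, "mzArrayBinary", sid)
        inten_vals = _read_mzdata_array(spec_elem, "intenArrayBinary", sid)
        if len(mz_vals) != len(inten_vals):
            raise FormatError(
                f"spectrum {sid}: m/z array has {len(mz_vals)} values but"
                f" intensity array has {len(inten_vals)}")
        spectrum.peaks = [Peak(m, i) for m, i in zip(mz_vals, inten_vals)]
        mzlist.spectra.append(spectrum)
    return mzlist.normalized()


def _read_mzdata_array(spec_elem, container: str, sid: str) -> list[float]:
    containers = _findall(spec_elem, container)
    if not containers:
        return []
    datas = _findall(containers[0], "data")
    if not datas:
        return []
    data_elem = datas[0]
    precision = int(data_elem.get("precision", "64"))
    endian = data_elem.get("endian", "little")
    if endian not in ("little", "big"):
        raise UnsupportedFeatureError(f"unsupported endianness {endian!r}")
    values = _decode_array(data_elem.text or "", precision, endian)
    declared = data_elem.get("length")
    if declared is not None and int(declared) != len(values):
        raise FormatError(
            f"spectrum {sid}: {container} declares length {declared} but"
            f" holds {len(values)} values")
    return values


def render_mzdata(mzlist: MzList, precision: int = 64) -> bytes:
    root = etree.Element("mzData", version="1.05")
    norm = mzlist.normalized()
    if norm.instrument_meta:
        desc = etree.SubElement(root, "description")
        instrument = etree.SubElement(desc, "instrument")
        additional = etree.SubElement(instrument, "additional")
        for key in sorted(norm.instrument_meta):
            etree.SubElement(additional, "userParam", name=key,
                             value=norm.instrument_meta[key])
    slist = etree.SubElement(root, "spectrumList",
                             count=str(len(norm.spectra)))
    for index, s in enumerate(norm.spectra, start=1):
        spec = etree.SubElement(slist, "spectrum", id=str(index))
        sdesc = etree.SubElement(spec, "spectrumDesc")
        if s.precursor_mz is not None or s.precursor_charge is not None:
            plist = etree.SubElement(sdesc, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor", msLevel="2",
                                    spectrumRef="0")
            ion = etree.SubElement(prec, "ionSelection")
            if s.precursor_mz is not None:
                etree.SubElement(ion, "cvParam", cvLabel="psi",
                                 accession="PSI:1000040",
                                 name="MassToChargeRatio",
                                 value=repr(s.precursor_mz))
            if s.precursor_charge is not None:
                etree.SubElement(ion, "cvParam", cvLabel="psi",
                                 accession="PSI:1000041", name="ChargeState",
                                 value=str(s.precursor_charge))
        for container, values in (
                ("mzArrayBinary", [p.mz for p in s.peaks]),
                ("intenArrayBinary", [p.intensity for p in s.peaks])):
            holder = etree.SubElement(spec, container)
            data_elem = etree.SubElement(holder, "data",
                                         precision=str(precision),
                                         endian="little",
                                         length=str(len(values)))
            data_elem.text = _encode_array(values, precision, "little")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
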