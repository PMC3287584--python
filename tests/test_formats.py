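"""Instrument-file dialects: detection, parsing, rendering, round trips."""

import base64
import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protrack import FormatError, UnsupportedFeatureError, synth
from protrack.formats import (MzList, Peak, Spectrum, detect_format,
                              parse_ident_table, parse_lc_peak_table,
                              parse_mgf, parse_mzdata, parse_mzml,
                              parse_mzxml, parse_pkl, parse_spot_table,
                              render_mzdata, render_mzml, render_mzxml,
                              render_pkl, write_mgf)

RENDERERS = {"pkl": lambda m: render_pkl(m).encode(),
             "mgf": lambda m: write_mgf(m).encode(),
             "mzml": render_mzml, "mzxml": render_mzxml,
             "mzdata": render_mzdata}
PARSERS = {"pkl": lambda b: parse_pkl(b.decode()),
           "mgf": lambda b: parse_mgf(b.decode()),
           "mzml": parse_mzml, "mzxml": parse_mzxml, "mzdata": parse_mzdata}


class TestDetect:
    @pytest.mark.parametrize("fmt", list(RENDERERS))
    def test_generated_files_detected_as_their_format(self, fmt):
        data = RENDERERS[fmt](synth.synth_spectra(2, 4, 1))
        assert detect_format(data) == fmt

    def test_signatures(self):
        assert detect_format(b"BEGIN IONS\nEND IONS\n") == "mgf"
        assert detect_format(synth.synth_spot_table(3, 1)[0]) == "spot_table"
        assert detect_format(synth.synth_lc_table(3, 1)[0]) == "lc_table"
        assert detect_format(b"") == "unknown"
        assert detect_format(b"just prose, no structure") == "unknown"
        assert detect_format(b"<notAPeakList/>") == "unknown"


class TestPkl:
    def test_single_block_transcription(self):
        text = "500.25 10000 2\n100.1 50\n200.2 75\n"
        mzlist = parse_pkl(text)
        (s,) = mzlist.spectra
        assert (s.precursor_mz, s.precursor_charge) == (500.25, 2)
        assert s.peaks == [Peak(100.1, 50.0), Peak(200.2, 75.0)]

    def test_empty_text_is_zero_spectra(self):
        assert parse_pkl("") == MzList("pkl")

    def test_malformed_header_reports_error(self):
        with pytest.raises(FormatError, match="3 numeric fields"):
            parse_pkl("500.25 10000\n100.1 50\n")

    def test_bad_peak_line_reports_line_number(self):
        with pytest.raises(FormatError, match="line 3"):
            parse_pkl("500.25 1 2\n100.1 50\noops nope\n")


class TestMgf:
    def test_round_trip_is_identity(self):
        truth = synth.synth_spectra(4, 7, 11)
        parsed = parse_mgf(write_mgf(truth))
        assert parsed.spectra == truth.normalized().spectra
        assert parsed.instrument_meta == truth.instrument_meta

    def test_spectrum_without_precursor_has_no_pepmass(self):
        mzlist = MzList("mgf", spectra=[Spectrum("s1", peaks=[Peak(100.0, 1.0)])])
        text = write_mgf(mzlist)
        assert "PEPMASS" not in text
        assert parse_mgf(text).spectra[0].precursor_mz is None

    def test_unterminated_block_rejected(self):
        with pytest.raises(FormatError, match="unterminated"):
            parse_mgf("BEGIN IONS\nTITLE=x\n100.0 1.0\n")

    def test_unknown_headers_preserved_in_instrument_meta(self):
        parsed = parse_mgf("BEGIN IONS\nTITLE=t\nSCANS=14\nEND IONS\n")
        assert parsed.instrument_meta["SCANS"] == "14"

    def test_agrees_with_pyteomics_reader(self):
        from pyteomics import mgf as pmgf
        truth = synth.synth_spectra(3, 6, 42)
        oracle = list(pmgf.read(io.StringIO(write_mgf(truth)),
                                use_index=False))
        assert len(oracle) == 3
        for mine, theirs in zip(truth.spectra, oracle):
            assert theirs["params"]["title"] == mine.scan_id
            assert theirs["params"]["pepmass"][0] == mine.precursor_mz
            assert list(theirs["m/z array"]) == [p.mz for p in mine.peaks]
            assert list(theirs["intensity array"]) == \
                [p.intensity for p in mine.peaks]

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(0, 5), k=st.integers(0, 8),
           seed=st.integers(0, 10_000))
    def test_round_trip_preserves_every_mz(self, n, k, seed):
        truth = synth.synth_spectra(n, k, seed)
        parsed = parse_mgf(write_mgf(truth))
        for a, b in zip(parsed.spectra, truth.spectra):
            assert [p.mz for p in a.peaks] == [p.mz for p in b.peaks]


class TestXmlDialects:
    def test_mzml_arrays_from_independent_encoder(self):
        """Arrays encoded with numpy's own IEEE-754/base64 path decode to
        the stated peaks."""
        mz_b64 = base64.b64encode(
            np.array([100.0, 200.0], "<f8").tobytes()).decode()
        inten_b64 = base64.b64encode(
            np.array([10.0, 20.0], "<f8").tobytes()).decode()
        xml = f"""<?xml version="1.0"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml">
 <run id="r"><spectrumList count="1">
  <spectrum index="0" id="scan=1" defaultArrayLength="2">
   <binaryDataArrayList count="2">
    <binaryDataArray><cvParam accession="MS:1000523" name="64-bit float"/>
     <cvParam accession="MS:1000576" name="no compression"/>
     <cvParam accession="MS:1000514" name="m/z array"/>
     <binary>{mz_b64}</binary></binaryDataArray>
    <binaryDataArray><cvParam accession="MS:1000523" name="64-bit float"/>
     <cvParam accession="MS:1000576" name="no compression"/>
     <cvParam accession="MS:1000515" name="intensity array"/>
     <binary>{inten_b64}</binary></binaryDataArray>
   </binaryDataArrayList>
  </spectrum>
 </spectrumList></run></mzML>"""
        (s,) = parse_mzml(xml).spectra
        assert s.peaks == [Peak(100.0, 10.0), Peak(200.0, 20.0)]

    @pytest.mark.parametrize("fmt", ["mzml", "mzxml", "mzdata"])
    def test_rendered_binary_decodes_with_numpy(self, fmt):
        from lxml import etree
        truth = synth.synth_spectra(1, 5, 21)
        doc = etree.fromstring(RENDERERS[fmt](truth))
        b64 = {"mzml": ".//{*}binary", "mzxml": ".//{*}peaks",
               "mzdata": ".//{*}data"}[fmt]
        first = doc.findall(b64)[0]
        raw = base64.b64decode(first.text)
        dtype = {"mzml": "<f8", "mzxml": ">f8", "mzdata": "<f8"}[fmt]
        values = np.frombuffer(raw, dtype=dtype)
        expected = [p.mz for p in truth.spectra[0].peaks]
        if fmt == "mzxml":  # interleaved m/z-intensity pairs
            assert list(values[0::2]) == expected
        else:
            assert list(values) == expected

    def test_empty_arrays_give_zero_peaks(self):
        empty = MzList("mzml", spectra=[Spectrum("s1")])
        for fmt in ("mzml", "mzxml", "mzdata"):
            parsed = PARSERS[fmt](RENDERERS[fmt](empty))
            assert parsed.spectra[0].peaks == []

    def test_compressed_arrays_raise_naming_the_feature(self):
        data = render_mzml(synth.synth_spectra(1, 3, 5)).decode()
        zml = data.replace("no compression", "zlib compression")
        with pytest.raises(UnsupportedFeatureError, match="zlib"):
            parse_mzml(zml)
        xdata = render_mzxml(synth.synth_spectra(1, 3, 5)).decode()
        zx = xdata.replace('compressionType="none"', 'compressionType="zlib"')
        with pytest.raises(UnsupportedFeatureError, match="zlib"):
            parse_mzxml(zx)

    def test_array_length_mismatch_rejected(self):
        truth = synth.synth_spectra(1, 4, 9)
        doc = render_mzml(truth).decode()
        short = base64.b64encode(
            np.array([1.0], "<f8").tobytes()).decode()
        # replace the intensity array (the second <binary>) with one value
        head, _, tail = doc.rpartition("<binary>")
        broken = (head + "<binary>" + short + "</binary>"
                  + tail.partition("</binary>")[2])
        with pytest.raises(FormatError, match="intensity array has 1"):
            parse_mzml(broken)

    def test_mzxml_odd_interleaved_length_rejected(self):
        odd = base64.b64encode(np.array([1.0, 2.0, 3.0], ">f8").tobytes())
        xml = (b'<mzXML><msRun scanCount="1"><scan num="1" peaksCount="1">'
               b'<peaks precision="64" byteOrder="network">'
               + odd + b'</peaks></scan></msRun></mzXML>')
        with pytest.raises(FormatError, match="odd length"):
            parse_mzxml(xml)

    @pytest.mark.parametrize("fmt", ["mzml", "mzxml", "mzdata"])
    def test_float32_arrays_round_to_float32(self, fmt):
        truth = synth.synth_spectra(2, 5, 33)
        render = {"mzml": render_mzml, "mzxml": render_mzxml,
                  "mzdata": render_mzdata}[fmt]
        parsed = PARSERS[fmt](render(truth, precision=32))
        for a, b in zip(parsed.spectra, truth.spectra):
            assert [p.mz for p in a.peaks] == \
                [float(np.float32(p.mz)) for p in b.peaks]


class TestCrossFormat:
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_all_dialects_normalize_identically(self, seed):
        truth = synth.synth_spectra(3, 6, seed)
        parsed = {fmt: PARSERS[fmt](RENDERERS[fmt](truth))
                  for fmt in RENDERERS}
        for fmt, mzlist in parsed.items():
            assert mzlist.source_format == fmt
            assert mzlist.spectra == truth.spectra, fmt

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(0, 4), k=st.integers(0, 6),
           seed=st.integers(0, 10_000),
           fmt=st.sampled_from(sorted(RENDERERS)))
    def test_parsers_total_over_generator_output(self, n, k, seed, fmt):
        parsed = PARSERS[fmt](RENDERERS[fmt](synth.synth_spectra(n, k, seed)))
        assert len(parsed.spectra) == n
        for s in parsed.spectra:
            mzs = [p.mz for p in s.peaks]
            assert mzs == sorted(mzs)


class TestSpotTable:
    def test_two_row_transcription(self):
        text = ("Spot\tX\tY\tIntensity\tVolume\tArea\t%Vol\tpI\tMW\n"
                "S1\t10\t20\t5000\t1.5e5\t120\t40.0\t5.2\t66.4\n"
                "S2\t30\t40\t2500\t7.5e4\t80\t20.0\t6.1\t45.0\n")
        records = parse_spot_table(text)
        assert [r.spot_id for r in records] == ["S1", "S2"]
        assert records[0].volume == 1.5e5
        assert records[1].pi == 6.1

    def test_header_only_is_empty(self):
        assert parse_spot_table("Spot\tX\tY\tIntensity\tVolume\tArea\n") == []

    def test_missing_required_column_named(self):
        with pytest.raises(FormatError, match="'volume'"):
            parse_spot_table("Spot\tX\tY\tIntensity\tArea\nS1\t1\t2\t3\t4\n")

    def test_non_numeric_cell_reports_row_and_column(self):
        text = "Spot\tX\tY\tIntensity\tVolume\tArea\nS1\t1\tbad\t3\t4\t5\n"
        with pytest.raises(FormatError, match="row 2.*'y'"):
            parse_spot_table(text)

    def test_generator_round_trip(self):
        text, truth = synth.synth_spot_table(50, 3)
        assert parse_spot_table(text) == truth


class TestLcTable:
    def test_rows_sorted_by_retention_time(self):
        text = "Peak,RetentionTime,Height,Area\n1,12.4,5,50\n2,3.1,7,70\n"
        assert [r.retention_time for r in parse_lc_peak_table(text)] == \
            [3.1, 12.4]

    def test_header_only_is_empty(self):
        assert parse_lc_peak_table("Peak,RetentionTime,Height,Area\n") == []

    def test_negative_retention_time_rejected(self):
        with pytest.raises(Exception, match="negative retention"):
            parse_lc_peak_table(
                "Peak,RetentionTime,Height,Area\n1,-2.0,5,50\n")

    def test_missing_column_rejected(self):
        with pytest.raises(FormatError, match="'area'"):
            parse_lc_peak_table("Peak,RetentionTime,Height\n1,2,3\n")

    def test_generator_round_trip(self):
        text, truth = synth.synth_lc_table(20, 5)
        assert parse_lc_peak_table(text) == truth


class TestIdentTables:
    def test_mascot_score_passes_through(self):
        text = "pep_query,prot_acc,prot_desc,pep_score\n1,P08237,PFK,45.2\n"
        (r,) = parse_ident_table(text, "mascot")
        assert r.score == 45.2
        assert r.accession == "P08237"

    def test_xtandem_expectation_becomes_neg_log10(self):
        text = "id,label,description,expect\n7,P02768,albumin,0.001\n"
        (r,) = parse_ident_table(text, "xtandem")
        assert r.score == pytest.approx(3.0)

    def test_omssa_evalue_becomes_neg_log10(self):
        text = "Spectrum number,Accession,Defline,E-value\n3,Q15149,plectin,0.01\n"
        (r,) = parse_ident_table(text, "omssa")
        assert r.score == pytest.approx(2.0)

    def test_unknown_engine_rejected(self):
        with pytest.raises(Exception, match="unknown identification engine"):
            parse_ident_table("a,b\n", "sequest")

    def test_missing_mapped_column_rejected(self):
        with pytest.raises(FormatError, match="pep_score"):
            parse_ident_table("pep_query,prot_acc,prot_desc\n1,A,d\n",
                              "mascot")

    @pytest.mark.parametrize("engine", ["mascot", "xtandem", "omssa"])
    def test_generator_round_trip(self, engine):
        text, truth = synth.synth_ident_table(engine, 10, 4)
        assert parse_ident_table(text, engine) == truth
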