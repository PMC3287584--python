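"""Deterministic fixture generators.

Every input dialect the store ingests can be generated synthetically with
its ground truth retained, so parser tests are exact round-trip oracles.
A single integer seed drives a named pseudorandom stream per generator
(``Random(f"{name}:{seed}")``), so adding a generator never perturbs the
output of another, and the same seed always yields byte-identical files.

Generated values are structural, not physico-chemical: m/z uniform in
[100, 2000] Th rounded to 4 decimals, intensities uniform in [1, 1e5]
rounded to 1 decimal, precursors uniform in [400, 1200] with charge 1-3.
No isotope envelopes, noise floors or retention-time physics are modelled.

:func:`make_demo_store` builds the worked provenance example used
throughout the documentation: a protein-extraction experiment (internal
id 1) whose samples feed experiments 100, 146 and 174, with products of
100 and 146 carried into MS experiments 101 and 148.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import access, tracking
from .errors import ValidationError
from .formats.peaklists import (MzList, Peak, Spectrum, render_mzdata,
                                render_mzml, render_mzxml, render_pkl,
                                write_mgf)
from .formats.tables import ENGINES, IdentRecord, LCPeakRow, SpotRecord
from .store import Store


def _rng(name: str, seed: int) -> random.Random:
    return random.Random(f"{name}:{seed}")


@dataclass
class GroundTruth:
    seed: int
    spectra: list[Spectrum] = field(default_factory=list)
    spots: list[SpotRecord] = field(default_factory=list)
    lc_rows: list[LCPeakRow] = field(default_factory=list)
    idents: list[IdentRecord] = field(default_factory=list)
    edges: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# peak lists

def synth_spectra(n_spectra: int, peaks_per_spectrum: int,
                  seed: int) -> MzList:
    """The shared ground truth for all five peak-list dialects: the same
    (n, k, seed) triple yields identical spectra whichever format renders
    them."""
    rng = _rng("spectra", seed)
    mzlist = MzList("pkl")
    for i in range(n_spectra):
        spectrum = Spectrum(
            scan_id=f"spectrum_{i + 1}",
            precursor_mz=round(rng.uniform(400, 1200), 4),
            precursor_charge=rng.randint(1, 3))
        mzs = sorted(round(rng.uniform(100, 2000), 4)
                     for _ in range(peaks_per_spectrum))
        spectrum.peaks = [Peak(mz, round(rng.uniform(1, 1e5), 1))
                          for mz in mzs]
        mzlist.spectra.append(spectrum)
    return mzlist.normalized()


def synth_pkl(n_spectra: int, peaks_per_spectrum: int,
              seed: int) -> tuple[str, MzList]:
    truth = synth_spectra(n_spectra, peaks_per_spectrum, seed)
    return render_pkl(truth), truth


def synth_mgf(n_spectra: int, peaks_per_spectrum: int,
              seed: int) -> tuple[str, MzList]:
    truth = synth_spectra(n_spectra, peaks_per_spectrum, seed)
    return write_mgf(truth), truth


def synth_mzml(n_spectra: int, peaks_per_spectrum: int, seed: int,
               precision: int = 64) -> tuple[bytes, MzList]:
    truth = synth_spectra(n_spectra, peaks_per_spectrum, seed)
    return render_mzml(truth, precision=precision), truth


def synth_mzxml(n_spectra: int, peaks_per_spectrum: int, seed: int,
                precision: int = 64) -> tuple[bytes, MzList]:
    truth = synth_spectra(n_spectra, peaks_per_spectrum, seed)
    return render_mzxml(truth, precision=precision), truth


def synth_mzdata(n_spectra: int, peaks_per_spectrum: int, seed: int,
                 precision: int = 64) -> tuple[bytes, MzList]:
    truth = synth_spectra(n_spectra, peaks_per_spectrum, seed)
    return render_mzdata(truth, precision=precision), truth


# ---------------------------------------------------------------------------
# tables

def synth_spot_table(n_spots: int, seed: int) -> tuple[str, list[SpotRecord]]:
    """Tab-delimited spot quantitation table; %Vol entries are volume
    fractions scaled so their sum stays below 100 even after rounding."""
    rng = _rng("spots", seed)
    volumes = [round(rng.uniform(1e3, 1e6), 1) for _ in range(n_spots)]
    total = sum(volumes) or 1.0
    records = []
    for i, volume in enumerate(volumes, start=1):
        records.append(SpotRecord(
            spot_id=f"S{i}",
            x=float(rng.randint(0, 4000)), y=float(rng.randint(0, 4000)),
            intensity=round(rng.uniform(10, 6.5e4), 1),
            volume=volume,
            area=float(rng.randint(10, 5000)),
            percent_volume=round(volume / total * 99.9, 3),
            pi=round(rng.uniform(3.0, 10.0), 2),
            mw=round(rng.uniform(10.0, 200.0), 1)))
    header = "Spot\tX\tY\tIntensity\tVolume\tArea\t%Vol\tpI\tMW"
    lines = [header] + [
        f"{r.spot_id}\t{r.x}\t{r.y}\t{r.intensity}\t{r.volume}\t{r.area}"
        f"\t{r.percent_volume}\t{r.pi}\t{r.mw}" for r in records]
    return "\n".join(lines) + "\n", records


def synth_lc_table(n_peaks: int, seed: int) -> tuple[str, list[LCPeakRow]]:
    rng = _rng("lc", seed)
    times = sorted(round(rng.uniform(0.5, 90.0), 2) for _ in range(n_peaks))
    rows = [LCPeakRow(peak_no=i + 1, retention_time=t,
                      height=round(rng.uniform(1, 2000.0), 1),
                      area=round(rng.uniform(10, 5e4), 1))
            for i, t in enumerate(times)]
    lines = ["Peak,RetentionTime,Height,Area"] + [
        f"{r.peak_no},{r.retention_time},{r.height},{r.area}" for r in rows]
    return "\n".join(lines) + "\n", rows


_ACCESSIONS = ("P08237", "Q15149", "P02768", "O43175", "P62258", "Q9Y490")


def synth_ident_table(engine: str, n_rows: int,
                      seed: int) -> tuple[str, list[IdentRecord]]:
    import math
    if engine not in ENGINES:
        raise ValidationError(f"unknown identification engine {engine!r}")
    rng = _rng(f"ident-{engine}", seed)
    headers = {"mascot": "pep_query,prot_acc,prot_desc,pep_score",
               "xtandem": "id,label,description,expect",
               "omssa": "Spectrum number,Accession,Defline,E-value"}
    lines = [headers[engine]]
    records = []
    for i in range(1, n_rows + 1):
        accession = rng.choice(_ACCESSIONS)
        description = f"protein {accession} hit {i}"
        if engine == "mascot":
            score = round(rng.uniform(15.0, 120.0), 1)
            lines.append(f"{i},{accession},{description},{score}")
            records.append(IdentRecord(engine, str(i), accession,
                                       description, score))
        else:
            expect = round(rng.uniform(1e-8, 0.1), 12)
            lines.append(f"{i},{accession},{description},{expect!r}")
            records.append(IdentRecord(engine, str(i), accession,
                                       description, -math.log10(expect)))
    return "\n".join(lines) + "\n", records


# ---------------------------------------------------------------------------
# random provenance DAGs

def random_dag(n_nodes: int, edge_prob: float,
               seed: int) -> list[tuple[int, int]]:
    """Random DAG over nodes 1..n, acyclic by construction: edges only run
    from lower to higher node index (a topological order)."""
    if not 0 <= edge_prob <= 1:
        raise ValidationError("edge_prob must be in [0, 1]")
    rng = _rng("dag", seed)
    return [(u, v)
            for u in range(1, n_nodes + 1)
            for v in range(u + 1, n_nodes + 1)
            if rng.random() < edge_prob]


# ---------------------------------------------------------------------------
# demo store

DEMO_USERS = (("gloria", "gloria-pw", "COORDINATOR"),
              ("herbert", "herbert-pw", "RESEARCHER"),
              ("guest", "guest", "GUEST"))

DEMO_EDGES = ((1, 100), (1, 146), (1, 174), (100, 101), (146, 148))


def make_demo_store(store: Store, seed: int = 0) -> Store:
    """Populate an empty store with the worked provenance example.

    Internal ids are pinned to 1 (PREP protein extraction), its children
    100, 146 and 174, and grandchildren 101 (from 100) and 148 (from 146);
    the assignment of grandchildren to parents is an arbitrary but fixed
    convention of this fixture.  The clock used for audit entries is a
    deterministic counter, so two builds with the same seed are
    byte-identical in every report.
    """
    if not store.is_empty():
        raise ValidationError("demo fixture requires an empty store")
    tick = {"n": 0}

    def demo_clock() -> str:
        tick["n"] += 1
        return f"2011-06-01T09:{tick['n'] // 60:02d}:{tick['n'] % 60:02d}"

    previous_clock, store.clock = store.clock, demo_clock
    try:
        for login, password, _role in DEMO_USERS:
            access.register_user(store, login, password, login.capitalize())
        project = store.create_project(
            "SmProteome", "S. mansoni adult-worm proteome survey", "gloria",
            guest_visible=True,
            publications=["Adult-worm soluble-fraction proteome, in prep."])
        store.add_member(project.project_id, "herbert", "RESEARCHER")
        store.add_member(project.project_id, "guest", "GUEST")
        sample = store.create_sample(
            "adult worm soluble extract", organism="Schistosoma mansoni",
            description="pooled soluble fraction, TCA/acetone precipitated")
        prep_protocol = store.create_protocol(
            "TCA/acetone extraction",
            "precipitate, wash, resolubilize in rehydration buffer", "PREP")
        gel_protocol = store.create_protocol(
            "2D-PAGE standard run", "IEF then SDS-PAGE", "GEL2D")
        ms_protocol = store.create_protocol(
            "MALDI-TOF peptide mass fingerprint", "in-gel tryptic digest",
            "MS")
        lc_protocol = store.create_protocol(
            "RP-HPLC fractionation", "C18, TFA/acetonitrile gradient", "LC")

        from .models import GelConditions, LCConditions, MSConditions
        store.create_experiment(
            project.project_id, "PREP", "Protein extraction", "gloria",
            "2011-05-02", samples=[sample.sample_id],
            protocol_id=prep_protocol.protocol_id, _force_id=1)
        gel_a = store.create_experiment(
            project.project_id, "GEL2D", "2D-PAGE pH 3-10", "herbert",
            "2011-05-09", conditions=GelConditions(
                strip_pi_low=3.0, strip_pi_high=10.0,
                focusing_volt_hours=32000.0, gel_percent=12.5,
                second_dim_voltage=200.0, run_time=360.0,
                stain="colloidal Coomassie"),
            samples=[sample.sample_id],
            protocol_id=gel_protocol.protocol_id, _force_id=100)
        gel_b = store.create_experiment(
            project.project_id, "GEL2D", "2D-PAGE pH 4-7", "herbert",
            "2011-05-10", conditions=GelConditions(
                strip_pi_low=4.0, strip_pi_high=7.0,
                focusing_volt_hours=28000.0, gel_percent=10.0,
                second_dim_voltage=200.0, run_time=330.0,
                stain="silver"),
            samples=[sample.sample_id],
            protocol_id=gel_protocol.protocol_id, _force_id=146)
        lc = store.create_experiment(
            project.project_id, "LC", "RP-HPLC fractionation", "gloria",
            "2011-05-11", conditions=LCConditions(
                instrument="AKTA Explorer 100", column="C18 4.6x250 mm",
                solvent_a="0.1% TFA in water",
                solvent_b="0.1% TFA in acetonitrile",
                gradient="5-60% B over 60 min", flow_rate=1.0,
                temperature=25.0, detection_wavelength=214.0),
            samples=[sample.sample_id],
            protocol_id=lc_protocol.protocol_id, _force_id=174)
        ms_a = store.create_experiment(
            project.project_id, "MS", "MALDI-TOF of gel spots (pH 3-10)",
            "herbert", "2011-05-16", conditions=MSConditions(
                instrument="Autoflex III", ionization="MALDI",
                analyzer_mode="TOF reflectron", matrix="CHCA",
                mz_low=700.0, mz_high=3500.0),
            samples=[sample.sample_id],
            protocol_id=ms_protocol.protocol_id, _force_id=101)
        ms_b = store.create_experiment(
            project.project_id, "MS", "MALDI-TOF of gel spots (pH 4-7)",
            "herbert", "2011-05-17", conditions=MSConditions(
                instrument="Autoflex III", ionization="MALDI",
                analyzer_mode="TOF reflectron", matrix="DHB",
                mz_low=700.0, mz_high=3500.0),
            samples=[sample.sample_id],
            protocol_id=ms_protocol.protocol_id, _force_id=148)
        for parent, child in DEMO_EDGES:
            tracking.link(store, parent, child)

        spot_a, _ = synth_spot_table(24, seed)
        spot_b, _ = synth_spot_table(18, seed + 1)
        store.attach_bytes(gel_a.id, spot_a.encode(), "gel_pH3-10_spots.txt",
                           "spot_table")
        store.attach_bytes(gel_b.id, spot_b.encode(), "gel_pH4-7_spots.txt",
                           "spot_table")
        lc_text, _ = synth_lc_table(20, seed)
        store.attach_bytes(lc.id, lc_text.encode(), "rp_hplc_peaks.csv",
                           "chromatogram")
        pkl_text, _ = synth_pkl(5, 12, seed)
        store.attach_bytes(ms_a.id, pkl_text.encode(), "spots_pH3-10.pkl",
                           "peak_list")
        mzml_bytes, _ = synth_mzml(4, 10, seed + 1)
        store.attach_bytes(ms_b.id, mzml_bytes, "spots_pH4-7.mzML",
                           "peak_list")
    finally:
        store.clock = previous_clock
    return store
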