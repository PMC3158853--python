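"""Readers and writers for the external formats.

* mzML (PSI standard) for centroided MS1 spectra — read by a compact
  namespace-aware lxml parser (64/32-bit float arrays, optional zlib
  compression, second/minute scan-time units, plain or indexed mzML),
  written by a small deterministic writer (64-bit, uncompressed) so
  simulated runs round-trip exactly.
* Peptide database, experimental design and intensity matrices as TSV.

Structural violations are rejected, never coerced: a profile-only mzML, a
peptide table with an impossible modification, or a matrix file without its
readout/normalization metadata all raise.  Retention times are minutes
everywhere in memory regardless of file units.
"""

from __future__ import annotations

import base64
import io
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

from . import chem
from .chem import MODIFICATIONS, Modification, PeptideIon


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------

@dataclass
class Ms1Scan:
    """One centroided survey spectrum."""

    scan_time: float  # minutes
    mz_array: np.ndarray  # ascending Th
    intensity_array: np.ndarray  # non-negative counts

    def __post_init__(self):
        self.mz_array = np.asarray(self.mz_array, float)
        self.intensity_array = np.asarray(self.intensity_array, float)
        if self.mz_array.shape != self.intensity_array.shape:
            raise FormatError("m/z and intensity arrays differ in length")
        if self.mz_array.size > 1 and not np.all(np.diff(self.mz_array) > 0):
            raise FormatError("m/z array not strictly ascending")
        if self.scan_time < 0:
            raise FormatError("negative scan time")


@dataclass
class MsRun:
    """A time-ordered sequence of MS1 scans from one LC-MS acquisition."""

    run_id: str
    scans: list[Ms1Scan]
    n_skipped_msn: int = 0

    def __post_init__(self):
        times = np.array([s.scan_time for s in self.scans])
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise FormatError(f"run {self.run_id}: scan times not strictly increasing")

    @property
    def scan_times(self) -> np.ndarray:
        return np.array([s.scan_time for s in self.scans])

    @property
    def total_ms1_intensity(self) -> float:
        """Summed intensity over all MS1 scans — the 'total chromatogram
        intensity' used as the normalization denominator."""
        return float(sum(s.intensity_array.sum() for s in self.scans))


@dataclass
class PeptideRecord:
    """A peptide-database row: an identified peptide ion plus bookkeeping."""

    peptide_id: str
    ion: PeptideIon
    declared_mass: float | None = None
    mass_flagged: bool = False  # declared mass disagrees with computed
    mascot_score_first: float | None = None
    mascot_score_second: float | None = None


@dataclass
class DesignTable:
    """Maps run ids to replicate groups and/or mixing proportions."""

    table: pd.DataFrame  # index run_id; columns: group, proportion

    def __post_init__(self):
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise FormatError(f"duplicate run ids in design: {dup}")

    @property
    def run_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self) -> dict[str, list[str]]:
        if "group" not in self.table or self.table["group"].isna().all():
            raise FormatError("design table has no replicate groups")
        out: dict[str, list[str]] = {}
        for run, grp in self.table["group"].dropna().items():
            out.setdefault(str(grp), []).append(run)
        return out

    def proportions(self) -> pd.Series:
        if "proportion" not in self.table or self.table["proportion"].isna().all():
            raise FormatError("design table has no mixing proportions")
        prop = self.table["proportion"].dropna().astype(float)
        if ((prop < 0) | (prop > 100)).any():
            raise FormatError("mixing proportions must lie in [0, 100]")
        return prop


_MATRIX_STATES = ("raw", "total_normalized", "percent_of_max")


@dataclass
class IntensityMatrix:
    """Peptides x runs intensities with missingness and provenance.

    Missing (NaN) is distinct from zero: quantification never emits zero, so
    NaN always means "no accepted peak".  The normalization state advances
    append-only: raw -> total_normalized -> percent_of_max.
    """

    values: pd.DataFrame  # index peptide ids, columns run ids, NaN = missing
    readout: str  # "height" | "area"
    states: tuple[str, ...] = ("raw",)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.readout not in ("height", "area"):
            raise FormatError(f"readout must be height or area, got {self.readout!r}")
        for s in self.states:
            if s not in _MATRIX_STATES:
                raise FormatError(f"unknown normalization state {s!r}")

    @property
    def state(self) -> str:
        return self.states[-1]

    def advanced(self, values: pd.DataFrame, new_state: str) -> "IntensityMatrix":
        if new_state in self.states:
            raise FormatError(f"normalization {new_state!r} already applied")
        return IntensityMatrix(values, self.readout, self.states + (new_state,),
                               dict(self.params))

    def dropped(self, run_ids: Sequence[str]) -> "IntensityMatrix":
        """Copy with the given runs (columns) removed, e.g. outliers."""
        keep = [c for c in self.values.columns if c not in set(run_ids)]
        return IntensityMatrix(self.values[keep], self.readout, self.states,
                               dict(self.params))


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _decode_array(bda: etree._Element, path: Path) -> tuple[str | None, np.ndarray]:
    accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    if _ACC_F64 in accs:
        dtype = "<f8"
    elif _ACC_F32 in accs:
        dtype = "<f4"
    else:
        raise FormatError(f"{path.name}: binary array is not 32/64-bit float")
    binary = bda.find(f"{_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = ("mz" if _ACC_MZ_ARRAY in accs
            else "intensity" if _ACC_INTENSITY_ARRAY in accs else None)
    return kind, arr


def _scan_time_minutes(spectrum: etree._Element, path: Path) -> float:
    for scan in spectrum.iter(f"{_NS}scan"):
        for cv in scan.iter(f"{_NS}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                value = float(cv.get("value"))
                unit = (cv.get("unitName") or "").lower()
                ua = cv.get("unitAccession") or ""
                if unit == "second" or ua == "UO:0000010":
                    return value / 60.0
                if unit == "millisecond" or ua == "UO:0000028":
                    return value / 60000.0
                return value  # minutes (UO:0000031) or unit unspecified
    raise FormatError(f"{path.name}: spectrum without scan start time")


def read_mzml(path: str | Path, run_id: str | None = None) -> MsRun:
    """Read the MS1 scans of an mzML file into an :class:`MsRun`.

    MSn spectra are skipped and counted; scan start times are converted to
    minutes whatever unit the file declares.  A file whose MS1 spectra are
    profile-mode raises (centroid upstream); a file without MS1 spectra
    raises.
    """
    path = Path(path)
    scans: list[Ms1Scan] = []
    n_skipped = 0
    for _, spectrum in etree.iterparse(str(path), tag=f"{_NS}spectrum"):
        accs = {cv.get("accession"): cv.get("value")
                for cv in spectrum.findall(f"{_NS}cvParam")}
        ms_level = int(accs.get(_ACC_MS_LEVEL, "0") or 0)
        if ms_level != 1:
            n_skipped += 1
            spectrum.clear(keep_tail=True)
            continue
        if _ACC_PROFILE in accs and _ACC_CENTROID not in accs:
            raise FormatError(
                f"{path.name}: MS1 spectra are profile mode; centroid the "
                "file (e.g. msconvert --filter 'peakPicking true 1-') first"
            )
        t = _scan_time_minutes(spectrum, path)
        mz = intensity = None
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            kind, arr = _decode_array(bda, path)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                intensity = arr
        if mz is None or intensity is None:
            raise FormatError(f"{path.name}: spectrum lacks m/z or intensity array")
        scans.append(Ms1Scan(t, mz, intensity))
        spectrum.clear(keep_tail=True)
    if not scans:
        raise FormatError(f"{path.name}: no MS1 spectra found")
    scans.sort(key=lambda s: s.scan_time)
    return MsRun(run_id or path.stem, scans, n_skipped_msn=n_skipped)


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode("ascii")


def write_mzml(run: MsRun, path: str | Path) -> None:
    """Write an MsRun as minimal centroid-MS1 mzML (64-bit, uncompressed).

    Deterministic: no timestamps, so identical runs produce byte-identical
    files.
    """
    path = Path(path)
    buf = io.StringIO()
    w = buf.write
    w('<?xml version="1.0" encoding="utf-8"?>\n')
    w('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n')
    w('<cvList count="2">\n'
      '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry '
      'Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
      '<cv id="UO" fullName="Unit Ontology" '
      'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>\n'
      '</cvList>\n')
    w('<fileDescription><fileContent>'
      '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
      '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
      '</fileContent></fileDescription>\n')
    w('<softwareList count="1"><software id="xicquant" version="0.1.0">'
      '<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="xicquant"/>'
      '</software></softwareList>\n')
    w('<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">'
      '<cvParam cvRef="MS" accession="MS:1000031" name="instrument model"/>'
      '</instrumentConfiguration></instrumentConfigurationList>\n')
    w('<dataProcessingList count="1"><dataProcessing id="dp1">'
      '<processingMethod order="1" softwareRef="xicquant">'
      '<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML"/>'
      '</processingMethod></dataProcessing></dataProcessingList>\n')
    w(f'<run id="{escape(run.run_id)}" defaultInstrumentConfigurationRef="IC1">\n')
    w(f'<spectrumList count="{len(run.scans)}" defaultDataProcessingRef="dp1">\n')
    for i, scan in enumerate(run.scans):
        mz_b64 = _b64(scan.mz_array)
        int_b64 = _b64(scan.intensity_array)
        w(f'<spectrum index="{i}" id="scan={i + 1}" '
          f'defaultArrayLength="{scan.mz_array.size}">\n')
        w('<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n')
        w('<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>\n')
        w('<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>\n')
        w('<scanList count="1">'
          '<cvParam cvRef="MS" accession="MS:1000795" name="no combination"/>'
          '<scan>'
          f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
          f'value="{float(scan.scan_time)!r}" unitCvRef="UO" unitAccession="UO:0000031" '
          'unitName="minute"/>'
          '</scan></scanList>\n')
        w('<binaryDataArrayList count="2">\n')
        w(f'<binaryDataArray encodedLength="{len(mz_b64)}">'
          '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
          '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
          '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" '
          'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
          f'<binary>{mz_b64}</binary></binaryDataArray>\n')
        w(f'<binaryDataArray encodedLength="{len(int_b64)}">'
          '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
          '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
          '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" '
          'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
          f'<binary>{int_b64}</binary></binaryDataArray>\n')
        w('</binaryDataArrayList>\n</spectrum>\n')
    w('</spectrumList>\n</run>\n</mzML>\n')
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Modification strings and the peptide database
# ---------------------------------------------------------------------------

def parse_modifications(
    spec: str, registry: Mapping[str, Modification] = MODIFICATIONS
) -> tuple[tuple[int | str, Modification], ...]:
    """Parse the ``pos:Name`` dialect: semicolon-separated, 1-based residue
    positions, ``nt``/``ct`` for the termini.  Example:
    ``"2:Phospho;nt:Pyro-glu"``."""
    spec = spec.strip()
    if not spec:
        return ()
    mods: list[tuple[int | str, Modification]] = []
    for item in spec.split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            pos_s, name = item.split(":", 1)
        except ValueError:
            raise FormatError(f"malformed modification {item!r}") from None
        pos: int | str
        if pos_s in ("nt", "ct"):
            pos = pos_s
        else:
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"malformed modification position {pos_s!r}") from None
        name = name.strip()
        if name not in registry:
            raise FormatError(f"unknown modification {name!r}")
        mods.append((pos, registry[name]))
    return tuple(mods)


def format_modifications(mods: Iterable[tuple[int | str, Modification]]) -> str:
    return ";".join(f"{pos}:{mod.name}" for pos, mod in mods)


PEPTIDE_DB_COLUMNS = ["id", "sequence", "modifications", "charge", "tR_min"]
_MASS_CHECK_TOL = 0.01  # Da


def read_peptide_db(path: str | Path) -> list[PeptideRecord]:
    """Read the peptide-database TSV.

    Required columns: id, sequence, modifications, charge, tR_min; optional:
    mass, score_first, score_second.  Sequences and modifications are
    validated chemically; a declared mass more than 0.01 Da from the
    computed one flags the record rather than silently passing.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in PEPTIDE_DB_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peptide db missing columns: {missing}")
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        pid = row["id"].strip()
        if not pid:
            raise FormatError(f"row {idx}: empty peptide id")
        if pid in seen:
            raise FormatError(f"duplicate peptide id {pid!r}")
        seen.add(pid)
        try:
            charge = int(row["charge"])
            tr = float(row["tR_min"])
        except ValueError as e:
            raise FormatError(f"peptide {pid}: {e}") from None
        mods = parse_modifications(row["modifications"])
        try:
            ion = PeptideIon(row["sequence"].strip(), mods, charge, tr)
        except chem.ChemError as e:
            raise FormatError(f"peptide {pid}: {e}") from None
        declared = None
        flagged = False
        if "mass" in df.columns and row["mass"].strip():
            declared = float(row["mass"])
            flagged = abs(declared - ion.monoisotopic_mass) > _MASS_CHECK_TOL
        def _score(col):
            return float(row[col]) if col in df.columns and row[col].strip() else None
        records.append(PeptideRecord(pid, ion, declared, flagged,
                                     _score("score_first"), _score("score_second")))
    return records


def write_peptide_db(records: Sequence[PeptideRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.peptide_id,
            "sequence": r.ion.sequence,
            "modifications": format_modifications(r.ion.modifications),
            "charge": r.ion.charge,
            "tR_min": r.ion.reference_tR,
            "mass": r.ion.monoisotopic_mass,
            "score_first": "" if r.mascot_score_first is None else r.mascot_score_first,
            "score_second": "" if r.mascot_score_second is None else r.mascot_score_second,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"run_id": str})
    if "run_id" not in df.columns:
        raise FormatError("design table needs a run_id column")
    if "group" not in df.columns and "proportion" not in df.columns:
        raise FormatError("design table needs a group or proportion column")
    for col in ("group", "proportion"):
        if col not in df.columns:
            df[col] = np.nan
    return DesignTable(df.set_index("run_id")[["group", "proportion"]])


def write_design(design: DesignTable, path: str | Path) -> None:
    design.table.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intensity matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    """TSV with ``# key: value`` metadata header lines; missing cells as NA."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# readout: {matrix.readout}\n")
        fh.write(f"# normalization: {','.join(matrix.states)}\n")
        for k, v in sorted(matrix.params.items()):
            fh.write(f"# param {k}: {v}\n")
        matrix.values.rename_axis("peptide_id").to_csv(
            fh, sep="\t", na_rep="NA", lineterminator="\n"
        )


def read_matrix(path: str | Path) -> IntensityMatrix:
    path = Path(path)
    readout = states = None
    params: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line[1:].partition(":")
        key, val = key.strip(), val.strip()
        if key == "readout":
            readout = val
        elif key == "normalization":
            states = tuple(val.split(","))
        elif key.startswith("param "):
            params[key[6:]] = val
    if readout is None or states is None:
        raise FormatError(f"{path.name}: missing readout/normalization metadata")
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t",
                     index_col="peptide_id", na_values=["NA"], keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path.name}: duplicate peptide rows {dup}")
    return IntensityMatrix(df.rename_axis(None), readout, states, params)
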