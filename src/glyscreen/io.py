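"""File I/O for the identification pipeline.

Reads mzXML runs (via pyteomics), tabular MS1/fragment databases (CSV or
XLSX), LC fluorescence traces and MALDI peak lists; writes result tables in
the app-style column layout and minimal mzXML (used by the run simulator).

Retention time is canonicalised to **minutes** everywhere; mzXML encodes
ISO-8601 durations in seconds and the conversion happens at the boundary.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pyteomics import mzxml as _mzxml

from .fragments import Fragment, FragmentSet
from .masses import FluorescentTag, get_tag

__all__ = [
    "Scan",
    "ScanSet",
    "MS1DatabaseEntry",
    "LCTrace",
    "read_mzxml",
    "write_mzxml",
    "read_ms1_database",
    "read_lc_trace",
    "detect_lc_peak_windows",
    "read_maldi_peaklist",
    "read_fragment_db",
    "write_fragment_db",
    "write_ms1_output",
    "write_maldi_output",
    "write_ms2_details",
    "MS1_COLUMNS",
    "MALDI_COLUMNS",
]

#: Output column order of the MS1 result table.
MS1_COLUMNS = [
    "Name",
    "Isomer peak no",
    "RT (min)",
    "Charge (z)",
    "Observed m/z",
    "Theoretical mass (Da)",
    "Observed mass (Da)",
    "Mass error (ppm)",
    "Intensity (count)",
    "Relative intensity (%)",
]

MALDI_COLUMNS = [
    "Name",
    "Theoretical mass (Da)",
    "Observed mass (Da)",
    "Observed m/z",
    "Mass error (Da)",
    "Intensity (count)",
    "Relative intensity (%)",
]


@dataclass
class Scan:
    """One mass spectrum: centroided sticks at a retention time."""

    num: int
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(f"scan {self.num}: m/z and intensity lengths differ")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.num}: negative intensity")

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass
class ScanSet:
    """All scans of one run, ordered by retention time."""

    scans: List[Scan]

    def __post_init__(self) -> None:
        self.scans = sorted(self.scans, key=lambda s: s.rt)

    def __len__(self) -> int:
        return len(self.scans)

    def by_level(self, ms_level: int) -> List[Scan]:
        return [s for s in self.scans if s.ms_level == ms_level]

    @property
    def ms1(self) -> List[Scan]:
        return self.by_level(1)

    @property
    def ms2(self) -> List[Scan]:
        return self.by_level(2)

    @property
    def rt_range(self) -> Tuple[float, float]:
        if not self.scans:
            return (0.0, 0.0)
        return (self.scans[0].rt, self.scans[-1].rt)


@dataclass(frozen=True)
class MS1DatabaseEntry:
    """One searchable glycan: name, theoretical labeled mass, optional RT."""

    name: str
    mass: float
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if self.rt is not None and self.rt <= 0:
            raise ValueError(f"{self.name}: RT must be blank or positive")


@dataclass
class LCTrace:
    """Fluorescence chromatogram: RT (minutes) vs intensity."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("LC trace RT and intensity lengths differ")
        if np.any(np.diff(self.rt) < 0):
            raise ValueError("LC trace RT must be non-decreasing")

    @property
    def apex_rt(self) -> float:
        return float(self.rt[int(np.argmax(self.intensity))])


# -- mzXML ------------------------------------------------------------------


def _rt_minutes(value) -> float:
    """pyteomics returns retentionTime as a unitfloat in minutes."""
    return float(value)


def read_mzxml(path: Union[str, Path]) -> ScanSet:
    """Load every MS1/MS2 scan of an mzXML file.

    Peak arrays are decoded (base64, 32/64-bit, optional zlib) by pyteomics
    and re-sorted by m/z.  MS2 scans without precursor information raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: List[Scan] = []
    with _mzxml.read(str(path)) as reader:
        for raw in reader:
            level = int(raw["msLevel"])
            num = int(raw["num"])
            prec_mz = prec_z = None
            if level >= 2:
                prec = raw.get("precursorMz")
                if not prec:
                    raise ValueError(f"MS2 scan {num} has no precursor information")
                prec_mz = float(prec[0]["precursorMz"])
                if "precursorCharge" in prec[0]:
                    prec_z = int(prec[0]["precursorCharge"])
            scans.append(
                Scan(
                    num=num,
                    ms_level=level,
                    rt=_rt_minutes(raw["retentionTime"]),
                    mz=raw["m/z array"],
                    intensity=raw["intensity array"],
                    precursor_mz=prec_mz,
                    precursor_charge=prec_z,
                )
            )
    return ScanSet(scans)


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray) -> str:
    pairs = np.empty(2 * len(mz), dtype=">f8")
    pairs[0::2] = mz
    pairs[1::2] = intensity
    return base64.b64encode(pairs.tobytes()).decode("ascii")


def write_mzxml(scanset: ScanSet, path: Union[str, Path]) -> None:
    """Write a minimal mzXML 3.2 file (64-bit, network order, uncompressed).

    The output round-trips exactly through :func:`read_mzxml`; it is the
    on-disk form of simulated runs.
    """
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(scanset)}">',
    ]
    for scan in scanset.scans:
        rt_s = scan.rt * 60.0
        lines.append(
            f'  <scan num="{scan.num}" msLevel="{scan.ms_level}"'
            f' retentionTime="PT{rt_s:.6f}S" peaksCount="{len(scan.mz)}">'
        )
        if scan.ms_level >= 2 and scan.precursor_mz is not None:
            charge = (
                f' precursorCharge="{scan.precursor_charge}"'
                if scan.precursor_charge is not None
                else ""
            )
            lines.append(
                f'   <precursorMz{charge} precursorIntensity="0">'
                f"{scan.precursor_mz:.6f}</precursorMz>"
            )
        payload = _encode_peaks(scan.mz, scan.intensity)
        lines.append(
            '   <peaks precision="64" byteOrder="network" contentType="m/z-int"'
            f' compressionType="none">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    Path(path).write_text("\n".join(lines))


# -- tabular inputs ---------------------------------------------------------


def _read_table(path: Union[str, Path], **kwargs) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, **kwargs)
    return pd.read_csv(path, **kwargs)


def _write_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_ms1_database(path: Union[str, Path]) -> List[MS1DatabaseEntry]:
    """Read the glycan search database: name, mass (Da), optional RT (min).

    Accepts CSV or XLSX; column order is positional (header optional names
    are tolerated).  A blank third column means "RT unknown".
    """
    table = _read_table(path)
    if table.shape[1] < 2:
        raise ValueError("MS1 database needs at least name and mass columns")
    if len(table) == 0:
        warnings.warn("MS1 database is empty")
        return []
    entries: List[MS1DatabaseEntry] = []
    for i, row in table.iterrows():
        name = str(row.iloc[0])
        try:
            mass = float(row.iloc[1])
        except (TypeError, ValueError):
            raise ValueError(f"row {i} ({name}): non-numeric mass {row.iloc[1]!r}")
        rt = None
        if table.shape[1] >= 3 and pd.notna(row.iloc[2]) and str(row.iloc[2]).strip():
            rt = float(row.iloc[2])
        entries.append(MS1DatabaseEntry(name=name, mass=mass, rt=rt))
    return entries


def read_lc_trace(path: Union[str, Path]) -> LCTrace:
    """Read an LC export as a 2-column (RT min, intensity) CSV/XLSX."""
    table = _read_table(path)
    if table.shape[1] < 2:
        raise ValueError("LC trace needs RT and intensity columns")
    return LCTrace(
        rt=table.iloc[:, 0].to_numpy(float),
        intensity=table.iloc[:, 1].to_numpy(float),
    )


def detect_lc_peak_windows(
    trace: LCTrace, min_rel_height: float = 0.01
) -> List[Tuple[float, float]]:
    """Elution-peak windows of a fluorescence trace.

    Contiguous regions where intensity >= ``min_rel_height`` x trace maximum,
    split at interior local minima, reported as (start RT, stop RT) pairs.
    """
    if len(trace.rt) < 3:
        raise ValueError("LC trace needs at least 3 points")
    top = float(trace.intensity.max())
    if top <= 0:
        warnings.warn("LC trace is flat; no elution windows detected")
        return []
    above = trace.intensity >= min_rel_height * top
    windows: List[Tuple[float, float]] = []
    i, n = 0, len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # split the [i, j] region at interior local minima
        start = i
        for k in range(i + 1, j):
            y = trace.intensity
            if y[k] < y[k - 1] and y[k] <= y[k + 1]:
                windows.append((float(trace.rt[start]), float(trace.rt[k])))
                start = k
        windows.append((float(trace.rt[start]), float(trace.rt[j])))
        i = j + 1
    return windows


def read_maldi_peaklist(path: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray]:
    """Read a MALDI peak list: 2-column (m/z, intensity) CSV/TXT/XLSX."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".tsv"):
        table = pd.read_csv(path, sep=None, engine="python")
    else:
        table = _read_table(path)
    if table.shape[1] < 2:
        raise ValueError("MALDI peak list needs m/z and intensity columns")
    mz = table.iloc[:, 0].to_numpy(float)
    inten = table.iloc[:, 1].to_numpy(float)
    order = np.argsort(mz)
    return mz[order], inten[order]


# -- fragment database ------------------------------------------------------


def write_fragment_db(
    sets: Sequence[FragmentSet], path: Union[str, Path], append: bool = False
) -> None:
    """Write fragment sets to the tabular MS2 fragment database."""
    rows = [
        {
            "parent_name": fs.parent,
            "parent_mass_Da": round(fs.parent_mass, 4),
            "fragment_id": f.fragment_id,
            "ion_class": f.ion_class,
            "cut_count": f.cut_count,
            "residue_composition": f.composition_str,
            "neutral_mass_Da": round(f.neutral_mass, 4),
        }
        for fs in sets
        for f in fs
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "parent_name",
            "parent_mass_Da",
            "fragment_id",
            "ion_class",
            "cut_count",
            "residue_composition",
            "neutral_mass_Da",
        ],
    )
    path = Path(path)
    if append and path.exists():
        frame = pd.concat([_read_table(path), frame], ignore_index=True)
    _write_table(frame, path)


def _composition_from_str(text: str) -> Dict[str, int]:
    out: Dict[str, int] = {}
    i = 0
    while i < len(text):
        code = text[i : i + 3]
        i += 3
        j = i
        while j < len(text) and text[j].isdigit():
            j += 1
        out[code] = int(text[i:j]) if j > i else 1
        i = j
    return out


def read_fragment_db(
    path: Union[str, Path], tag: Union[str, float, FluorescentTag] = "ProCA"
) -> Dict[str, FragmentSet]:
    """Load the fragment database back into per-parent FragmentSets.

    Retained node sets are not stored on disk; matching needs only masses,
    ion classes and residue counts, so placeholder node sets are used.
    """
    tag = get_tag(tag)
    table = _read_table(path)
    sets: Dict[str, FragmentSet] = {}
    for parent, group in table.groupby("parent_name", sort=False):
        fragments = []
        for _, row in group.iterrows():
            comp = _composition_from_str(str(row["residue_composition"]))
            fragments.append(
                Fragment(
                    parent=str(parent),
                    fragment_id=str(row["fragment_id"]),
                    retained=frozenset(range(sum(comp.values()))),
                    ion_class=str(row["ion_class"]),
                    cut_count=int(row.get("cut_count", 1)),
                    contains_tag=str(row["ion_class"]) == "Y",
                    composition=tuple(sorted(comp.items())),
                    neutral_mass=float(row["neutral_mass_Da"]),
                )
            )
        sets[str(parent)] = FragmentSet(
            parent=str(parent),
            parent_mass=float(group["parent_mass_Da"].iloc[0]),
            tag=tag,
            fragments=fragments,
        )
    return sets


# -- result tables ----------------------------------------------------------


def write_ms1_output(hits: Sequence, path: Union[str, Path]) -> None:
    """Write MS1 hits in the app-style column layout (CSV or XLSX)."""
    rows = [
        {
            "Name": h.name,
            "Isomer peak no": h.isomer_peak,
            "RT (min)": round(h.rt, 3),
            "Charge (z)": h.charge,
            "Observed m/z": round(h.observed_mz, 4),
            "Theoretical mass (Da)": round(h.theoretical_mass, 4),
            "Observed mass (Da)": round(h.observed_mass, 4),
            "Mass error (ppm)": round(abs(h.ppm_error), 1),
            "Intensity (count)": round(h.intensity, 0),
            "Relative intensity (%)": round(h.relative_intensity, 0),
        }
        for h in hits
    ]
    _write_table(pd.DataFrame(rows, columns=MS1_COLUMNS), path)


def read_ms1_output(path: Union[str, Path]) -> pd.DataFrame:
    return _read_table(path)


def write_maldi_output(hits: Sequence, path: Union[str, Path]) -> None:
    rows = [
        {
            "Name": h.name,
            "Theoretical mass (Da)": round(h.theoretical_mass, 4),
            "Observed mass (Da)": round(h.observed_mass, 4),
            "Observed m/z": round(h.observed_mz, 4),
            "Mass error (Da)": round(h.mass_error, 4),
            "Intensity (count)": round(h.intensity, 0),
            "Relative intensity (%)": round(h.relative_intensity, 1),
        }
        for h in hits
    ]
    _write_table(pd.DataFrame(rows, columns=MALDI_COLUMNS), path)


def write_ms2_details(results: Sequence, path: Union[str, Path]) -> None:
    """Write per-glycan MS2 confirmation statistics."""
    rows = []
    for r in results:
        rows.append(
            {
                "Name": r.name,
                "MS2 RT (min)": round(r.rt, 3) if r.rt is not None else "",
                "Confirmed": r.confirmed,
                "Distinct peaks": r.n_distinct_peaks,
                "Annotated peaks": r.n_annotated_peaks,
                "Qualifying fragments": r.n_qualifying,
                "Qualifying identified": r.n_qualifying_matched,
                "Percent identified": (
                    round(r.percent_identified, 1)
                    if r.percent_identified is not None
                    else "undefined"
                ),
                "Unique vs isomers found": ";".join(
                    f"{m:.4f}" for m in sorted(r.unique_masses_found)
                ),
                "Adducts found": ";".join(sorted(r.adducts_found)),
            }
        )
    _write_table(pd.DataFrame(rows), path)
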