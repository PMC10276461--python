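"""MS1 accurate-mass peak identification.

For each database glycan and each charge state up to the configured
maximum, the search builds an extracted ion chromatogram (XIC) inside a
ppm- or Da-wide m/z window around the theoretical [M+zH]z+ value, picks the
highest-intensity point that passes the intensity threshold as the primary
peak, and then scans +-1.75 min around it for chromatographically separated
isomer peaks using a slope-sign rule on the XIC.  Database glycans sharing
one theoretical mass (to 0.001 Da) form an isomer group: they share a
single peak list and the number of reportable isomer peaks equals the group
size.

The retention-time range searched for the primary peak can be restricted
either by a per-glycan expected RT (+- a configurable interval) or by
fluorescence elution windows from an LC trace, aligned to the MS time base
by matching the apexes of the two base-peak profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io import LCTrace, MS1DatabaseEntry, Scan, ScanSet, detect_lc_peak_windows
from .masses import (
    FluorescentTag,
    TAG_PROCA,
    get_tag,
    mass_from_mz,
    mz_from_mass,
    ppm_error,
)

__all__ = [
    "MS1Params",
    "XIC",
    "MS1Hit",
    "mz_window",
    "align_lc_to_ms",
    "build_xic",
    "find_primary_peak",
    "detect_isomer_peaks",
    "run_ms1",
]

#: Half-width (minutes) of the RT range scanned for isomer peaks around the
#: primary peak.  Fixed: isomers elute near one another.
ISOMER_WINDOW_MIN = 1.75

#: Slope-rule window: a peak needs >=3 of the 4 slopes before it positive
#: and >=3 of the 4 after it negative.
SLOPE_WINDOW = 4
SLOPE_REQUIRED = 3

#: Theoretical masses within this many Da are "the same mass" for isomer
#: grouping purposes.
SAME_MASS_TOL_DA = 0.001


@dataclass(frozen=True)
class MS1Params:
    """User-tunable MS1 search settings (defaults mirror the app's)."""

    tolerance: float = 10.0
    tolerance_unit: str = "ppm"  # "ppm" or "Da"
    tag: Union[str, float, FluorescentTag] = TAG_PROCA
    max_charge: int = 2
    threshold_type: str = "relative"  # "relative" (%) or "absolute" (counts)
    threshold: float = 25.0
    rt_interval: float = 0.25  # minutes; used only when the DB has RTs

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("mass tolerance must be positive")
        if self.tolerance_unit not in ("ppm", "Da"):
            raise ValueError("tolerance unit must be 'ppm' or 'Da'")
        if not 1 <= self.max_charge <= 4:
            raise ValueError("max charge must be 1..4")
        if self.threshold_type not in ("relative", "absolute"):
            raise ValueError("threshold type must be 'relative' or 'absolute'")
        if self.threshold_type == "relative" and not 0 <= self.threshold <= 100:
            raise ValueError("relative threshold must be 0..100%")
        if self.rt_interval <= 0:
            raise ValueError("RT interval must be positive")


@dataclass
class XIC:
    """Extracted ion chromatogram for one glycan mass at one charge."""

    name: str
    charge: int
    mz_lo: float
    mz_hi: float
    rt: np.ndarray
    intensity: np.ndarray
    scan_index: np.ndarray  # indices into the MS1 scan list


@dataclass(frozen=True)
class MS1Hit:
    """One identified (glycan, isomer peak, charge) row."""

    name: str
    isomer_peak: int
    rt: float
    charge: int
    observed_mz: float
    theoretical_mass: float
    observed_mass: float
    ppm_error: float
    intensity: float
    relative_intensity: float


def mz_window(
    entry: MS1DatabaseEntry, z: int, params: MS1Params
) -> Tuple[float, float]:
    """The (lo, hi) m/z search window for a glycan at charge ``z``."""
    center = mz_from_mass(entry.mass, z)
    if params.tolerance_unit == "ppm":
        half = center * params.tolerance * 1e-6
    else:
        half = params.tolerance / z
    return center - half, center + half


def align_lc_to_ms(trace: LCTrace, scans: ScanSet) -> float:
    """RT offset (minutes) mapping the LC time base onto the MS time base.

    Computed as MS base-peak apex RT minus LC fluorescence apex RT; adding
    the offset to an LC retention time yields the matching MS retention
    time.
    """
    ms1 = scans.ms1
    if not ms1:
        raise ValueError("scan set contains no MS1 scans")
    if float(trace.intensity.max(initial=0.0)) <= 0:
        warnings.warn("flat LC trace; assuming zero LC/MS offset")
        return 0.0
    totals = np.array([s.intensity.sum() if s.intensity.size else 0.0 for s in ms1])
    ms_apex = ms1[int(np.argmax(totals))].rt
    return ms_apex - trace.apex_rt


def build_xic(
    scans: ScanSet,
    window: Tuple[float, float],
    rt_range: Optional[Tuple[float, float]] = None,
) -> XIC:
    """Summed intensity inside an m/z window, per MS1 scan."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("invalid m/z window")
    rts, totals, idx = [], [], []
    for i, scan in enumerate(scans.ms1):
        if rt_range is not None and not rt_range[0] <= scan.rt <= rt_range[1]:
            continue
        a = np.searchsorted(scan.mz, lo, side="left")
        b = np.searchsorted(scan.mz, hi, side="right")
        rts.append(scan.rt)
        totals.append(float(scan.intensity[a:b].sum()))
        idx.append(i)
    return XIC(
        name="",
        charge=0,
        mz_lo=lo,
        mz_hi=hi,
        rt=np.asarray(rts),
        intensity=np.asarray(totals),
        scan_index=np.asarray(idx, dtype=int),
    )


def _spectrum_peak(scan: Scan, lo: float, hi: float) -> Optional[Tuple[float, float]]:
    """Most intense stick of a scan inside [lo, hi]: (m/z, intensity)."""
    a = np.searchsorted(scan.mz, lo, side="left")
    b = np.searchsorted(scan.mz, hi, side="right")
    if b <= a:
        return None
    k = a + int(np.argmax(scan.intensity[a:b]))
    return float(scan.mz[k]), float(scan.intensity[k])


def _passes_threshold(intensity: float, scan: Scan, params: MS1Params) -> bool:
    if params.threshold_type == "absolute":
        return intensity >= params.threshold
    base = scan.base_peak_intensity
    return base > 0 and intensity >= params.threshold / 100.0 * base


@dataclass(frozen=True)
class _Candidate:
    rt: float
    xic_index: int
    scan_index: int
    observed_mz: float
    intensity: float
    relative_intensity: float


def _candidate_at(
    xic: XIC, i: int, scans: ScanSet, params: MS1Params
) -> Optional[_Candidate]:
    scan = scans.ms1[int(xic.scan_index[i])]
    peak = _spectrum_peak(scan, xic.mz_lo, xic.mz_hi)
    if peak is None:
        return None
    mz, inten = peak
    if not _passes_threshold(inten, scan, params):
        return None
    base = scan.base_peak_intensity
    rel = min(100.0 * inten / base, 100.0) if base else 0.0
    return _Candidate(
        rt=float(xic.rt[i]),
        xic_index=i,
        scan_index=int(xic.scan_index[i]),
        observed_mz=mz,
        intensity=inten,
        relative_intensity=rel,
    )


def find_primary_peak(
    xic: XIC, scans: ScanSet, params: MS1Params
) -> Optional[_Candidate]:
    """Highest-intensity XIC point whose spectrum peak passes the threshold.

    XIC points are visited in decreasing order of summed intensity; the
    first whose most intense in-window spectrum stick clears the intensity
    threshold (absolute counts, or percent of that scan's base peak) wins.
    """
    if xic.intensity.size == 0:
        return None
    for i in np.argsort(-xic.intensity, kind="stable"):
        if xic.intensity[i] <= 0:
            break
        cand = _candidate_at(xic, int(i), scans, params)
        if cand is not None:
            return cand
    return None


def _slope_peak_indices(intensity: np.ndarray) -> List[int]:
    """Indices that qualify as peaks under the slope-sign rule.

    A point is a peak when it is a strict local maximum (slope into it
    positive, slope out of it negative) and at least 3 of the up-to-4
    slopes on each side agree in sign; the 4-slope windows tolerate one
    noisy slope and truncate at the chromatogram edges.
    """
    n = len(intensity)
    if n < 3:
        return []
    slopes = np.diff(intensity)
    peaks = []
    for i in range(1, n - 1):
        if not (slopes[i - 1] > 0 and slopes[i] < 0):
            continue
        before = slopes[max(0, i - SLOPE_WINDOW) : i]
        after = slopes[i : i + SLOPE_WINDOW]
        n_pos = int(np.sum(before > 0))
        n_neg = int(np.sum(after < 0))
        # truncated edge windows need every available slope, up to 3
        need_pos = min(SLOPE_REQUIRED, len(before))
        need_neg = min(SLOPE_REQUIRED, len(after))
        if len(before) >= 2 and len(after) >= 2 and n_pos >= need_pos and n_neg >= need_neg:
            peaks.append(i)
    return peaks


def detect_isomer_peaks(
    xic: XIC,
    primary: _Candidate,
    n_isomers: int,
    scans: ScanSet,
    params: MS1Params,
) -> List[_Candidate]:
    """Up to ``n_isomers`` isomer peaks within +-1.75 min of the primary.

    Slope-rule peaks are ranked by XIC intensity; the primary is always
    kept.  The returned list is sorted by ascending RT (the caller numbers
    isomer peaks 1..k in that order).
    """
    if n_isomers < 1:
        raise ValueError("n_isomers must be >= 1")
    lo, hi = primary.rt - ISOMER_WINDOW_MIN, primary.rt + ISOMER_WINDOW_MIN
    mask = (xic.rt >= lo) & (xic.rt <= hi)
    (idx,) = np.nonzero(mask)
    sub = xic.intensity[idx]
    ranked: List[_Candidate] = [primary]
    for j in sorted(_slope_peak_indices(sub), key=lambda j: -sub[j]):
        if len(ranked) >= n_isomers:
            break
        i = int(idx[j])
        if i == primary.xic_index:
            continue
        cand = _candidate_at(xic, i, scans, params)
        if cand is not None:
            ranked.append(cand)
    return sorted(ranked, key=lambda c: c.rt)


def _mass_groups(db: Sequence[MS1DatabaseEntry]) -> List[List[MS1DatabaseEntry]]:
    """Group DB entries whose theoretical masses agree to 0.001 Da."""
    groups: List[List[MS1DatabaseEntry]] = []
    for entry in db:
        for group in groups:
            if abs(group[0].mass - entry.mass) <= SAME_MASS_TOL_DA:
                group.append(entry)
                break
        else:
            groups.append([entry])
    return groups


def run_ms1(
    scans: ScanSet,
    db: Sequence[MS1DatabaseEntry],
    params: MS1Params = MS1Params(),
    lc: Optional[LCTrace] = None,
) -> List[MS1Hit]:
    """The full MS1 screen: every database glycan at every charge state.

    RT restriction for the primary-peak search, in order of precedence:
    the entry's expected RT +- ``rt_interval`` when present, else aligned
    LC elution windows when a trace is supplied, else the whole run.
    Isomer detection always uses the unrestricted chromatogram around the
    primary peak.
    """
    if not db:
        warnings.warn("empty MS1 database; nothing to search")
        return []
    if not scans.ms1:
        raise ValueError("run contains no MS1 scans")

    lc_windows: Optional[List[Tuple[float, float]]] = None
    if lc is not None:
        offset = align_lc_to_ms(lc, scans)
        lc_windows = [
            (start + offset, stop + offset)
            for start, stop in detect_lc_peak_windows(lc)
        ]

    hits: List[MS1Hit] = []
    for group in _mass_groups(db):
        n_isomers = len(group)
        mass = group[0].mass
        rts = [e.rt for e in group if e.rt is not None]
        expected_rt = rts[0] if rts else None
        for z in range(1, params.max_charge + 1):
            lo, hi = mz_window(group[0], z, params)
            full_xic = build_xic(scans, (lo, hi))
            full_xic.charge = z

            primary = None
            if expected_rt is not None:
                rt_range = (
                    expected_rt - params.rt_interval,
                    expected_rt + params.rt_interval,
                )
                primary = _find_primary_in_range(full_xic, rt_range, scans, params)
            elif lc_windows is not None:
                for window in lc_windows:
                    cand = _find_primary_in_range(full_xic, window, scans, params)
                    if cand is not None and (
                        primary is None or cand.intensity > primary.intensity
                    ):
                        primary = cand
            else:
                primary = find_primary_peak(full_xic, scans, params)
            if primary is None:
                continue

            peaks = detect_isomer_peaks(full_xic, primary, n_isomers, scans, params)
            for entry in group:
                for k, cand in enumerate(peaks, start=1):
                    observed_mass = mass_from_mz(cand.observed_mz, z)
                    hits.append(
                        MS1Hit(
                            name=entry.name,
                            isomer_peak=k,
                            rt=cand.rt,
                            charge=z,
                            observed_mz=cand.observed_mz,
                            theoretical_mass=entry.mass,
                            observed_mass=observed_mass,
                            ppm_error=ppm_error(observed_mass, entry.mass),
                            intensity=cand.intensity,
                            relative_intensity=cand.relative_intensity,
                        )
                    )
    return hits


def _find_primary_in_range(
    xic: XIC,
    rt_range: Tuple[float, float],
    scans: ScanSet,
    params: MS1Params,
) -> Optional[_Candidate]:
    """Primary-peak search restricted to an RT range of an existing XIC."""
    mask = (xic.rt >= rt_range[0]) & (xic.rt <= rt_range[1])
    (idx,) = np.nonzero(mask)
    if idx.size == 0:
        return None
    for j in np.argsort(-xic.intensity[idx], kind="stable"):
        i = int(idx[j])
        if xic.intensity[i] <= 0:
            break
        cand = _candidate_at(xic, i, scans, params)
        if cand is not None:
            return cand
    return None
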