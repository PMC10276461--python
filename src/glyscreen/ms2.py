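"""MS2 peak confirmation and spectrum annotation statistics.

Given an MS1 hit (glycan, RT, charge), the confirmation step finds the
first MS2 scan at or after RT - 0.1 min whose precursor matches the
glycan's theoretical m/z at that charge, then matches the glycan's fragment
database against the spectrum: every stick whose relative intensity (vs the
scan base peak) clears the label threshold is compared with each fragment
ion — plain and as +Na / +K / -OH adduct species — within the mass
tolerance.  Each peak carries at most two annotations, ranked no-adduct
first, then by absolute ppm error, then by fewer bond cuts.

The Details statistics report the fraction of *qualifying* fragments
identified (fragments of two or more residues whose mass is unique within
the parent's own fragment set) and the matched masses that are unique to
the parent versus its same-mass isomers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .fragments import (
    Fragment,
    FragmentSet,
    multi_residue_unique_fragments,
    unique_fragment_masses,
)
from .io import Scan, ScanSet
from .masses import (
    FluorescentTag,
    TAG_PROCA,
    adduct_mz,
    get_tag,
    mz_from_mass,
    ppm_error,
)
from .ms1 import MS1Hit

__all__ = [
    "MS2Params",
    "FragmentMatch",
    "PeakAnnotation",
    "MS2Result",
    "locate_ms2_scan",
    "match_fragments",
    "compute_details",
    "run_ms2",
]

#: The MS2 scan search starts this many minutes before the MS1 hit RT.
PRECURSOR_SEARCH_BACK_MIN = 0.1

ADDUCTS = ("+Na", "+K", "-OH")


@dataclass(frozen=True)
class MS2Params:
    """User-tunable MS2 confirmation settings (defaults mirror the app's)."""

    tolerance: float = 100.0
    tolerance_unit: str = "ppm"  # "ppm" or "Da"
    tag: Union[str, float, FluorescentTag] = TAG_PROCA
    label_threshold: float = 3.0  # % of base peak
    fragment_charges: Tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("mass tolerance must be positive")
        if self.tolerance_unit not in ("ppm", "Da"):
            raise ValueError("tolerance unit must be 'ppm' or 'Da'")
        if not 0 <= self.label_threshold <= 100:
            raise ValueError("label threshold must be 0..100%")
        if not self.fragment_charges or any(
            not 1 <= z <= 4 for z in self.fragment_charges
        ):
            raise ValueError("fragment charges must be within 1..4")

    def mz_tolerance(self, mz: float) -> float:
        """Tolerance half-width in m/z units at a given m/z."""
        if self.tolerance_unit == "ppm":
            return mz * self.tolerance * 1e-6
        return self.tolerance


@dataclass(frozen=True)
class FragmentMatch:
    fragment_id: str
    ion_class: str
    charge: int
    adduct: Optional[str]  # None, "+Na", "+K", "-OH"
    theoretical_mz: float
    ppm: float
    cut_count: int
    neutral_mass: float


@dataclass
class PeakAnnotation:
    """A spectrum stick above threshold and its (<= 2) fragment matches."""

    mz: float
    intensity: float
    relative_intensity: float
    matches: List[FragmentMatch] = field(default_factory=list)


@dataclass
class MS2Result:
    """Confirmation outcome and Details statistics for one glycan-RT pair."""

    name: str
    rt: Optional[float]
    precursor_mz: Optional[float]
    charge: Optional[int]
    confirmed: bool
    annotations: List[PeakAnnotation] = field(default_factory=list)
    n_distinct_peaks: int = 0
    n_annotated_peaks: int = 0
    n_qualifying: int = 0
    n_qualifying_matched: int = 0
    percent_identified: Optional[float] = None
    unique_masses_found: Set[float] = field(default_factory=set)
    adducts_found: Set[str] = field(default_factory=set)


def locate_ms2_scan(
    scans: ScanSet, hit: MS1Hit, params: MS2Params = MS2Params()
) -> Optional[Scan]:
    """First matching MS2 scan at or after the hit RT minus 0.1 min.

    A scan matches when its precursor m/z is within tolerance of the
    theoretical [M+zH]z+ of the hit and its precursor charge equals the hit
    charge (scans without a recorded precursor charge match any charge,
    with a warning).
    """
    target_mz = mz_from_mass(hit.theoretical_mass, hit.charge)
    for scan in scans.ms2:
        if scan.rt < hit.rt - PRECURSOR_SEARCH_BACK_MIN:
            continue
        if scan.precursor_mz is None:
            continue
        if abs(scan.precursor_mz - target_mz) > params.mz_tolerance(target_mz):
            continue
        if scan.precursor_charge is None:
            warnings.warn(
                f"MS2 scan {scan.num} lacks a precursor charge; assuming z={hit.charge}"
            )
        elif scan.precursor_charge != hit.charge:
            continue
        return scan
    return None


def _fragment_ion_mz(
    fragment: Fragment, z: int, adduct: Optional[str]
) -> float:
    if adduct is None:
        return mz_from_mass(fragment.neutral_mass, z)
    return adduct_mz(fragment.neutral_mass, adduct, z)


def match_fragments(
    scan: Scan, fragments: FragmentSet, params: MS2Params = MS2Params()
) -> List[PeakAnnotation]:
    """Annotate every above-threshold spectrum stick with <= 2 fragments.

    Candidate ions are each fragment at each allowed charge, plain and with
    each adduct; matches within tolerance are ranked (no-adduct first, then
    |ppm|, then fewer cuts) and the best two kept.  Sticks with no match
    are returned unannotated.
    """
    if scan.ms_level != 2:
        raise ValueError("fragment matching requires an MS2 scan")
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    base = scan.base_peak_intensity
    if base <= 0:
        return []

    # candidate ion table: (m/z, fragment, charge, adduct)
    ions: List[Tuple[float, Fragment, int, Optional[str]]] = []
    for frag in fragments:
        for z in params.fragment_charges:
            for adduct in (None,) + ADDUCTS:
                ions.append((_fragment_ion_mz(frag, z, adduct), frag, z, adduct))
    ions.sort(key=lambda t: t[0])
    ion_mz = np.array([t[0] for t in ions])

    annotations: List[PeakAnnotation] = []
    for mz, inten in zip(scan.mz, scan.intensity):
        rel = 100.0 * inten / base
        if rel < params.label_threshold:
            continue
        half = params.mz_tolerance(mz)
        a = np.searchsorted(ion_mz, mz - half, side="left")
        b = np.searchsorted(ion_mz, mz + half, side="right")
        matches = []
        for k in range(a, b):
            theo, frag, z, adduct = ions[k]
            matches.append(
                FragmentMatch(
                    fragment_id=frag.fragment_id,
                    ion_class=frag.ion_class,
                    charge=z,
                    adduct=adduct,
                    theoretical_mz=theo,
                    ppm=ppm_error(mz, theo),
                    cut_count=frag.cut_count,
                    neutral_mass=frag.neutral_mass,
                )
            )
        matches.sort(
            key=lambda m: (m.adduct is not None, abs(m.ppm), m.cut_count, m.fragment_id)
        )
        annotations.append(
            PeakAnnotation(
                mz=float(mz),
                intensity=float(inten),
                relative_intensity=rel,
                matches=matches[:2],
            )
        )
    return annotations


def _count_distinct_peaks(
    annotations: Sequence[PeakAnnotation], params: MS2Params
) -> int:
    """Above-threshold local maxima after merging sticks within tolerance."""
    if not annotations:
        return 0
    groups = 0
    prev_mz = None
    for ann in annotations:  # already sorted by m/z (scan order)
        if prev_mz is None or ann.mz - prev_mz > params.mz_tolerance(ann.mz):
            groups += 1
        prev_mz = ann.mz
    return groups


def compute_details(
    result: MS2Result,
    fragments: FragmentSet,
    isomer_sets: Iterable[FragmentSet] = (),
    params: MS2Params = MS2Params(),
) -> MS2Result:
    """Fill in the Details statistics of a matched result.

    Percent identified = matched / all qualifying fragments (2+ residues,
    mass unique within the parent's own set); undefined when there are no
    qualifying fragments.  Matched masses are also intersected with the
    masses unique to this parent versus its isomers.
    """
    qualifying = multi_residue_unique_fragments(fragments)
    qual_masses = qualifying.masses()
    matched_ids: Set[str] = set()
    matched_masses: Set[float] = set()
    adducts: Set[str] = set()
    for ann in result.annotations:
        for m in ann.matches:
            matched_masses.add(round(m.neutral_mass, 4))
            if m.adduct is not None:
                adducts.add(m.adduct)
            matched_ids.add(m.fragment_id)

    qual_matched = {f.fragment_id for f in qualifying if f.fragment_id in matched_ids}
    result.n_qualifying = len(qualifying)
    result.n_qualifying_matched = len(qual_matched)
    if len(qualifying) > 0:
        result.percent_identified = 100.0 * len(qual_matched) / len(qualifying)
    else:
        result.percent_identified = None  # undefined, flagged in outputs
    unique_masses = unique_fragment_masses(fragments, isomer_sets)
    result.unique_masses_found = matched_masses & unique_masses
    result.adducts_found = adducts
    result.n_distinct_peaks = _count_distinct_peaks(result.annotations, params)
    result.n_annotated_peaks = sum(1 for a in result.annotations if a.matches)
    return result


def run_ms2(
    scans: ScanSet,
    hits: Sequence[MS1Hit],
    fragment_db: Dict[str, FragmentSet],
    params: MS2Params = MS2Params(),
    select: Union[str, Sequence[Tuple[str, float]]] = "all",
) -> List[MS2Result]:
    """Confirm selected (glycan, RT) pairs against their fragment sets.

    ``select`` is either ``"all"`` (every MS1 hit with a fragment set) or a
    list of (name, rt) pairs drawn from the MS1 output.  Glycans whose MS2
    scan cannot be located are reported unconfirmed.  Isomer context for
    the unique-mass statistic is every other fragment set in the database
    whose parent mass matches within 0.001 Da.
    """
    if select == "all":
        chosen = [h for h in hits if h.name in fragment_db]
    else:
        index = {(h.name, round(h.rt, 3)): h for h in hits}
        chosen = []
        for name, rt in select:
            key = (name, round(rt, 3))
            if key not in index:
                raise KeyError(f"selection {name!r}@{rt} not found in MS1 hits")
            if name not in fragment_db:
                raise KeyError(f"no fragment set for glycan {name!r}")
            chosen.append(index[key])

    results: List[MS2Result] = []
    for hit in chosen:
        fragments = fragment_db[hit.name]
        isomer_sets = [
            fs
            for other, fs in fragment_db.items()
            if other != hit.name and abs(fs.parent_mass - fragments.parent_mass) <= 0.001
        ]
        scan = locate_ms2_scan(scans, hit, params)
        if scan is None:
            results.append(
                MS2Result(
                    name=hit.name,
                    rt=None,
                    precursor_mz=None,
                    charge=hit.charge,
                    confirmed=False,
                )
            )
            continue
        result = MS2Result(
            name=hit.name,
            rt=scan.rt,
            precursor_mz=scan.precursor_mz,
            charge=hit.charge,
            confirmed=True,
            annotations=match_fragments(scan, fragments, params),
        )
        results.append(compute_details(result, fragments, isomer_sets, params))
    return results
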