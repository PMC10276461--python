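"""Synthetic LC-MS/MS run generator with planted glycans.

Builds complete, deterministic test runs — MS1 scans with Gaussian elution
profiles of labeled-glycan sticks, MS2 scans containing a planted subset
of the true fragment ions plus sub-threshold noise, a matching LC
fluorescence trace, a MALDI peak list — together with the databases and a
truth table for automated scoring.  Everything any pipeline stage consumes
can be synthesised here; no external data is required.

The generator plants single-isotope sticks (no isotope envelopes — the
search operates on single m/z windows) and uniform random noise sticks
whose m/z values are kept away from every searched window so threshold
behaviour is exercised without seed-lottery false positives.

Default conditions mirror the instrument settings of the motivating
workflow: procainamide tag, m/z range 500-2000, charge 2 precursors,
isomer peaks a few tenths of a minute apart with apex intensities spanning
7.6e6 down to a few 1e5 counts, and mass errors of a few ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .fragments import (
    FragmentSet,
    enumerate_fragments,
    multi_residue_unique_fragments,
    parse_structure_code,
)
from .io import LCTrace, MS1DatabaseEntry, Scan, ScanSet, write_mzxml
from .masses import (
    ADDUCT_DELTAS,
    FluorescentTag,
    TAG_PROCA,
    get_tag,
    labeled_neutral_mass,
    mz_from_mass,
)

__all__ = [
    "PlantSpec",
    "make_run",
    "make_lc_trace",
    "make_maldi_peaklist",
    "study_plants",
    "write_run_files",
    "MZ_RANGE",
]

#: Instrument m/z acquisition range.
MZ_RANGE = (500.0, 2000.0)

#: Default chromatographic peak sigma, minutes.
DEFAULT_WIDTH_MIN = 0.06

#: Default MS1 scan spacing, minutes.
DEFAULT_RT_GRID = 0.02


@dataclass
class PlantSpec:
    """One glycan planted into a synthetic run.

    ``rts`` lists one retention time per isomer peak; ``apexes`` the
    matching apex intensities.  ``ms2_fragments`` limits which true
    fragments are planted into the MS2 scan (None = every qualifying
    fragment).
    """

    name: str
    composition: Dict[str, int]
    structure_code: Optional[str] = None
    rts: Sequence[float] = (13.39,)
    apexes: Sequence[float] = (7.59e6,)
    width_min: float = DEFAULT_WIDTH_MIN
    charges: Sequence[int] = (2,)
    jitter_ppm: float = 3.0
    plant_signal: bool = True  # False: name shares another plant's MS1 signal
    plant_ms2: bool = True
    ms2_fragments: Optional[int] = None
    ms2_noise_peaks: int = 10
    ms2_noise_rel_max: float = 2.5  # % of base peak; below the 3% threshold

    def __post_init__(self) -> None:
        if len(self.rts) != len(self.apexes):
            raise ValueError(f"{self.name}: rts and apexes lengths differ")
        if self.width_min <= 0:
            raise ValueError(f"{self.name}: peak width must be positive")
        if self.jitter_ppm < 0:
            raise ValueError(f"{self.name}: jitter must be >= 0")

    def labeled_mass(self, tag: Union[str, float, FluorescentTag] = TAG_PROCA) -> float:
        return labeled_neutral_mass(self.composition, tag)


def _protected_windows(masses: Sequence[float], charges=(1, 2, 3, 4)) -> List[float]:
    """m/z values noise must stay away from (all searched charge states)."""
    out = []
    for m in masses:
        for z in charges:
            mz = mz_from_mass(m, z)
            if MZ_RANGE[0] - 1 <= mz <= MZ_RANGE[1] + 1:
                out.append(mz)
    return out


def _draw_noise_mz(rng: np.random.Generator, n: int, protected: Sequence[float]) -> np.ndarray:
    """Uniform noise m/z positions at least 100 ppm from protected values."""
    prot = np.asarray(sorted(protected))
    out: List[float] = []
    while len(out) < n:
        mz = rng.uniform(*MZ_RANGE)
        if prot.size and np.min(np.abs(prot - mz)) < mz * 100e-6:
            continue
        out.append(mz)
    return np.asarray(out)


def make_run(
    seed: int,
    plants: Sequence[PlantSpec],
    rt_grid: float = DEFAULT_RT_GRID,
    rt_span: Optional[Tuple[float, float]] = None,
    tag: Union[str, float, FluorescentTag] = TAG_PROCA,
    noise_peaks_per_scan: int = 5,
    noise_intensity: Tuple[float, float] = (5e3, 5e4),
    decoy_masses: Sequence[float] = (),
    lc_offset: float = 0.0,
) -> Tuple[ScanSet, LCTrace, pd.DataFrame]:
    """Synthesise a full run: (scans, LC trace, truth table).

    The truth table has one row per planted (glycan, isomer peak, charge)
    with the planted RT, m/z and apex intensity — the ground truth for
    true/false-positive scoring.  ``decoy_masses`` are only used to keep
    noise sticks out of their search windows.
    """
    rng = np.random.default_rng(seed)
    tag = get_tag(tag)
    if not plants:
        raise ValueError("at least one plant is required")
    all_rts = [rt for p in plants for rt in p.rts]
    if rt_span is None:
        rt_span = (min(all_rts) - 2.5, max(all_rts) + 2.5)

    masses = [p.labeled_mass(tag) for p in plants]
    protected = _protected_windows(list(masses) + list(decoy_masses))

    # fixed mass jitter per mass class (same molecule, same calibration
    # error): shared-mass isomers present one consistent observed m/z
    jitters: Dict[float, float] = {}
    for p in plants:
        key = round(p.labeled_mass(tag), 3)
        if key not in jitters:
            jitters[key] = rng.uniform(-p.jitter_ppm, p.jitter_ppm)

    truth_rows = []
    sticks_per_plant: List[Tuple[PlantSpec, int, float]] = []  # (plant, z, mz)
    for p, mass in zip(plants, masses):
        for z in p.charges:
            jitter = jitters[round(mass, 3)]
            mz = mz_from_mass(mass, z) * (1 + jitter * 1e-6)
            if not MZ_RANGE[0] <= mz <= MZ_RANGE[1]:
                continue
            if p.plant_signal:
                sticks_per_plant.append((p, z, mz))
            for k, (rt, apex) in enumerate(zip(p.rts, p.apexes), start=1):
                truth_rows.append(
                    {
                        "name": p.name,
                        "isomer_peak": k,
                        "rt": rt,
                        "charge": z,
                        "mz": mz,
                        "labeled_mass": mass,
                        "apex_intensity": apex,
                        "jitter_ppm": jitter,
                    }
                )

    scans: List[Scan] = []
    num = 0
    rt_values = np.arange(rt_span[0], rt_span[1] + 0.5 * rt_grid, rt_grid)
    for rt in rt_values:
        num += 1
        mzs: List[float] = []
        intens: List[float] = []
        for p, z, mz in sticks_per_plant:
            y = 0.0
            for rt0, apex in zip(p.rts, p.apexes):
                y += apex * float(np.exp(-0.5 * ((rt - rt0) / p.width_min) ** 2))
            if y >= 1.0:
                mzs.append(mz)
                intens.append(y)
        noise_mz = _draw_noise_mz(rng, noise_peaks_per_scan, protected)
        noise_y = rng.uniform(*noise_intensity, size=noise_peaks_per_scan)
        mzs.extend(noise_mz.tolist())
        intens.extend(noise_y.tolist())
        scans.append(
            Scan(num=num, ms_level=1, rt=float(rt), mz=np.array(mzs), intensity=np.array(intens))
        )

    # MS2 scans: one per planted (glycan, isomer RT) shortly after the apex
    for p, mass in zip(plants, masses):
        if not p.plant_ms2 or p.structure_code is None:
            continue
        frag_set = enumerate_fragments(
            parse_structure_code(p.structure_code, p.name), tag=tag
        )
        planted = list(multi_residue_unique_fragments(frag_set))
        if p.ms2_fragments is not None:
            planted = planted[: p.ms2_fragments]
        if not planted:
            continue
        z = p.charges[0]
        prec_mz = mz_from_mass(mass, z)
        for rt0 in p.rts:
            num += 1
            rels = np.linspace(100.0, 10.0, num=len(planted))
            frag_mz = np.array(
                [
                    mz_from_mass(f.neutral_mass, 1)
                    * (1 + rng.uniform(-p.jitter_ppm, p.jitter_ppm) * 1e-6)
                    for f in planted
                ]
            )
            base = 1e5
            noise_mz = _draw_noise_mz(
                rng,
                p.ms2_noise_peaks,
                [mz_from_mass(f.neutral_mass, 1) for f in frag_set],
            )
            noise_y = rng.uniform(0.2, p.ms2_noise_rel_max, size=p.ms2_noise_peaks)
            scans.append(
                Scan(
                    num=num,
                    ms_level=2,
                    rt=rt0 + 0.05,
                    mz=np.concatenate([frag_mz, noise_mz]),
                    intensity=np.concatenate([rels, noise_y]) * base / 100.0,
                    precursor_mz=prec_mz,
                    precursor_charge=z,
                )
            )

    lc = make_lc_trace(plants, rt_span, offset=lc_offset)
    truth = pd.DataFrame(truth_rows)
    return ScanSet(scans), lc, truth


def make_lc_trace(
    plants: Sequence[PlantSpec],
    rt_span: Tuple[float, float],
    grid: float = 0.01,
    offset: float = 0.0,
) -> LCTrace:
    """Fluorescence trace with one bump per planted isomer peak.

    ``offset`` shifts the LC time base relative to the MS time base, as a
    real split-flow detector does; alignment must recover it.
    """
    rt = np.arange(rt_span[0] + offset, rt_span[1] + offset, grid)
    y = np.zeros_like(rt)
    for p in plants:
        for rt0, apex in zip(p.rts, p.apexes):
            y += apex * np.exp(-0.5 * ((rt - (rt0 + offset)) / p.width_min) ** 2)
    return LCTrace(rt=rt, intensity=y)


def make_maldi_peaklist(
    seed: int,
    db: Sequence[MS1DatabaseEntry],
    jitter_da: float = 0.3,
    ion_mass: float = ADDUCT_DELTAS["+Na"],
    intensity_range: Tuple[float, float] = (1e3, 1e5),
    n_noise: int = 0,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Synthetic MALDI peak list: one sodiated peak per database glycan.

    Returns (m/z, intensity, truth).  TOF mass error is modelled as a
    calibration-style systematic displacement: every peak is shifted by
    ``jitter_da`` in magnitude with a random sign, so the planted error is
    exactly the stated value rather than scattering toward zero.
    """
    rng = np.random.default_rng(seed)
    rows = []
    mzs, intens = [], []
    for entry in db:
        mz = entry.mass + ion_mass + jitter_da * rng.choice([-1.0, 1.0])
        inten = rng.uniform(*intensity_range)
        mzs.append(mz)
        intens.append(inten)
        rows.append({"name": entry.name, "mass": entry.mass, "mz": mz, "intensity": inten})
    for _ in range(n_noise):
        mzs.append(rng.uniform(1200.0, 6000.0))
        intens.append(rng.uniform(*intensity_range) * 0.01)
    mzs = np.asarray(mzs)
    intens = np.asarray(intens)
    order = np.argsort(mzs)
    return mzs[order], intens[order], pd.DataFrame(rows)


# -- the reference study scenario ------------------------------------------

#: Ten glycans: a three-membered isomer mass class (monogalactosylated
#: fucosylated biantennary arms plus the hybrid of the same composition)
#: eluting 0.3-0.4 min apart, and seven singletons of distinct mass.
_STUDY_GLYCANS: List[Tuple[str, Dict[str, int], Optional[str]]] = [
    (
        "A1G1F(a1,6)",
        {"HeN": 4, "Hex": 4, "Fuc": 1},
        "GlN(Fuc)GlN Man(Man[a1,3] GlN)(Man[a1,6] GlN Gal)",
    ),
    (
        "A1G1F(a1,3)",
        {"HeN": 4, "Hex": 4, "Fuc": 1},
        "GlN(Fuc)GlN Man(Man[a1,3] GlN Gal)(Man[a1,6] GlN)",
    ),
    (
        "A2G0M4F",
        {"HeN": 4, "Hex": 4, "Fuc": 1},
        "GlN(Fuc)GlN Man(Man[a1,3] GlN)(Man[a1,6](Man) GlN)",
    ),
    ("M5", {"HeN": 2, "Hex": 5}, "GlN GlN Man(Man Man)(Man(Man))"),
    ("M6", {"HeN": 2, "Hex": 6}, "GlN GlN Man(Man Man)(Man(Man)(Man))"),
    ("A2G0", {"HeN": 4, "Hex": 3}, "GlN GlN Man(Man GlN)(Man GlN)"),
    ("A2G0F", {"HeN": 4, "Hex": 3, "Fuc": 1}, "GlN(Fuc)GlN Man(Man GlN)(Man GlN)"),
    ("A2G1", {"HeN": 4, "Hex": 4}, "GlN GlN Man(Man GlN Gal)(Man GlN)"),
    ("A2G2F", {"HeN": 4, "Hex": 5, "Fuc": 1}, "GlN(Fuc)GlN Man(Man GlN Gal)(Man GlN Gal)"),
    ("A2G2", {"HeN": 4, "Hex": 5}, "GlN GlN Man(Man GlN Gal)(Man GlN Gal)"),
]


def study_plants(
    tag: Union[str, float, FluorescentTag] = TAG_PROCA,
) -> Tuple[List[PlantSpec], List[MS1DatabaseEntry], List[MS1DatabaseEntry]]:
    """The reference planted-run scenario: (plants, database, decoys).

    Ten glycans, three of which share one labeled mass and elute as isomer
    peaks at 13.39 / 13.78 / 14.08 min with apex intensities spanning two
    orders of magnitude; seven singletons spread over the run.  Decoys are
    ten masses at least 50 ppm away from every planted mass.
    """
    tag = get_tag(tag)
    trio_rts = (13.39, 13.78, 14.08)
    trio_apexes = (7.59e6, 1.61e6, 3.6e5)
    plants: List[PlantSpec] = []
    db: List[MS1DatabaseEntry] = []
    single_rts = [10.5, 11.2, 11.9, 12.6, 15.0, 15.7, 16.4]
    k = 0
    for name, comp, code in _STUDY_GLYCANS:
        mass = labeled_neutral_mass(comp, tag)
        if name in ("A1G1F(a1,6)", "A1G1F(a1,3)", "A2G0M4F"):
            rts, apexes = trio_rts, trio_apexes
        else:
            rts, apexes = (single_rts[k],), (rng_free_apex(k),)
            k += 1
        plants.append(
            PlantSpec(
                name=name,
                composition=comp,
                structure_code=code,
                rts=rts,
                apexes=apexes,
            )
        )
        db.append(MS1DatabaseEntry(name=name, mass=mass))

    # the three isomers are one molecule chromatographically: only the
    # first plants MS1 signal and MS2 scans; the rest share its peaks but
    # stay in the truth table as expected identifications
    shared = {"A1G1F(a1,6)", "A1G1F(a1,3)", "A2G0M4F"}
    seen_shared = False
    for p in plants:
        if p.name in shared:
            if seen_shared:
                p.plant_signal = False
                p.plant_ms2 = False
            seen_shared = True

    planted_masses = sorted({e.mass for e in db})
    decoys: List[MS1DatabaseEntry] = []
    i = 0
    while len(decoys) < 10:
        base = planted_masses[i % len(planted_masses)]
        candidate = base * (1 + (150e-6 * (1 + i // len(planted_masses))))
        if all(abs(candidate - m) / m > 50e-6 for m in planted_masses):
            decoys.append(MS1DatabaseEntry(name=f"decoy{len(decoys) + 1}", mass=candidate))
        i += 1
    return plants, db, decoys


def rng_free_apex(k: int) -> float:
    """Deterministic spread of singleton apex intensities, 5e5..4e6."""
    return 5e5 * (1 + 0.9 * k)


def write_run_files(
    outdir: Union[str, Path],
    seed: int,
    plants: Sequence[PlantSpec],
    db: Sequence[MS1DatabaseEntry],
    tag: Union[str, float, FluorescentTag] = TAG_PROCA,
    decoys: Sequence[MS1DatabaseEntry] = (),
    lc_offset: float = 0.0,
) -> Dict[str, Path]:
    """Write run.mzXML, lc.csv, db.csv, fragdb.csv, maldi.csv and truth.csv."""
    from .io import write_fragment_db

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scans, lc, truth = make_run(
        seed, plants, tag=tag, decoy_masses=[d.mass for d in decoys], lc_offset=lc_offset
    )
    paths = {
        "run": outdir / "run.mzXML",
        "lc": outdir / "lc.csv",
        "db": outdir / "db.csv",
        "fragdb": outdir / "fragdb.csv",
        "maldi": outdir / "maldi.csv",
        "truth": outdir / "truth.csv",
    }
    write_mzxml(scans, paths["run"])
    pd.DataFrame({"rt_min": lc.rt, "intensity": lc.intensity}).to_csv(
        paths["lc"], index=False
    )
    rows = [{"name": e.name, "mass_Da": e.mass, "rt_min": e.rt or ""} for e in db] + [
        {"name": d.name, "mass_Da": d.mass, "rt_min": ""} for d in decoys
    ]
    pd.DataFrame(rows).to_csv(paths["db"], index=False)
    frag_sets = [
        enumerate_fragments(parse_structure_code(p.structure_code, p.name), tag=tag)
        for p in plants
        if p.structure_code is not None
    ]
    write_fragment_db(frag_sets, paths["fragdb"])
    mz, inten, maldi_truth = make_maldi_peaklist(seed, db)
    pd.DataFrame({"mz": mz, "intensity": inten}).to_csv(paths["maldi"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
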