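"""MALDI-TOF peak identification for permethylated glycans.

A MALDI run yields a single peak list of intact glycan ions — for
permethylated glycans in DHB matrix, dominantly sodiated [M+Na]+ species.
Matching is Da-scale (TOF mass error grows with m/z, so a fixed-Da window
is the field's convention here): every above-threshold peak within
tolerance of a database mass yields a hit, and one peak may legitimately
match several same-mass database glycans (double assignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from .io import MS1DatabaseEntry
from .masses import (
    ADDUCT_DELTAS,
    PROTON_MASS,
    WATER_MASS,
    composition_residue_mass,
)

__all__ = [
    "MALDIParams",
    "MALDIHit",
    "run_maldi",
    "permethylated_mass",
    "DEFAULT_METHYL_SITES",
]

#: Mass added per methylation (CH2), Da.
METHYL_DELTA = 14.015650064

#: Default permethylation site counts per in-chain residue, by code class.
#: These are composition-level approximations (linkage positions shift the
#: true count by +-1 per branch point); real databases should supply their
#: own counts or tabled permethylated masses directly.
DEFAULT_METHYL_SITES: Dict[str, int] = {
    "Xyl": 2,
    "Fuc": 2,
    "Gal": 3,
    "Man": 3,
    "Hex": 3,
    "GaN": 3,
    "GlN": 3,
    "HeN": 3,
    "NAN": 5,
    "NGN": 6,
}


@dataclass(frozen=True)
class MALDIParams:
    """MALDI matching settings: Da-scale tolerance, sodiated by default."""

    tolerance: float = 1.0
    tolerance_unit: str = "Da"  # "Da" or "ppm"
    threshold_type: str = "relative"
    threshold: float = 0.0
    ion_form: str = "[M+Na]+"  # or "[M+H]+"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.tolerance_unit not in ("Da", "ppm"):
            raise ValueError("tolerance unit must be 'Da' or 'ppm'")
        if self.threshold_type not in ("relative", "absolute"):
            raise ValueError("threshold type must be 'relative' or 'absolute'")
        if self.ion_form not in ("[M+Na]+", "[M+H]+"):
            raise ValueError("ion form must be '[M+Na]+' or '[M+H]+'")

    @property
    def adduct_mass(self) -> float:
        if self.ion_form == "[M+Na]+":
            return ADDUCT_DELTAS["+Na"]
        return PROTON_MASS


@dataclass(frozen=True)
class MALDIHit:
    name: str
    theoretical_mass: float
    observed_mass: float
    observed_mz: float
    mass_error: float  # Da, signed
    intensity: float
    relative_intensity: float


def run_maldi(
    peaks_mz: np.ndarray,
    peaks_intensity: np.ndarray,
    db: Sequence[MS1DatabaseEntry],
    params: MALDIParams = MALDIParams(),
) -> List[MALDIHit]:
    """Match a database of permethylated glycan masses to one peak list.

    Database masses are neutral permethylated masses; the expected m/z is
    mass + Na+ (or + H+).  Every peak above the intensity threshold and
    within tolerance of an expected m/z produces a hit, so one peak can be
    assigned to multiple same-mass glycans.
    """
    peaks_mz = np.asarray(peaks_mz, dtype=float)
    peaks_intensity = np.asarray(peaks_intensity, dtype=float)
    if peaks_mz.size == 0:
        warnings.warn("empty MALDI peak list")
        return []
    base = float(peaks_intensity.max())
    if params.threshold_type == "relative":
        floor = params.threshold / 100.0 * base
    else:
        floor = params.threshold

    hits: List[MALDIHit] = []
    for entry in db:
        expected_mz = entry.mass + params.adduct_mass
        tol = (
            params.tolerance
            if params.tolerance_unit == "Da"
            else expected_mz * params.tolerance * 1e-6
        )
        for mz, inten in zip(peaks_mz, peaks_intensity):
            if inten < floor:
                continue
            if abs(mz - expected_mz) > tol:
                continue
            observed_mass = mz - params.adduct_mass
            hits.append(
                MALDIHit(
                    name=entry.name,
                    theoretical_mass=entry.mass,
                    observed_mass=observed_mass,
                    observed_mz=float(mz),
                    mass_error=observed_mass - entry.mass,
                    intensity=float(inten),
                    relative_intensity=100.0 * float(inten) / base if base else 0.0,
                )
            )
    return hits


def permethylated_mass(
    composition: Mapping[str, int],
    reduced_end: bool = False,
    site_counts: Optional[Mapping[str, int]] = None,
) -> float:
    """Neutral mass of a permethylated free glycan from its composition.

    free mass + 14.01565 x total methylation sites, with per-code site
    counts taken from ``site_counts`` (default
    :data:`DEFAULT_METHYL_SITES`).  ``reduced_end`` adds one extra site for
    the additional hydroxyl of a reduced (alditol) reducing end.
    """
    if not composition or all(n == 0 for n in composition.values()):
        raise ValueError("empty glycan composition")
    sites = DEFAULT_METHYL_SITES if site_counts is None else site_counts
    free_mass = composition_residue_mass(composition) + WATER_MASS
    total_sites = 1 if reduced_end else 0
    for code, count in composition.items():
        if code not in sites:
            raise KeyError(f"no methylation site count configured for {code!r}")
        total_sites += sites[code] * count
    return free_mass + METHYL_DELTA * total_sites
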