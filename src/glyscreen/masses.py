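"""Monoisotopic mass arithmetic for labeled N-glycans.

Every other module builds on this one: elemental masses, the monosaccharide
registry (3-letter codes as used in glycan structure codes), fluorescent-tag
conventions for reductively aminated glycans, m/z <-> neutral-mass conversion
and ppm error, and adduct m/z (+Na, +K, -OH).

Conventions
-----------
* All masses are monoisotopic, in daltons.
* A *full* monosaccharide mass is the free sugar (e.g. hexose C6H12O6); the
  *residue* mass is full mass minus water, i.e. the increment a residue adds
  inside a chain.
* The tabled mass of a fluorescent tag (2-AB 138.0793, procainamide 237.1841)
  absorbs both the terminal water of the reducing-end residue and the net +2H
  of reductive amination, so a labeled glycan's neutral mass is simply
  ``sum(residue masses) + tag mass``.  A "custom" tag of mass 18.0106 Da
  (water) therefore recovers the free, unlabeled glycan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple, Union

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "WATER_MASS",
    "ADDUCT_DELTAS",
    "Monosaccharide",
    "FluorescentTag",
    "MONOSACCHARIDES",
    "TAGS",
    "parse_formula",
    "monoisotopic_mass",
    "residue_mass",
    "composition_residue_mass",
    "labeled_neutral_mass",
    "mz_from_mass",
    "mass_from_mz",
    "ppm_error",
    "adduct_mz",
    "register_monosaccharides_from_table",
]

#: Monoisotopic masses of the supported elements, Da (CODATA/AME values).
ELEMENT_MASSES: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton (H+), Da.  Distinct from the hydrogen *atom* mass: m/z
#: arithmetic at ppm accuracy needs the electron removed.
PROTON_MASS: float = 1.007276467

#: Monoisotopic mass of water, Da.
WATER_MASS: float = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]

#: Electron mass, Da.
ELECTRON_MASS: float = 0.00054857990

#: Neutral-mass deltas for the supported adduct species, Da.  "+Na" / "+K"
#: replace the charging proton by a metal cation; "-OH" is a neutral hydroxyl
#: loss (17.00274 Da) before normal protonation.
ADDUCT_DELTAS: Dict[str, float] = {
    "+Na": ELEMENT_MASSES["Na"] - ELECTRON_MASS,   # 22.98922 as cation
    "+K": ELEMENT_MASSES["K"] - ELECTRON_MASS,     # 38.96316 as cation
    "-OH": -(ELEMENT_MASSES["O"] + ELEMENT_MASSES["H"]),
    "-H2O": -WATER_MASS,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: Union[str, Mapping[str, int]]) -> Dict[str, int]:
    """Parse a Hill-style elemental formula ("C6H12O5") into counts.

    Already-parsed mappings pass through unchanged.  Unknown element symbols
    are rejected by name.
    """
    if isinstance(formula, Mapping):
        counts = dict(formula)
    else:
        counts = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise ValueError(
                    f"cannot parse formula {formula!r} at position {pos}"
                )
            pos = match.end()
            sym, num = match.group(1), match.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    for sym, n in counts.items():
        if sym not in ELEMENT_MASSES:
            raise ValueError(f"unknown element symbol {sym!r}")
        if n < 0:
            raise ValueError(f"negative count for element {sym!r}")
    return counts


def monoisotopic_mass(formula: Union[str, Mapping[str, int]]) -> float:
    """Monoisotopic mass (Da) of an elemental composition.

    >>> round(monoisotopic_mass("C6H12O5"), 4)   # fucose
    164.0685
    """
    counts = parse_formula(formula)
    return sum(ELEMENT_MASSES[sym] * n for sym, n in counts.items())


@dataclass(frozen=True)
class Monosaccharide:
    """A registered monosaccharide: 3-letter code, formula, masses.

    ``full_mass`` is the free sugar; ``residue_mass`` = full - water is the
    in-chain increment.  Several codes share one mass (Gal/Man/Hex;
    GaN/GlN/HeN): isomer logic downstream compares masses, never codes.
    """

    id_code: str
    name: str
    formula: str
    snfg: Tuple[str, str] = ("circle", "#808080")  # (shape, color) cartoon key

    @property
    def full_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def residue_mass(self) -> float:
        return self.full_mass - WATER_MASS


#: Built-in monosaccharide registry.  SNFG-style shape/color keys drive the
#: cartoon renderer; generic Hex/HeN render grey.
MONOSACCHARIDES: Dict[str, Monosaccharide] = {
    m.id_code: m
    for m in [
        Monosaccharide("Xyl", "xylose", "C5H10O5", ("star", "#F47920")),
        Monosaccharide("Fuc", "fucose", "C6H12O5", ("triangle", "#ED1C24")),
        Monosaccharide("Gal", "galactose", "C6H12O6", ("circle", "#FFD400")),
        Monosaccharide("Man", "mannose", "C6H12O6", ("circle", "#00A651")),
        Monosaccharide("Hex", "hexose", "C6H12O6", ("circle", "#FFFFFF")),
        Monosaccharide("GaN", "N-acetylgalactosamine", "C8H15NO6", ("square", "#FFD400")),
        Monosaccharide("GlN", "N-acetylglucosamine", "C8H15NO6", ("square", "#0072BC")),
        Monosaccharide("HeN", "N-acetylhexosamine", "C8H15NO6", ("square", "#FFFFFF")),
        Monosaccharide("NAN", "N-acetylneuraminic acid", "C11H19NO9", ("diamond", "#A54399")),
        Monosaccharide("NGN", "N-glycolylneuraminic acid", "C11H19NO10", ("diamond", "#8FCCE9")),
    ]
}


@dataclass(frozen=True)
class FluorescentTag:
    """Reducing-end fluorescent label.

    ``mass`` is the tabled tag mass (label + 2H of reductive amination plus
    the terminal water it replaces), so labeled mass = residues + tag mass.
    """

    name: str
    mass: float
    is_custom: bool = False

    def __post_init__(self):
        if self.mass < 0:
            raise ValueError("tag mass must be >= 0")

    @classmethod
    def custom(cls, mass: float) -> "FluorescentTag":
        return cls(f"custom({mass:g})", float(mass), is_custom=True)


TAG_2AB = FluorescentTag("2-AB", 138.0793)
TAG_PROCA = FluorescentTag("ProCA", 237.1841)
#: A custom tag equal to water expresses a free (unlabeled) glycan.
TAG_FREE = FluorescentTag("free", round(WATER_MASS, 4), is_custom=True)

TAGS: Dict[str, FluorescentTag] = {
    "2-AB": TAG_2AB,
    "2AB": TAG_2AB,
    "ProCA": TAG_PROCA,
    "PROCA": TAG_PROCA,
    "free": TAG_FREE,
}


def get_tag(spec: Union[str, float, FluorescentTag]) -> FluorescentTag:
    """Resolve a tag from a name ('ProCA'), a bare mass, or a tag object."""
    if isinstance(spec, FluorescentTag):
        return spec
    if isinstance(spec, (int, float)):
        return FluorescentTag.custom(float(spec))
    key = spec.strip()
    if key in TAGS:
        return TAGS[key]
    if key.upper() in TAGS:
        return TAGS[key.upper()]
    if key.lower().startswith("custom:"):
        return FluorescentTag.custom(float(key.split(":", 1)[1]))
    raise KeyError(f"unknown fluorescent tag {spec!r}")


def residue_mass(code: str) -> float:
    """Residue (in-chain) mass of a registered monosaccharide code, Da."""
    try:
        return MONOSACCHARIDES[code].residue_mass
    except KeyError:
        raise KeyError(f"unknown monosaccharide code {code!r}") from None


def composition_residue_mass(composition: Mapping[str, int]) -> float:
    """Summed residue mass of a composition {code: count}, Da."""
    total = 0.0
    for code, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for {code!r}")
        total += count * residue_mass(code)
    return total


def labeled_neutral_mass(
    composition: Mapping[str, int], tag: Union[str, float, FluorescentTag]
) -> float:
    """Neutral mass (Da) of a labeled glycan: sum of residues + tag mass.

    >>> round(labeled_neutral_mass({"HeN": 4, "Hex": 4, "Fuc": 1}, "ProCA"), 1)
    1843.8
    """
    if not composition or all(n == 0 for n in composition.values()):
        raise ValueError("empty glycan composition")
    return composition_residue_mass(composition) + get_tag(tag).mass


MAX_CHARGE = 4


def _check_charge(z: int) -> None:
    if not (1 <= int(z) <= MAX_CHARGE):
        raise ValueError(f"charge must be in 1..{MAX_CHARGE}, got {z}")


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion of a neutral mass."""
    _check_charge(z)
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral_mass + z * PROTON_MASS) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass recovered from an observed [M + zH]^z+ m/z."""
    _check_charge(z)
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return z * mz - z * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def adduct_mz(neutral_mass: float, adduct: str, z: int) -> float:
    """m/z of an adducted ion of a neutral mass.

    "+Na" and "+K" substitute one charging proton with the metal cation;
    "-OH" (and the alternative "-H2O") are neutral losses followed by normal
    protonation at charge ``z``.
    """
    _check_charge(z)
    if adduct not in ADDUCT_DELTAS:
        raise ValueError(f"unsupported adduct {adduct!r}; use one of {sorted(ADDUCT_DELTAS)}")
    delta = ADDUCT_DELTAS[adduct]
    if adduct in ("+Na", "+K"):
        return (neutral_mass + delta + (z - 1) * PROTON_MASS) / z
    return (neutral_mass + delta + z * PROTON_MASS) / z


def register_monosaccharides_from_table(path: Union[str, Path]) -> None:
    """Extend the monosaccharide registry from a CSV config file.

    Columns: ``id_code, formula`` with optional ``name``.  Existing codes are
    overwritten; masses always derive from the formula.
    """
    import pandas as pd

    table = pd.read_csv(path)
    for _, row in table.iterrows():
        code = str(row["id_code"]).strip()
        formula = str(row["formula"]).strip()
        parse_formula(formula)  # validate early
        name = str(row["name"]) if "name" in table.columns else code
        MONOSACCHARIDES[code] = Monosaccharide(code, name, formula)
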