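"""Elemental formulas and monoisotopic masses of (cyclic) core peptides,
with amatoxin-style modification sets and ppm matching against MS1 peaks.

The chemistry here is deliberately small: amatoxins are head-to-tail
cyclized octa-ish peptides carrying a tryptathionine (Trp-Cys) cross-bridge
(net -2H), several hydroxylations and one sulfoxide (each +1O). The
"amatoxin" preset (-2H +5O) turns cyclo(IWGIGCNP) into the alpha-amanitin
formula C39H54N10O14S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .seqio import PeakList

__all__ = [
    "ElementalFormula",
    "ModSet",
    "MassMatch",
    "AMINO_ACID_FORMULAS",
    "MONOISOTOPIC_MASS",
    "peptide_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "match_peaks",
    "PRESET_MODS",
]

ELEMENTS = ("C", "H", "N", "O", "S")

# IUPAC/CODATA monoisotopic isotope masses (Da)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

HYDROGEN_ATOM_MASS = 1.0078250319
PROTON_MASS = 1.0072764665


@dataclass(frozen=True)
class ElementalFormula:
    """Non-negative C/H/N/O/S counts; signed deltas use FormulaDelta."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self):
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(
                    f"negative {el} count in formula {self.as_dict()}"
                )

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ELEMENTS}

    def __add__(self, other: "ElementalFormula | FormulaDelta"):
        return ElementalFormula(
            **{el: getattr(self, el) + getattr(other, el) for el in ELEMENTS}
        )

    def __sub__(self, other: "ElementalFormula | FormulaDelta"):
        return ElementalFormula(
            **{el: getattr(self, el) - getattr(other, el) for el in ELEMENTS}
        )

    def __str__(self) -> str:
        parts = []
        for el in ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    @property
    def n_atoms(self) -> int:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class FormulaDelta:
    """Signed elemental delta (e.g. -2H +5O for the amatoxin preset)."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0


WATER = ElementalFormula(H=2, O=1)

# Free amino acid formulas; residue-in-chain = free - H2O.
AMINO_ACID_FORMULAS: Mapping[str, ElementalFormula] = {
    "A": ElementalFormula(3, 7, 1, 2, 0),
    "R": ElementalFormula(6, 14, 4, 2, 0),
    "N": ElementalFormula(4, 8, 2, 3, 0),
    "D": ElementalFormula(4, 7, 1, 4, 0),
    "C": ElementalFormula(3, 7, 1, 2, 1),
    "E": ElementalFormula(5, 9, 1, 4, 0),
    "Q": ElementalFormula(5, 10, 2, 3, 0),
    "G": ElementalFormula(2, 5, 1, 2, 0),
    "H": ElementalFormula(6, 9, 3, 2, 0),
    "I": ElementalFormula(6, 13, 1, 2, 0),
    "L": ElementalFormula(6, 13, 1, 2, 0),
    "K": ElementalFormula(6, 14, 2, 2, 0),
    "M": ElementalFormula(5, 11, 1, 2, 1),
    "F": ElementalFormula(9, 11, 1, 2, 0),
    "P": ElementalFormula(5, 9, 1, 2, 0),
    "S": ElementalFormula(3, 7, 1, 3, 0),
    "T": ElementalFormula(4, 9, 1, 3, 0),
    "W": ElementalFormula(11, 12, 2, 2, 0),
    "Y": ElementalFormula(9, 11, 1, 3, 0),
    "V": ElementalFormula(5, 11, 1, 2, 0),
}


@dataclass
class ModSet:
    """A named set of elemental modifications applied to a peptide.

    Application is additive and order-independent (pure formula deltas).
    """

    name: str
    delta: FormulaDelta

    def apply(self, formula: ElementalFormula) -> ElementalFormula:
        return formula + self.delta


def _mods(name, **kw):
    return ModSet(name, FormulaDelta(**kw))


PRESET_MODS: dict[str, ModSet] = {
    # tryptathionine Trp-Cys cross-bridge: lose 2 H
    "tryptathionine": _mods("tryptathionine", H=-2),
    "hydroxylation": _mods("hydroxylation", O=1),
    "sulfoxide": _mods("sulfoxide", O=1),
    # amatoxin = tryptathionine + 4x hydroxylation + sulfoxide
    "amatoxin": _mods("amatoxin", H=-2, O=5),
}


def peptide_formula(aa_seq: str, topology: str = "linear") -> ElementalFormula:
    """Elemental formula of a peptide.

    linear: sum of residue formulas + one water; head-to-tail cyclic:
    one water fewer (the extra peptide bond).
    """
    if topology not in ("linear", "cyclic", "head-to-tail-cyclic"):
        raise ValueError(f"unknown topology {topology!r}")
    if not aa_seq:
        raise ValueError("empty peptide")
    total = ElementalFormula()
    for aa in aa_seq.upper():
        if aa not in AMINO_ACID_FORMULAS:
            raise ValueError(f"non-standard residue {aa!r} in {aa_seq!r}")
        total = total + AMINO_ACID_FORMULAS[aa] - WATER
    total = total + WATER  # free N/C termini of the linear chain
    if topology != "linear":
        total = total - WATER  # macrolactam closes the ring
    return total


def monoisotopic_mass(formula: ElementalFormula) -> float:
    return sum(
        getattr(formula, el) * MONOISOTOPIC_MASS[el] for el in ELEMENTS
    )


def adduct_mz(neutral_mass: float, adduct: str = "M+H", charge: int = 1,
              proton: bool = False) -> float:
    """m/z of an adduct ion.

    By default each added "H" contributes a hydrogen-*atom* mass
    (1.0078250): 918.3541 + 1.0078250 = 919.3620, the arithmetic the
    study's printed [M+H]+ values follow. ``proton=True`` switches to the
    physically stricter proton mass (1.0072765).
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    unit = PROTON_MASS if proton else HYDROGEN_ATOM_MASS
    if adduct == "M+H":
        n_h = 1
    elif adduct == "M+2H":
        n_h = 2
    elif adduct == "M+3H":
        n_h = 3
    else:
        raise ValueError(f"unknown adduct {adduct!r}")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + n_h * unit) / charge


def ppm_error(observed: float, calculated: float) -> float:
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return 1e6 * (observed - calculated) / calculated


@dataclass(frozen=True)
class MassMatch:
    peak_mz: float
    candidate: str
    calc_mz: float
    ppm: float
    tolerance: float

    def __post_init__(self):
        assert abs(self.ppm) <= self.tolerance


def match_peaks(peaks: PeakList, candidates: Mapping[str, float],
                tol: float = 10.0) -> list[MassMatch]:
    """All (peak, candidate) pairs within ``tol`` ppm.

    ``candidates`` maps a name to its calculated m/z. A peak may match
    several candidates; every match is reported.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    matches = []
    for mz, _ in peaks.peaks:
        for name, calc in candidates.items():
            err = ppm_error(mz, calc)
            if abs(err) <= tol:
                matches.append(MassMatch(mz, name, calc, err, tol))
    return matches
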