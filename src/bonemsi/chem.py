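"""Exact-mass chemistry: elemental formulas, negative-mode adducts, glycan compositions.

All masses are monoisotopic, in daltons.  The element table is restricted to
the elements that occur in small endogenous metabolites and in the adduct
rules used for negative-mode MALDI (9-aminoacridine matrix): C, H, N, O, P,
S, K, Na, Cl.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "parse_formula",
    "neutral_mass",
    "AdductRule",
    "ADDUCT_RULES",
    "adduct_mz",
    "GlycanComposition",
    "GLYCAN_RESIDUES",
    "GLYCAN_MODIFICATIONS",
    "glycan_fragment_mass",
    "glycan_fragment_formula",
]

# IUPAC monoisotopic atomic masses (most abundant isotope), Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "K": 38.9637069,
    "Na": 22.98976928,
    "Cl": 34.96885271,
}

ELECTRON_MASS = 0.00054858
#: Mass removed by deprotonation: H atom minus the electron it leaves behind.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for formulas that cannot be parsed against the element table."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula such as ``C6H12O6`` into counts.

    Multi-letter symbols (Na, Cl) are recognised; repeated element symbols
    accumulate.  Raises :class:`FormulaError` on empty input, unknown
    elements, or stray characters.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable formula {formula!r} at position {pos}"
            )
        pos = match.end()
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def neutral_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic mass of a neutral molecule from its elemental formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    for element, n in counts.items():
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {element!r}")
        if n < 0:
            raise FormulaError(f"negative count for {element}")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class AdductRule:
    """A negative-mode ionisation rule: neutral M -> singly charged anion.

    ``atom_delta`` holds the signed change in atom counts relative to the
    neutral molecule; the ion additionally carries one extra electron
    (charge -1).
    """

    label: str
    atom_delta: dict[str, int] = field(hash=False)
    charge: int = -1

    @property
    def mass_shift(self) -> float:
        """m/z offset applied to the neutral mass (includes the electron)."""
        delta = sum(
            MONOISOTOPIC_MASS[el] * n for el, n in self.atom_delta.items()
        )
        return delta + ELECTRON_MASS * abs(self.charge)


#: The five negative adducts considered during annotation.  "M-H2O" is the
#: deprotonated water-loss ion [M-H2O-H]-; a bare neutral water loss carries
#: no charge and would not be detected.
ADDUCT_RULES: dict[str, AdductRule] = {
    "M-H": AdductRule("M-H", {"H": -1}),
    "M-H2O": AdductRule("M-H2O", {"H": -3, "O": -1}),
    "M+K-2H": AdductRule("M+K-2H", {"K": 1, "H": -2}),
    "M+Na-2H": AdductRule("M+Na-2H", {"Na": 1, "H": -2}),
    "M+Cl": AdductRule("M+Cl", {"Cl": 1}),
}


def adduct_mz(neutral: float, rule: AdductRule | str) -> float:
    """m/z of the singly charged anion formed from a neutral mass.

    Raises ``KeyError`` for an unknown rule label and ``ValueError`` when the
    neutral mass or the resulting ion mass is non-positive (e.g. water losing
    water plus a proton).
    """
    if isinstance(rule, str):
        rule = ADDUCT_RULES[rule]
    if neutral <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral}")
    mz = neutral + rule.mass_shift
    if mz <= 0:
        raise ValueError(
            f"adduct {rule.label} of neutral {neutral} Da gives non-positive m/z"
        )
    return mz


# ---------------------------------------------------------------------------
# Glycan compositions
# ---------------------------------------------------------------------------

#: Residue (dehydrated monosaccharide) elemental formulas.  A residue is the
#: monosaccharide minus one water, i.e. the unit incorporated into a chain.
GLYCAN_RESIDUES: dict[str, str] = {
    "Hex": "C6H10O5",      # hexose (glucose, galactose, mannose, ...)
    "HexNAc": "C8H13NO5",  # N-acetylhexosamine
    "HexA": "C6H8O6",      # hexuronic acid
    "HexN": "C6H11NO4",    # hexosamine
    "dHex": "C6H10O4",     # deoxyhexose (fucose, ...)
    "NeuAc": "C11H17NO8",  # N-acetylneuraminic acid
    "NeuGc": "C11H17NO9",  # N-glycolylneuraminic acid
    "Pen": "C5H8O4",       # pentose
}

#: Substituent modifications as net elemental additions.
GLYCAN_MODIFICATIONS: dict[str, str] = {
    "S": "SO3",     # sulfate (esterification: +SO3)
    "P": "HPO3",    # phosphate
    "Ac": "C2H2O",  # O-acetyl
}

_RESIDUE_ORDER = ["Hex", "HexNAc", "HexA", "HexN", "dHex", "NeuAc", "NeuGc", "Pen"]
_MODIFICATION_ORDER = ["S", "P", "Ac"]


@dataclass(frozen=True)
class GlycanComposition:
    """A glycan fragment given as residue and modification counts.

    Composition-level only: no linkage or branching information, matching
    what accurate mass alone can distinguish.
    """

    residues: tuple[tuple[str, int], ...]
    modifications: tuple[tuple[str, int], ...] = ()
    reducing_end_water: bool = True

    @staticmethod
    def from_counts(
        residues: dict[str, int],
        modifications: dict[str, int] | None = None,
        reducing_end_water: bool = True,
    ) -> "GlycanComposition":
        res = tuple(
            (r, residues[r]) for r in _RESIDUE_ORDER if residues.get(r, 0)
        )
        mods = tuple(
            (m, (modifications or {}).get(m, 0))
            for m in _MODIFICATION_ORDER
            if (modifications or {}).get(m, 0)
        )
        comp = GlycanComposition(res, mods, reducing_end_water)
        comp.validate()
        return comp

    def validate(self) -> None:
        for name, n in self.residues:
            if name not in GLYCAN_RESIDUES:
                raise ValueError(f"unknown residue {name!r}")
            if n < 0:
                raise ValueError(f"negative count for residue {name}")
        for name, n in self.modifications:
            if name not in GLYCAN_MODIFICATIONS:
                raise ValueError(f"unknown modification {name!r}")
            if n < 0:
                raise ValueError(f"negative count for modification {name}")
        if sum(n for _, n in self.residues) <= 0:
            raise ValueError("glycan composition needs at least one residue")

    @property
    def label(self) -> str:
        """Composition label in residue-count nomenclature, e.g. HexNAc1S1."""
        parts = [f"{r}{n}" for r, n in self.residues]
        parts += [f"{m}{n}" for m, n in self.modifications]
        return "".join(parts)


def glycan_fragment_formula(comp: GlycanComposition) -> dict[str, int]:
    """Expanded elemental formula of a glycan composition."""
    comp.validate()
    counts: dict[str, int] = {}

    def _add(formula: str, times: int) -> None:
        for el, n in parse_formula(formula).items():
            counts[el] = counts.get(el, 0) + n * times

    for residue, n in comp.residues:
        _add(GLYCAN_RESIDUES[residue], n)
    for mod, n in comp.modifications:
        _add(GLYCAN_MODIFICATIONS[mod], n)
    if comp.reducing_end_water:
        _add("H2O", 1)
    return counts


def glycan_fragment_mass(comp: GlycanComposition) -> float:
    """Neutral monoisotopic mass of a glycan composition.

    Sum of residue masses (monosaccharide minus water) plus modification
    deltas, plus one water when the reducing end is free.
    """
    return neutral_mass(glycan_fragment_formula(comp))
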