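"""Elemental-composition arithmetic and exact-mass bookkeeping for PC ions.

All masses are monoisotopic (Da).  Ion m/z values are electron-corrected:
an anion gains one electron mass, a cation loses one, which is folded into
the +/-1.00728 proton constants.  Every species handled here is singly
charged; the deuterium (``D``) and oxygen-18 (``[18O]``) isotopes are
tracked as element symbols of their own so that labeled and unlabeled
compositions never mix silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ElementComposition",
    "AdductKind",
    "MzValue",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ISOTOPE_MASSES",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_mass_from_mz",
    "apply_heavy_oxygen",
    "ppm_error",
    "mass_of",
    "H2O",
    "H2O2",
    "H2_18O",
    "METHYL_FORMATE",
    "TRIMETHYLAMINE",
    "CH2",
    "C13_C12_DELTA",
    "O18_O16_DELTA",
]

#: IUPAC/CODATA monoisotopic masses, Da.
ISOTOPE_MASSES: Dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250,
    "D": 2.0141018,
    "N": 14.0030740,
    "O": 15.9949146,
    "[18O]": 17.9991596,
    "P": 30.9737615,
}

ELECTRON_MASS = 0.0005486
#: Mass of H+ (hydrogen atom minus one electron).
PROTON_MASS = ISOTOPE_MASSES["H"] - ELECTRON_MASS

#: Mass gained per 16O -> 18O substitution.
O18_O16_DELTA = ISOTOPE_MASSES["[18O]"] - ISOTOPE_MASSES["O"]
#: 13C - 12C spacing used for isotopologue partner detection.
C13_C12_DELTA = 1.00336

_FORMULA_TOKEN = re.compile(r"\[(?P<iso>\d+[A-Z][a-z]?)\]|(?P<sym>[A-Z][a-z]?)(?P<n>\d*)")


class ChemError(ValueError):
    """Raised on invalid compositions, unknown elements or polarity clashes."""


@dataclass(frozen=True)
class ElementComposition:
    """Immutable bag of element counts.

    Supports ``+``, ``-`` (never negative) and integer ``*``.  Construct
    from keyword counts via :meth:`from_counts` or a Hill-style formula
    string via :meth:`from_formula` (isotopes bracketed, e.g.
    ``"C42H80NO8P"`` or ``"C41H73D7NO8P"`` or ``"[18O]2"``).
    """

    counts: Tuple[Tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        for sym, n in self.counts:
            if sym not in ISOTOPE_MASSES:
                raise ChemError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise ChemError(f"negative count for {sym}: {n}")

    @classmethod
    def from_counts(cls, **counts: int) -> "ElementComposition":
        # O18 keyword maps to the bracketed isotope symbol
        norm = {("[18O]" if k == "O18" else k): v for k, v in counts.items() if v}
        return cls(tuple(sorted(norm.items())))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ChemError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
            pos = m.end()
            if m.group("iso"):
                sym = f"[{m.group('iso')}]"
                tail = formula[pos:]
                nm = re.match(r"\d+", tail)
                n = int(nm.group()) if nm else 1
                pos += nm.end() if nm else 0
            else:
                sym = m.group("sym")
                n = int(m.group("n")) if m.group("n") else 1
            counts[sym] = counts.get(sym, 0) + n
        if pos != len(formula):
            raise ChemError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        return cls(tuple(sorted((k, v) for k, v in counts.items() if v)))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def get(self, symbol: str, default: int = 0) -> int:
        return self.as_dict().get(symbol, default)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        d = self.as_dict()
        for sym, n in other:
            d[sym] = d.get(sym, 0) + n
        return ElementComposition(tuple(sorted((k, v) for k, v in d.items() if v)))

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        d = self.as_dict()
        for sym, n in other:
            d[sym] = d.get(sym, 0) - n
            if d[sym] < 0:
                raise ChemError(
                    f"subtraction yields negative {sym} count ({d[sym]})"
                )
        return ElementComposition(tuple(sorted((k, v) for k, v in d.items() if v)))

    def __mul__(self, k: int) -> "ElementComposition":
        if k < 0:
            raise ChemError("cannot multiply composition by a negative integer")
        return ElementComposition(tuple((sym, n * k) for sym, n in self.counts if n * k))

    __rmul__ = __mul__

    def formula(self) -> str:
        """Hill-ish formula string (C, H first, then alphabetical)."""
        d = self.as_dict()
        order = ["C", "H", "D"] + sorted(k for k in d if k not in ("C", "H", "D"))
        parts = []
        for sym in order:
            n = d.get(sym, 0)
            if n == 0:
                continue
            parts.append(f"{sym}{n if n != 1 else ''}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - display only
        return self.formula()


def monoisotopic_mass(comp: ElementComposition | Mapping[str, int] | str) -> float:
    """Monoisotopic mass of a composition, Da.  Empty composition -> 0.0."""
    if isinstance(comp, str):
        comp = ElementComposition.from_formula(comp)
    elif not isinstance(comp, ElementComposition):
        comp = ElementComposition.from_counts(**dict(comp))
    return sum(ISOTOPE_MASSES[sym] * n for sym, n in comp)


def mass_of(formula: str) -> float:
    """Shorthand: monoisotopic mass of a formula string."""
    return monoisotopic_mass(ElementComposition.from_formula(formula))


# Neutral-loss / delta constants used by fragment rules.
H2O = mass_of("H2O")
H2O2 = mass_of("H2O2")
H2_18O = mass_of("H2[18O]")
METHYL_FORMATE = mass_of("C2H4O2")  # CH3OCHO, lost on PC head-group demethylation
TRIMETHYLAMINE = mass_of("C3H9N")
CH2 = mass_of("CH2")
_FORMATE_ANION = mass_of("CHO2") + ELECTRON_MASS


class AdductKind(Enum):
    """The three singly charged PC adducts used throughout."""

    FORMATE_NEG = "[M+HCOO]-"
    DEPROTONATED_NEG = "[M-H]-"
    PROTONATED_POS = "[M+H]+"

    @property
    def polarity(self) -> str:
        return "+" if self is AdductKind.PROTONATED_POS else "-"

    @property
    def mass_delta(self) -> float:
        """m/z minus neutral mass, electron-corrected."""
        if self is AdductKind.FORMATE_NEG:
            return _FORMATE_ANION
        if self is AdductKind.DEPROTONATED_NEG:
            return -PROTON_MASS
        return PROTON_MASS


@dataclass(frozen=True)
class MzValue:
    """A singly charged m/z value with its polarity ('+' or '-')."""

    value: float
    polarity: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ChemError(f"m/z must be positive, got {self.value}")
        if self.polarity not in ("+", "-"):
            raise ChemError(f"polarity must be '+' or '-', got {self.polarity!r}")


def adduct_mz(neutral_mass: float, adduct: AdductKind) -> MzValue:
    """m/z of an adduct ion of a neutral species of the given mass."""
    if neutral_mass <= 0:
        raise ChemError(f"neutral mass must be positive, got {neutral_mass}")
    return MzValue(neutral_mass + adduct.mass_delta, adduct.polarity)


def neutral_mass_from_mz(mz: MzValue, adduct: AdductKind) -> float:
    """Exact inverse of :func:`adduct_mz`."""
    if mz.polarity != adduct.polarity:
        raise ChemError(f"polarity mismatch: ion {mz.polarity}, adduct {adduct.value}")
    return mz.value - adduct.mass_delta


def apply_heavy_oxygen(comp: ElementComposition, n_labels: int) -> ElementComposition:
    """Replace ``n_labels`` 16O atoms by 18O (+2.00425 Da each).

    Only chemistry-level bookkeeping happens here; restricting the exchange
    to oxidation-added oxygens is enforced by the caller, which knows how
    many oxygens the modification added.
    """
    if n_labels < 0:
        raise ChemError("n_labels must be >= 0")
    if n_labels == 0:
        return comp
    available = comp.get("O")
    if n_labels > available:
        raise ChemError(
            f"cannot label {n_labels} oxygens: composition has only {available}"
        )
    d = comp.as_dict()
    d["O"] = available - n_labels
    d["[18O]"] = d.get("[18O]", 0) + n_labels
    return ElementComposition(tuple(sorted((k, v) for k, v in d.items() if v)))


def ppm_error(observed: MzValue | float, theoretical: MzValue | float) -> float:
    """Signed relative error, parts per million."""
    if isinstance(observed, MzValue) and isinstance(theoretical, MzValue):
        if observed.polarity != theoretical.polarity:
            raise ChemError(
                f"polarity mismatch: {observed.polarity} vs {theoretical.polarity}"
            )
    obs = observed.value if isinstance(observed, MzValue) else observed
    theo = theoretical.value if isinstance(theoretical, MzValue) else theoretical
    return 1e6 * (obs - theo) / theo
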