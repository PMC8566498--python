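"""Structural library of oxidized phosphatidylcholines (oxPCs).

A diacyl PC is modelled as a glycerophosphocholine backbone (C8H20NO6P)
esterified with two fatty acyls (each contributed as the free acid, minus
one water per ester bond).  Oxidation lives on the sn-2 acyl and is encoded
by the shorthand suffix grammar used in oxidative lipidomics:

=========  ==================================  ========  =======
suffix     meaning                             added O   H delta
=========  ==================================  ========  =======
``;O``     one added oxygen (epoxide/OH,           1        0
           or a truncated aldehyde terminus)
``;O2``    two added oxygens                       2        0
``;OOH``   hydroperoxide                           2        0
``;oxo``   ketone                                  1       -2
``;O-H2``  added O with two fewer hydrogens        1       -2
``;COOH``  truncated carboxyl terminus             2       -2
=========  ==================================  ========  =======

``;OOH`` and the epoxy-hydroxide ``;O2`` are isobaric; they are distinct
library entries separated only by functional class and by their
positive-mode neutral-loss behaviour (H2O2 vs H2O).

A modification catalogue (one row per oxidized sn-2 acyl) is expanded over
a set of sn-1 chains into :class:`LibraryEntry` records carrying precursor
m/z values for all three adducts and rule-predicted diagnostic fragments.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (
    AdductKind,
    ChemError,
    ElementComposition,
    ELECTRON_MASS,
    H2O,
    H2O2,
    METHYL_FORMATE,
    TRIMETHYLAMINE,
    CH2,
    MzValue,
    PROTON_MASS,
    adduct_mz,
    apply_heavy_oxygen,
    monoisotopic_mass,
)

__all__ = [
    "FunctionalClass",
    "AcylSpec",
    "ModCatalogueEntry",
    "LibraryEntry",
    "PredictedFragment",
    "LibraryError",
    "parse_shorthand",
    "parse_acyl",
    "species_composition",
    "build_entry",
    "expand_catalogue",
    "predict_fragments",
    "within_element_bounds",
    "load_catalogue",
    "save_catalogue",
    "default_catalogue",
    "export_library",
    "load_library",
    "GPC_BACKBONE",
    "ELEMENT_BOUNDS_MIN",
    "ELEMENT_BOUNDS_MAX",
]


class LibraryError(ValueError):
    """Malformed names, catalogue schema violations, duplicate entries."""


class FunctionalClass(Enum):
    NONE = "none"
    HYDROPEROXIDE = "hydroperoxide"
    EPOXIDE_OR_HYDROXIDE = "epoxide_or_hydroxide"
    OXO = "oxo"
    CARBOXYL_TERMINAL = "carboxyl_terminal"
    ALDEHYDE_TERMINAL = "aldehyde_terminal"


#: Glycerophosphocholine backbone: PC = backbone + 2 fatty acids - 2 H2O.
GPC_BACKBONE = ElementComposition.from_formula("C8H20NO6P")
_H2O_COMP = ElementComposition.from_formula("H2O")

#: Element-count gates of the nontargeted workflow (per-element, inclusive).
ELEMENT_BOUNDS_MIN = ElementComposition.from_formula("C26H48NO6P")
ELEMENT_BOUNDS_MAX = ElementComposition.from_formula("C60H130NO30P")


@dataclass(frozen=True)
class AcylSpec:
    """One fatty-acyl chain, counted as its free fatty acid.

    Composition: C(carbons) H(2*carbons - 2*double_bonds + h_delta)
    O(2 + added_O).  ``truncated`` marks chain-shortened oxidation products
    (aldehyde- or carboxyl-terminated).
    """

    carbons: int
    double_bonds: int
    added_O: int = 0
    h_delta: int = 0
    functional_class: FunctionalClass = FunctionalClass.NONE
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise LibraryError(f"acyl needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0 or self.added_O < 0:
            raise LibraryError("double_bonds and added_O must be >= 0")
        if self.h_delta % 2:
            raise LibraryError(f"h_delta must be even, got {self.h_delta}")
        if self.functional_class is FunctionalClass.HYDROPEROXIDE and self.added_O < 2:
            raise LibraryError("a hydroperoxide carries at least two added oxygens")
        if (
            self.functional_class
            in (FunctionalClass.CARBOXYL_TERMINAL, FunctionalClass.ALDEHYDE_TERMINAL)
            and not self.truncated
        ):
            raise LibraryError(f"{self.functional_class.value} implies truncated=True")

    def composition(self) -> ElementComposition:
        h = 2 * self.carbons - 2 * self.double_bonds + self.h_delta
        if h <= 0:
            raise LibraryError(
                f"acyl {self.carbons}:{self.double_bonds} (h_delta {self.h_delta}) "
                "has no hydrogens left"
            )
        return ElementComposition.from_counts(C=self.carbons, H=h, O=2 + self.added_O)

    @property
    def suffix(self) -> str:
        """Oxidation suffix of the shorthand name ('' when unmodified)."""
        fc = self.functional_class
        if fc is FunctionalClass.CARBOXYL_TERMINAL:
            return ";COOH"
        if fc is FunctionalClass.HYDROPEROXIDE and self.added_O == 2 and self.h_delta == 0:
            return ";OOH"
        if fc is FunctionalClass.OXO and self.added_O == 1 and self.h_delta == -2:
            return ";oxo"
        if self.added_O == 0 and self.h_delta == 0:
            return ""
        o_part = ";O" if self.added_O == 1 else f";O{self.added_O}"
        if self.added_O == 0:
            o_part = ";"  # bare H-loss, not produced by the grammar but defensive
        h_part = "-H2" if self.h_delta == -2 else ""
        return o_part + h_part

    @property
    def name(self) -> str:
        return f"{self.carbons}:{self.double_bonds}{self.suffix}"

    def composition_key(self) -> Tuple[int, int, int, int]:
        """Fields that determine elemental composition (class-agnostic)."""
        return (self.carbons, self.double_bonds, self.added_O, self.h_delta)


_ACYL_RE = re.compile(r"^(\d+):(\d+)(;.+)?$")
_ON_RE = re.compile(r"^O(\d*)(-H2)?$")


def parse_acyl(token: str) -> AcylSpec:
    """Parse one acyl token such as ``18:2;OOH`` or ``9:0;COOH``."""
    m = _ACYL_RE.match(token)
    if not m:
        raise LibraryError(f"malformed acyl token: {token!r}")
    carbons, dbs = int(m.group(1)), int(m.group(2))
    suffix = (m.group(3) or "")[1:]  # strip leading ';'
    if not suffix:
        return AcylSpec(carbons, dbs)
    if suffix == "OOH":
        return AcylSpec(carbons, dbs, added_O=2, functional_class=FunctionalClass.HYDROPEROXIDE)
    if suffix == "oxo":
        return AcylSpec(carbons, dbs, added_O=1, h_delta=-2, functional_class=FunctionalClass.OXO)
    if suffix == "COOH":
        return AcylSpec(
            carbons, dbs, added_O=2, h_delta=-2,
            functional_class=FunctionalClass.CARBOXYL_TERMINAL, truncated=True,
        )
    om = _ON_RE.match(suffix)
    if om:
        n = int(om.group(1)) if om.group(1) else 1
        return AcylSpec(carbons, dbs, added_O=n, h_delta=-2 if om.group(2) else 0)
    raise LibraryError(f"unknown oxidation suffix: ;{suffix!r} in {token!r}")


_NAME_RE = re.compile(r"^PC([^/_]+)([/_])(.+)$")


def parse_shorthand(name: str) -> Tuple[AcylSpec, AcylSpec, str]:
    """Parse ``PC<sn1>[/|_]<sn2>`` shorthand.

    Returns ``(sn1, sn2, linkage)`` where linkage ``"/"`` asserts known
    sn-positions and ``"_"`` leaves them unknown.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise LibraryError(f"malformed species name: {name!r} (expected PCc:d[/_]c:d[;mod])")
    sn1 = parse_acyl(m.group(1))
    sn2 = parse_acyl(m.group(3))
    return sn1, sn2, m.group(2)


def species_composition(sn1: AcylSpec, sn2: AcylSpec) -> ElementComposition:
    """Neutral elemental composition of the diacyl PC."""
    return GPC_BACKBONE + sn1.composition() + sn2.composition() - 2 * _H2O_COMP


def within_element_bounds(
    comp: ElementComposition,
    lo: ElementComposition = ELEMENT_BOUNDS_MIN,
    hi: ElementComposition = ELEMENT_BOUNDS_MAX,
) -> bool:
    """Element-wise inclusion test against the workflow's C/H/N/O/P gates.

    18O counts toward total oxygen and D toward total hydrogen.
    """
    totals = {
        "C": comp.get("C"),
        "H": comp.get("H") + comp.get("D"),
        "N": comp.get("N"),
        "O": comp.get("O") + comp.get("[18O]"),
        "P": comp.get("P"),
    }
    return all(lo.get(el) <= totals[el] <= hi.get(el) for el in totals)


@dataclass(frozen=True)
class ModCatalogueEntry:
    """One oxidized sn-2 acyl with its diagnostic-fragment annotations."""

    sn2: AcylSpec
    fragments: Tuple[Tuple[str, ElementComposition], ...] = ()
    rt_class: str = ""
    provenance: str = "unspecified"
    sn_known: bool = False

    def key(self) -> Tuple[Tuple[int, int, int, int], FunctionalClass]:
        return (self.sn2.composition_key(), self.sn2.functional_class)


@dataclass(frozen=True)
class PredictedFragment:
    label: str
    mz: MzValue
    rule_id: str


@dataclass(frozen=True)
class LibraryEntry:
    """One oxPC species: name, composition, adduct precursors, fragments."""

    name: str
    sn1: AcylSpec
    catalogue: ModCatalogueEntry
    composition: ElementComposition = field(compare=False, default=None)  # type: ignore[assignment]
    precursors: Tuple[Tuple[AdductKind, MzValue], ...] = field(compare=False, default=())

    @property
    def sn2(self) -> AcylSpec:
        return self.catalogue.sn2

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def exchangeable_oxygens(self) -> int:
        """Oxygens added by oxidation: the only ones 18O-exchangeable."""
        return self.sn2.added_O

    def precursor(self, adduct: AdductKind) -> MzValue:
        return dict(self.precursors)[adduct]

    @property
    def primary_negative_adduct(self) -> AdductKind:
        """Carboxyl-terminated oxPCs ionize as [M-H]-; others as [M+HCOO]-."""
        if self.sn2.functional_class is FunctionalClass.CARBOXYL_TERMINAL:
            return AdductKind.DEPROTONATED_NEG
        return AdductKind.FORMATE_NEG

    def labeled_composition(self, n_labels: int) -> ElementComposition:
        if n_labels > self.exchangeable_oxygens:
            raise LibraryError(
                f"{self.name}: only {self.exchangeable_oxygens} oxidation-added "
                f"oxygens are exchangeable, cannot label {n_labels}"
            )
        return apply_heavy_oxygen(self.composition, n_labels)


def build_entry(sn1: AcylSpec, cat: ModCatalogueEntry) -> LibraryEntry:
    comp = species_composition(sn1, cat.sn2)
    mass = monoisotopic_mass(comp)
    precursors = tuple((ad, adduct_mz(mass, ad)) for ad in AdductKind)
    link = "/" if cat.sn_known else "_"
    name = f"PC{sn1.name}{link}{cat.sn2.name}"
    return LibraryEntry(name=name, sn1=sn1, catalogue=cat, composition=comp, precursors=precursors)


def expand_catalogue(
    catalogue: Sequence[ModCatalogueEntry], sn1_chains: Sequence[AcylSpec]
) -> List[LibraryEntry]:
    """Cross every catalogue row with every sn-1 chain (|cat| x |sn1| entries)."""
    if not catalogue or not sn1_chains:
        raise LibraryError("catalogue and sn1_chains must be nonempty")
    seen_keys: Dict[object, int] = {}
    dups = []
    for i, cat in enumerate(catalogue):
        k = cat.key()
        if k in seen_keys:
            dups.append((seen_keys[k], i, cat.sn2.name))
        seen_keys[k] = i
    if dups:
        raise LibraryError(f"duplicate catalogue entries: {dups}")
    if len({c.composition_key() for c in sn1_chains}) != len(sn1_chains):
        raise LibraryError("sn1_chains contains duplicates")
    return [build_entry(sn1, cat) for cat in catalogue for sn1 in sn1_chains]


def _acid_anion_mz(acyl: AcylSpec) -> float:
    """Carboxylate anion m/z of a free fatty acid ([FA-H]-)."""
    return monoisotopic_mass(acyl.composition()) - PROTON_MASS


def predict_fragments(entry: LibraryEntry, polarity: str) -> List[PredictedFragment]:
    """Rule-predicted diagnostic fragments for one library entry.

    Negative mode, formate-adduct species (everything except carboxyl
    termini): sn-1 carboxylate (R1), oxidized-acyl carboxylate [oxFA]-
    (R2), its water loss (R3) and head-group demethylation [M-CH3]- from
    the formate adduct (R4).  Carboxyl-terminated species fragment from
    [M-H]-: sn-1 carboxylate (R1), trimethylamine loss (R5) and the
    methylated oxidized acyl [oxFA+CH2]- (R6).  Positive mode from [M+H]+:
    water loss for epoxides/hydroxides (R7), H2O2 loss for hydroperoxides
    (R8).  Catalogue-supplied fragment formulas (e.g. regiochemistry
    markers) are emitted as anions under rule id ``CAT``.
    """
    sn2 = entry.sn2
    frags: List[PredictedFragment] = []
    if polarity == "-":
        frags.append(
            PredictedFragment(f"[{entry.sn1.name}]-", MzValue(_acid_anion_mz(entry.sn1), "-"), "R1")
        )
        if sn2.functional_class is FunctionalClass.CARBOXYL_TERMINAL:
            prec = entry.precursor(AdductKind.DEPROTONATED_NEG).value
            frags.append(
                PredictedFragment("[M-H-N(CH3)3]-", MzValue(prec - TRIMETHYLAMINE, "-"), "R5")
            )
            frags.append(
                PredictedFragment(
                    f"[{sn2.name}+CH2]-",
                    MzValue(monoisotopic_mass(sn2.composition()) + CH2 - PROTON_MASS, "-"),
                    "R6",
                )
            )
        else:
            ox = _acid_anion_mz(sn2)
            frags.append(PredictedFragment(f"[{sn2.name}]-", MzValue(ox, "-"), "R2"))
            if ox - H2O > 0:
                frags.append(PredictedFragment(f"[{sn2.name}-H2O]-", MzValue(ox - H2O, "-"), "R3"))
            prec = entry.precursor(AdductKind.FORMATE_NEG).value
            frags.append(
                PredictedFragment("[M-CH3]-", MzValue(prec - METHYL_FORMATE, "-"), "R4")
            )
        for label, comp in entry.catalogue.fragments:
            frags.append(
                PredictedFragment(label, MzValue(monoisotopic_mass(comp) + ELECTRON_MASS, "-"), "CAT")
            )
    elif polarity == "+":
        prec = entry.precursor(AdductKind.PROTONATED_POS).value
        fc = sn2.functional_class
        if fc in (FunctionalClass.EPOXIDE_OR_HYDROXIDE, FunctionalClass.ALDEHYDE_TERMINAL) or (
            fc is FunctionalClass.NONE and sn2.added_O > 0
        ):
            frags.append(PredictedFragment("[M+H-H2O]+", MzValue(prec - H2O, "+"), "R7"))
        if fc is FunctionalClass.HYDROPEROXIDE:
            frags.append(PredictedFragment("[M+H-H2O2]+", MzValue(prec - H2O2, "+"), "R8"))
    else:
        raise LibraryError(f"polarity must be '+' or '-', got {polarity!r}")
    return frags


# ---------------------------------------------------------------------------
# Catalogue and library I/O
# ---------------------------------------------------------------------------

_CATALOGUE_COLUMNS = [
    "name_suffix",
    "carbons",
    "double_bonds",
    "added_O",
    "h_delta",
    "functional_class",
    "truncated",
    "fragments",
    "rt_class",
    "provenance",
]


def _catalogue_row(cat: ModCatalogueEntry) -> Dict[str, object]:
    # fragments serialize as semicolon-separated anion formulas; labels are
    # regenerated as "[formula]-" on load
    frag_text = ";".join(comp.formula() for _, comp in cat.fragments)
    sn2 = cat.sn2
    return {
        "name_suffix": sn2.suffix,
        "carbons": sn2.carbons,
        "double_bonds": sn2.double_bonds,
        "added_O": sn2.added_O,
        "h_delta": sn2.h_delta,
        "functional_class": sn2.functional_class.value,
        "truncated": int(sn2.truncated),
        "fragments": frag_text,
        "rt_class": cat.rt_class,
        "provenance": cat.provenance,
    }


def _parse_catalogue_row(row: Dict[str, str], rownum: int) -> ModCatalogueEntry:
    try:
        fc = FunctionalClass(row["functional_class"].strip())
        sn2 = AcylSpec(
            carbons=int(row["carbons"]),
            double_bonds=int(row["double_bonds"]),
            added_O=int(row["added_O"]),
            h_delta=int(row["h_delta"]),
            functional_class=fc,
            truncated=bool(int(row["truncated"])),
        )
        fragments = []
        for formula in filter(None, (row.get("fragments") or "").split(";")):
            fragments.append((f"[{formula}]-", ElementComposition.from_formula(formula)))
        return ModCatalogueEntry(
            sn2=sn2,
            fragments=tuple(fragments),
            rt_class=row.get("rt_class", "") or "",
            provenance=row.get("provenance", "") or "unspecified",
        )
    except (KeyError, ValueError, ChemError) as exc:
        raise LibraryError(f"catalogue row {rownum}: {exc}") from exc


def load_catalogue(path: str | Path) -> List[ModCatalogueEntry]:
    """Load a modification catalogue from CSV (or JSON list of row dicts)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise LibraryError(f"{path}: JSON catalogue must be a list of row objects")
        raw = [{k: str(v) for k, v in r.items()} for r in rows]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise LibraryError(f"{path}: empty catalogue file")
            missing = set(_CATALOGUE_COLUMNS[:7]) - set(reader.fieldnames)
            if missing:
                raise LibraryError(f"{path}: missing columns {sorted(missing)}")
            raw = list(reader)
    if not raw:
        raise LibraryError(f"{path}: catalogue has no rows")
    entries = [_parse_catalogue_row(r, i + 2) for i, r in enumerate(raw)]
    keys = [e.key() for e in entries]
    if len(set(keys)) != len(keys):
        dup = [k for k in set(keys) if keys.count(k) > 1]
        raise LibraryError(f"{path}: duplicate catalogue keys {dup}")
    return entries


def save_catalogue(entries: Sequence[ModCatalogueEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CATALOGUE_COLUMNS)
        writer.writeheader()
        for e in entries:
            writer.writerow(_catalogue_row(e))


def default_catalogue() -> List[ModCatalogueEntry]:
    """The bundled 155-row modification catalogue (see data/default_catalogue.csv)."""
    from importlib.resources import files

    path = files("oxpclib").joinpath("data/default_catalogue.csv")
    with path.open(newline="") as fh:  # type: ignore[call-arg]
        raw = list(csv.DictReader(fh))
    return [_parse_catalogue_row(r, i + 2) for i, r in enumerate(raw)]


def export_library(
    entries: Sequence[LibraryEntry], path: str | Path, format: str = "csv"
) -> None:
    """Write the expanded library as CSV, JSON, or MGF (predicted spectra)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["name", "formula", "neutral_mass"]
                + [ad.value for ad in AdductKind]
                + ["primary_neg_adduct", "functional_class", "rt_class", "provenance", "fragments_neg"]
            )
            for e in entries:
                frags = ";".join(
                    f"{f.label}@{f.mz.value:.4f}[{f.rule_id}]" for f in predict_fragments(e, "-")
                )
                writer.writerow(
                    [e.name, e.composition.formula(), f"{e.neutral_mass:.5f}"]
                    + [f"{e.precursor(ad).value:.4f}" for ad in AdductKind]
                    + [
                        e.primary_negative_adduct.value,
                        e.sn2.functional_class.value,
                        e.catalogue.rt_class,
                        e.catalogue.provenance,
                        frags,
                    ]
                )
    elif fmt == "json":
        rows = []
        for e in entries:
            rows.append(
                {
                    "name": e.name,
                    "formula": e.composition.formula(),
                    "neutral_mass": e.neutral_mass,
                    "precursors": {ad.value: e.precursor(ad).value for ad in AdductKind},
                    "catalogue": _catalogue_row(e.catalogue),
                    "sn1": e.sn1.name,
                }
            )
        path.write_text(json.dumps(rows, indent=1))
    elif fmt == "mgf":
        from pyteomics import mgf

        spectra = []
        for e in entries:
            neg = e.primary_negative_adduct
            frags = sorted(predict_fragments(e, "-"), key=lambda f: f.mz.value)
            spectra.append(
                {
                    "m/z array": [f.mz.value for f in frags],
                    "intensity array": [100.0] * len(frags),
                    "params": {
                        "title": e.name,
                        "pepmass": (e.precursor(neg).value, None),
                        "charge": "1-",
                    },
                }
            )
        mgf.write(spectra, output=str(path), file_mode="w")
    else:
        raise LibraryError(f"unknown export format: {format!r}")


def load_library(path: str | Path) -> List[LibraryEntry]:
    """Rebuild library entries from a CSV/JSON export.

    Names are re-parsed; the functional class (which the shorthand alone
    cannot always convey, e.g. truncated aldehydes named ``;O``) is
    restored from the export's ``functional_class``/``catalogue`` field.
    """
    path = Path(path)
    entries = []
    if path.suffix.lower() == ".json":
        for row in json.loads(path.read_text()):
            sn1, _, link = parse_shorthand(row["name"])
            cat = replace(
                _parse_catalogue_row({k: str(v) for k, v in row["catalogue"].items()}, 0),
                sn_known=(link == "/"),
            )
            entries.append(build_entry(sn1, cat))
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                sn1, sn2, link = parse_shorthand(row["name"])
                fc = FunctionalClass(row.get("functional_class", "none") or "none")
                sn2 = replace(
                    sn2,
                    functional_class=fc,
                    truncated=fc
                    in (FunctionalClass.CARBOXYL_TERMINAL, FunctionalClass.ALDEHYDE_TERMINAL),
                )
                cat = ModCatalogueEntry(
                    sn2=sn2,
                    rt_class=row.get("rt_class", "") or "",
                    provenance=row.get("provenance", "") or "unspecified",
                    sn_known=(link == "/"),
                )
                entries.append(build_entry(sn1, cat))
    return entries
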