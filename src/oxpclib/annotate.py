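"""Library matching and annotation of oxPC MS/MS spectra.

Mirrors the manual three-ion annotation logic: a candidate is accepted
only when the sn-1 acyl carboxylate is present together with either an
oxidized-acyl ion or a head-group diagnostic.  Isobaric hydroperoxide vs
epoxy-hydroxide candidates cannot be separated in negative mode; the
positive-mode neutral-loss check (H2O2 before H2O, since hydroperoxides
may also dehydrate) resolves them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np

from .chem import H2O, H2O2, MzValue, ppm_error
from .library import AdductKind, FunctionalClass, LibraryEntry, predict_fragments
from .peakproc import Spectrum

__all__ = [
    "ClassCall",
    "Annotation",
    "AnnotateError",
    "match_precursor",
    "annotate_msms",
    "discriminate_functional_isomer",
]


class AnnotateError(ValueError):
    pass


class ClassCall(Enum):
    HYDROPEROXIDE = "hydroperoxide"
    EPOXIDE_OR_HYDROXIDE = "epoxide_or_hydroxide"
    CARBOXYL = "carboxyl"
    UNRESOLVED = "unresolved"


@dataclass
class Annotation:
    compound_key: str
    library_name: Optional[str]
    precursor_ppm: float
    evidence: Dict[str, bool] = field(default_factory=dict)
    functional_class: ClassCall = ClassCall.UNRESOLVED
    score: int = 0

    @property
    def accepted(self) -> bool:
        return self.library_name is not None and self.score >= 1


_EVIDENCE_BY_RULE = {
    "R1": "sn1_ion",
    "R2": "oxacyl_ion",
    "R3": "oxacyl_ion",
    "R4": "headgroup_ion",
    "R5": "trimethylamine_loss",
    "R6": "methylated_oxFA",
    "CAT": "oxacyl_ion",
}


def match_precursor(
    mz: MzValue | float,
    library: Sequence[LibraryEntry],
    tol_ppm: float = 5.0,
    polarity: Optional[str] = None,
) -> List[LibraryEntry]:
    """All library entries with any adduct within +/-tol, sorted by |ppm|.

    When ``mz`` is a bare float, ``polarity`` restricts which adducts are
    searched (both polarities when None).
    """
    if not library:
        raise AnnotateError("library is empty")
    if isinstance(mz, MzValue):
        value, polarity = mz.value, mz.polarity
    else:
        value = float(mz)
    hits = []
    for entry in library:
        best = None
        for adduct, prec in entry.precursors:
            if polarity is not None and adduct.polarity != polarity:
                continue
            err = ppm_error(value, prec.value)
            if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best)):
                best = err
        if best is not None:
            hits.append((abs(best), best, entry))
    hits.sort(key=lambda h: (h[0], h[2].name))
    return [entry for _, _, entry in hits]


def _peak_present(spectrum: Spectrum, mz: float, tol_ppm: float) -> bool:
    half = mz * tol_ppm * 1e-6
    lo = np.searchsorted(spectrum.mz, mz - half)
    hi = np.searchsorted(spectrum.mz, mz + half, side="right")
    return hi > lo


def annotate_msms(
    ms2: Spectrum,
    candidates: Sequence[LibraryEntry],
    frag_tol_ppm: float = 10.0,
    compound_key: str = "",
    precursor_tol_ppm: float = 5.0,
) -> Annotation:
    """Score candidates by matched diagnostic ions; pick the best.

    Acceptance requires sn-1 acyl evidence plus at least one other
    diagnostic (oxidized-acyl or head-group ion).  Fragments predicted at
    indistinguishable m/z are counted once.  Ties on score break on the
    smaller absolute precursor ppm error.  When nothing reaches the
    evidence floor the annotation comes back UNRESOLVED with score 0.
    """
    best: Optional[Annotation] = None
    best_key = None
    for entry in candidates:
        if ms2.precursor_mz is not None:
            errs = [
                ppm_error(ms2.precursor_mz, prec.value)
                for adduct, prec in entry.precursors
                if adduct.polarity == ms2.polarity
            ]
            prec_ppm = min(errs, key=abs) if errs else float("inf")
            if abs(prec_ppm) > precursor_tol_ppm:
                continue
        else:
            prec_ppm = 0.0
        evidence = {
            "headgroup_ion": False,
            "sn1_ion": False,
            "oxacyl_ion": False,
            "trimethylamine_loss": False,
            "methylated_oxFA": False,
        }
        score = 0
        seen_mz: List[float] = []
        for frag in predict_fragments(entry, ms2.polarity):
            if any(abs(frag.mz.value - m) <= m * 1e-6 for m in seen_mz):
                continue
            seen_mz.append(frag.mz.value)
            if _peak_present(ms2, frag.mz.value, frag_tol_ppm):
                score += 1
                key = _EVIDENCE_BY_RULE.get(frag.rule_id)
                if key:
                    evidence[key] = True
        other = evidence["oxacyl_ion"] or evidence["headgroup_ion"] or (
            evidence["trimethylamine_loss"] or evidence["methylated_oxFA"]
        )
        if not (evidence["sn1_ion"] and other):
            continue
        fc = ClassCall.UNRESOLVED
        if (
            entry.sn2.functional_class is FunctionalClass.CARBOXYL_TERMINAL
            and evidence["trimethylamine_loss"]
            and evidence["methylated_oxFA"]
        ):
            fc = ClassCall.CARBOXYL
        cand = Annotation(
            compound_key=compound_key,
            library_name=entry.name,
            precursor_ppm=prec_ppm,
            evidence=evidence,
            functional_class=fc,
            score=score,
        )
        key = (-score, abs(prec_ppm))
        if best is None or key < best_key:
            best, best_key = cand, key
    if best is None:
        return Annotation(compound_key=compound_key, library_name=None, precursor_ppm=float("nan"))
    return best


def discriminate_functional_isomer(
    pos_ms2: Spectrum, precursor: MzValue | float, tol_ppm: float = 10.0
) -> ClassCall:
    """Split the isobaric +2O isomers from a positive-mode [M+H]+ spectrum.

    An H2O2 neutral loss calls hydroperoxide; failing that, an H2O loss
    calls epoxide/hydroxide; otherwise unresolved.  The H2O2 check runs
    first because hydroperoxides can also dehydrate.
    """
    if pos_ms2.polarity != "+":
        raise AnnotateError(f"expected a positive-mode spectrum, got {pos_ms2.polarity!r}")
    prec = precursor.value if isinstance(precursor, MzValue) else float(precursor)
    if _peak_present(pos_ms2, prec - H2O2, tol_ppm):
        return ClassCall.HYDROPEROXIDE
    if _peak_present(pos_ms2, prec - H2O, tol_ppm):
        return ClassCall.EPOXIDE_OR_HYDROXIDE
    return ClassCall.UNRESOLVED
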