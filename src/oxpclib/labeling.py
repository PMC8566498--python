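"""18O labeling and MALDI-MS/MS imaging support.

Oxidation under an 18O2 atmosphere shifts every oxidation-added oxygen by
+2.00425 Da, moving genuine in-vivo products away from any artifact formed
from ambient 16O2 during workup or laser desorption.  This module designs
the corresponding precursor -> product transitions (loss of H2-18O from
the labeled species), estimates the atom labeling fraction from an
isotopologue envelope, renders single-transition ion images on the 0-100
pseudocolor scale, and flags transitions prone to artificial oxidation.

Nominal MALDI transition m/z values are quoted at one decimal by
truncation (the ion-trap convention of citing the lower 0.1 boundary of
the isolation window), so 794.5682 is quoted as 794.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import AdductKind, H2O, H2_18O, adduct_mz, monoisotopic_mass
from .library import LibraryEntry

__all__ = [
    "LabelingError",
    "Transition",
    "MsiGrid",
    "IsotopologueEnvelope",
    "labeled_transition",
    "estimate_labeling_efficiency",
    "simulate_envelope",
    "render_ion_image",
    "artificial_oxidation_screen",
]


class LabelingError(ValueError):
    pass


def _nominal(mz: float) -> float:
    """Truncate to one decimal (lower 0.1 boundary)."""
    return math.floor(mz * 10.0) / 10.0


@dataclass(frozen=True)
class Transition:
    """A MALDI-MS/MS precursor -> product pair at nominal (0.1) precision."""

    precursor: float
    product: float
    loss_label: str
    isolation_width: float = 1.0
    name: str = ""
    n_labels: int = 0

    def __post_init__(self) -> None:
        if not self.product < self.precursor:
            raise LabelingError("product m/z must be below precursor m/z")
        if self.isolation_width <= 0:
            raise LabelingError("isolation width must be > 0")


@dataclass
class MsiGrid:
    """A rectangular single-transition intensity raster."""

    intensities: np.ndarray
    pixel_pitch_um: float = 60.0
    transition: Optional[Transition] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise LabelingError("MSI grid must be two-dimensional")
        if self.pixel_pitch_um <= 0:
            raise LabelingError("pixel pitch must be > 0")


def labeled_transition(entry: LibraryEntry, n_labels: int, isolation_width: float = 1.0
                       ) -> Transition:
    """Design the water-loss MALDI transition for an (18O-labeled) oxPC.

    Precursor is the [M+H]+ of the species with ``n_labels`` added oxygens
    replaced by 18O; the product results from loss of H2-18O (20.0148 Da)
    when at least one label is present, otherwise plain H2O (18.0106 Da).
    Both m/z values are quoted at one decimal (truncated).
    """
    comp = entry.labeled_composition(n_labels)
    prec_exact = adduct_mz(monoisotopic_mass(comp), AdductKind.PROTONATED_POS).value
    if n_labels >= 1:
        loss, label = H2_18O, "-H2[18O]"
    else:
        loss, label = H2O, "-H2O"
    return Transition(
        precursor=_nominal(prec_exact),
        product=_nominal(prec_exact - loss),
        loss_label=label,
        isolation_width=isolation_width,
        name=entry.name,
        n_labels=n_labels,
    )


def estimate_labeling_efficiency(
    intensities: Sequence[float], n_exchangeable: Optional[int] = None
) -> float:
    """Atom-level 18O incorporation from an isotopologue envelope.

    ``intensities[k]`` is the signal of the species carrying k heavy
    labels, k = 0..n.  The estimate is the intensity-weighted labeled-atom
    fraction sum(k * I_k) / (n * sum(I_k)) -- the binomial maximum-
    likelihood estimate of the per-atom labeling probability, and it is
    invariant to overall intensity scale.
    """
    env = np.asarray(intensities, dtype=float)
    if env.ndim != 1 or env.size < 2:
        raise LabelingError("envelope needs intensities I0..In with n >= 1")
    if (env < 0).any():
        raise LabelingError("envelope intensities must be >= 0")
    total = env.sum()
    if total == 0:
        raise LabelingError("all-zero envelope")
    n = n_exchangeable if n_exchangeable is not None else env.size - 1
    if n < env.size - 1:
        raise LabelingError(f"envelope has I0..I{env.size - 1} but n_exchangeable = {n}")
    k = np.arange(env.size)
    return float((k * env).sum() / (n * total))


#: Alias matching the domain type name.
IsotopologueEnvelope = np.ndarray


def simulate_envelope(p: float, n_exchangeable: int, n_ions: int, seed: int) -> np.ndarray:
    """Binomial envelope: ``n_ions`` molecules, each oxygen labeled w.p. ``p``."""
    if not 0.0 <= p <= 1.0:
        raise LabelingError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = rng.binomial(n_exchangeable, p, size=n_ions)
    return np.bincount(labels, minlength=n_exchangeable + 1).astype(float)


def render_ion_image(grid: MsiGrid | np.ndarray) -> np.ndarray:
    """Linear 0-100 pseudocolor scaling: max pixel -> 100, zero stays 0.

    An all-zero grid renders all-zero (no division by the maximum).
    """
    arr = grid.intensities if isinstance(grid, MsiGrid) else np.asarray(grid, dtype=float)
    if (arr < 0).any():
        raise LabelingError("negative intensities in MSI grid")
    peak = arr.max() if arr.size else 0.0
    if peak == 0:
        return np.zeros_like(arr)
    return arr * (100.0 / peak)


def artificial_oxidation_screen(
    labeled_signal: Sequence[float] | float,
    unlabeled_control_signal: Sequence[float] | float,
    fraction_threshold: float = 0.05,
) -> np.ndarray | bool:
    """Flag compounds whose unlabeled (16O) transition fires in a
    no-stimulation control above ``fraction_threshold`` of the labeled
    channel -- evidence of workup/laser oxidation artifacts.  Informational
    only; zero signal in both channels is clean (no evidence either way).
    """
    lab = np.asarray(labeled_signal, dtype=float)
    ctl = np.asarray(unlabeled_control_signal, dtype=float)
    if lab.shape != ctl.shape:
        raise LabelingError("labeled and control channels differ in shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(lab > 0, ctl / np.where(lab > 0, lab, 1.0), np.where(ctl > 0, np.inf, 0.0))
    flagged = frac > fraction_threshold
    if flagged.ndim == 0:
        return bool(flagged)
    return flagged
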