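"""Ground-truthed synthetic inputs for the whole workflow.

Emulates the study conditions of the differential oxidation screen:

* paired runs -- a shared nonoxidized PC matrix in both channels (with
  10% multiplicative log-normal abundance noise) plus oxPC spikes present
  only in the oxidized channel;
* chromatography -- Gaussian elution profiles, sigma 0.05 min, sampled
  every 0.012 min (about ten points across the FWHM), each compound with
  a lower-intensity +1.00336 Da 13C isotopologue partner;
* DDA-style MS/MS -- every spiked compound gets a product-ion spectrum
  holding its rule-predicted fragments plus uniform-random decoy peaks
  kept at least 20 ppm away from any true fragment;
* inducer presets -- 'radical' and 'autoxidation' weight hydroperoxides
  up, 'metal' weights epoxide/hydroxide and keto products up;
* MSI -- liver-section-like grids, either uniform or with elevated
  pericentral disks on a low background.

Everything is driven by one integer seed through numpy's default
(PCG64) generator, so identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import AdductKind, C13_C12_DELTA
from .library import (
    AcylSpec,
    FunctionalClass,
    LibraryEntry,
    ModCatalogueEntry,
    build_entry,
    default_catalogue,
    expand_catalogue,
    predict_fragments,
)
from .labeling import MsiGrid
from .peakproc import Spectrum

__all__ = [
    "SimulationSpec",
    "SyntheticError",
    "make_simulation",
    "simulate_pair",
    "simulate_msms",
    "simulate_msi",
    "PRESET_CLASS_WEIGHTS",
]


class SyntheticError(ValueError):
    pass


#: Relative abundance weight per functional class for each LPO inducer preset.
PRESET_CLASS_WEIGHTS: Dict[str, Dict[FunctionalClass, float]] = {
    # radical initiation accumulates primary hydroperoxides far above the
    # secondary products, which only build up once metals decompose them
    "radical": {
        FunctionalClass.HYDROPEROXIDE: 6.0,
        FunctionalClass.EPOXIDE_OR_HYDROXIDE: 0.8,
        FunctionalClass.OXO: 0.5,
        FunctionalClass.NONE: 0.5,
        FunctionalClass.ALDEHYDE_TERMINAL: 0.6,
        FunctionalClass.CARBOXYL_TERMINAL: 0.6,
    },
    "metal": {
        FunctionalClass.HYDROPEROXIDE: 0.5,
        FunctionalClass.EPOXIDE_OR_HYDROXIDE: 2.5,
        FunctionalClass.OXO: 2.0,
        FunctionalClass.NONE: 1.0,
        FunctionalClass.ALDEHYDE_TERMINAL: 1.5,
        FunctionalClass.CARBOXYL_TERMINAL: 1.5,
    },
    "autoxidation": {
        FunctionalClass.HYDROPEROXIDE: 5.0,
        FunctionalClass.EPOXIDE_OR_HYDROXIDE: 0.8,
        FunctionalClass.OXO: 0.6,
        FunctionalClass.NONE: 0.5,
        FunctionalClass.ALDEHYDE_TERMINAL: 0.5,
        FunctionalClass.CARBOXYL_TERMINAL: 0.5,
    },
}


@dataclass
class SimulationSpec:
    """Everything needed to generate one oxidized/nonoxidized pair."""

    seed: int
    spikes: List[Tuple[LibraryEntry, float]]
    matrix: List[Tuple[LibraryEntry, float]] = field(default_factory=list)
    polarity: str = "-"
    rt_range: Tuple[float, float] = (2.0, 13.0)
    peak_sigma: float = 0.05  # minutes
    scan_interval: float = 0.012  # minutes, ~10 scans across FWHM
    intensity_cv: float = 0.10  # multiplicative log-normal noise
    noise_peaks: int = 0
    noise_intensity: float = 2_000.0
    n_decoys: int = 0  # decoy peaks per attached MS/MS spectrum
    isotopologue_fraction_per_c: float = 0.011  # +1 partner height per carbon

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        for entry, ab in self.spikes + self.matrix:
            if ab <= 0:
                raise SyntheticError(f"abundance must be > 0 ({entry.name})")


def _default_matrix_entries() -> List[LibraryEntry]:
    """Nonoxidized PC matrix: the three PUFA-PCs plus PC16:0/18:1."""
    sn1 = AcylSpec(16, 0)
    out = []
    for c, d in ((18, 2), (20, 4), (22, 6), (18, 1)):
        cat = ModCatalogueEntry(sn2=AcylSpec(c, d), sn_known=True)
        out.append(build_entry(sn1, cat))
    return out


def make_simulation(
    seed: int,
    n_spikes: int = 12,
    preset: str = "metal",
    catalogue: Optional[Sequence[ModCatalogueEntry]] = None,
    n_decoys: int = 0,
    noise_peaks: int = 0,
    abundance: float = 5e5,
) -> SimulationSpec:
    """Draw a ground-truthed spike set from the catalogue.

    Spike abundances are ``abundance`` scaled by the preset's class weight
    with a log-normal spread, mirroring inducer-dependent product profiles.
    """
    if preset not in PRESET_CLASS_WEIGHTS:
        raise SyntheticError(f"unknown preset {preset!r}; choose {sorted(PRESET_CLASS_WEIGHTS)}")
    rng = np.random.default_rng(seed)
    cat = list(catalogue) if catalogue is not None else default_catalogue()
    entries = expand_catalogue(cat, [AcylSpec(16, 0)])
    if n_spikes > len(entries):
        raise SyntheticError(f"cannot spike {n_spikes} species from {len(entries)} entries")
    # spike selection is biased by the inducer's class weights (a radical
    # system yields mostly hydroperoxides, a metal system their breakdown
    # products), and spiked precursors stay >= 20 ppm apart so the ground
    # truth is unambiguous
    weights = PRESET_CLASS_WEIGHTS[preset]
    w = np.array([weights[e.sn2.functional_class] for e in entries])
    chosen: List[LibraryEntry] = []
    order = rng.choice(len(entries), size=len(entries), replace=False, p=w / w.sum())
    for i in order:
        e = entries[i]
        mz = e.precursor(e.primary_negative_adduct).value
        if all(
            abs(mz - c.precursor(c.primary_negative_adduct).value) > 20e-6 * mz for c in chosen
        ):
            chosen.append(e)
        if len(chosen) == n_spikes:
            break
    if len(chosen) < n_spikes:
        raise SyntheticError("could not find enough mass-separated spike species")
    spikes = []
    for e in chosen:
        w = weights[e.sn2.functional_class]
        spikes.append((e, float(abundance * w * rng.lognormal(0.0, 0.25))))
    matrix = [(e, float(2e6 * rng.lognormal(0.0, 0.25))) for e in _default_matrix_entries()]
    return SimulationSpec(
        seed=int(rng.integers(2**31 - 1)),
        spikes=spikes,
        matrix=matrix,
        n_decoys=n_decoys,
        noise_peaks=noise_peaks,
    )


def _entry_mz(entry: LibraryEntry, polarity: str) -> float:
    if polarity == "-":
        return entry.precursor(entry.primary_negative_adduct).value
    return entry.precursor(AdductKind.PROTONATED_POS).value


def _entry_rt(entry: LibraryEntry, rng: np.random.Generator, rt_range: Tuple[float, float]) -> float:
    return float(rng.uniform(rt_range[0] + 0.5, rt_range[1] - 0.5))


def _build_run(
    compounds: List[Tuple[float, float, float]],  # (mz, rt, apex)
    spec: SimulationSpec,
    rng: np.random.Generator,
    carbons: List[int],
    ms2: List[Spectrum],
) -> List[Spectrum]:
    t0, t1 = spec.rt_range
    times = np.arange(t0, t1, spec.scan_interval)
    traces = []
    for (mz, rt, apex), nc in zip(compounds, carbons):
        traces.append((mz, rt, apex))
        traces.append((mz + C13_C12_DELTA, rt, apex * spec.isotopologue_fraction_per_c * nc))
    noise = [
        (float(rng.uniform(250.0, 1000.0)), float(rng.uniform(t0, t1)),
         float(rng.exponential(spec.noise_intensity)))
        for _ in range(spec.noise_peaks)
    ]
    run: List[Spectrum] = []
    for t in times:
        mzs, ints = [], []
        for mz, rt, apex in traces:
            h = apex * np.exp(-0.5 * ((t - rt) / spec.peak_sigma) ** 2)
            if h >= 1.0:
                mzs.append(mz)
                ints.append(h)
        for mz, rt, h in noise:
            if abs(t - rt) < spec.scan_interval / 2:
                mzs.append(mz)
                ints.append(max(h, 1.0))
        run.append(
            Spectrum(scan_time=float(t), polarity=spec.polarity, ms_level=1,
                     mz=np.array(mzs), intensity=np.array(ints))
        )
    # interleave DDA MS/MS near each target's apex
    for s in sorted(ms2, key=lambda s: s.scan_time):
        run.append(s)
    run.sort(key=lambda s: (s.scan_time, s.ms_level))
    return run


def simulate_pair(spec: SimulationSpec) -> Tuple[List[Spectrum], List[Spectrum], pd.DataFrame]:
    """Generate (oxidized run, nonoxidized run, truth table).

    Matrix compounds appear in both runs at equal nominal abundance (each
    run re-jittered); spikes appear only in the oxidized run, each with a
    DDA MS/MS spectrum near its elution apex.  The truth table lists name,
    functional class, m/z, RT and abundance of every spike.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    ox_compounds, ox_carbons, nox_compounds, nox_carbons = [], [], [], []
    ms2: List[Spectrum] = []
    for entry, ab in spec.spikes:
        mz = _entry_mz(entry, spec.polarity)
        rt = _entry_rt(entry, rng, spec.rt_range)
        apex = ab * rng.lognormal(0.0, spec.intensity_cv)
        ox_compounds.append((mz, rt, apex))
        ox_carbons.append(entry.composition.get("C"))
        ms2.append(
            simulate_msms(
                entry,
                spec.polarity,
                n_decoys=spec.n_decoys,
                seed=int(rng.integers(2**31 - 1)),
                scan_time=rt,
            )
        )
        rows.append(
            dict(name=entry.name, functional_class=entry.sn2.functional_class.value,
                 mz=mz, rt=rt, abundance=ab)
        )
    for entry, ab in spec.matrix:
        mz = _entry_mz(entry, spec.polarity)
        rt = _entry_rt(entry, rng, spec.rt_range)
        for comps, carbs in ((ox_compounds, ox_carbons), (nox_compounds, nox_carbons)):
            comps.append((mz, rt, ab * rng.lognormal(0.0, spec.intensity_cv)))
            carbs.append(entry.composition.get("C"))
    ox_run = _build_run(ox_compounds, spec, rng, ox_carbons, ms2)
    nox_run = _build_run(nox_compounds, spec, rng, nox_carbons, [])
    truth = pd.DataFrame(rows, columns=["name", "functional_class", "mz", "rt", "abundance"])
    return ox_run, nox_run, truth


def simulate_msms(
    entry: LibraryEntry,
    polarity: str,
    n_decoys: int = 0,
    seed: int = 0,
    scan_time: float = 0.0,
    decoy_exclusion_ppm: float = 20.0,
) -> Spectrum:
    """A product-ion spectrum holding every rule-predicted fragment.

    Fragment intensities are drawn uniformly in [1e4, 1e6]; decoy peaks
    are uniform over the scan range but rejected within
    ``decoy_exclusion_ppm`` of any true fragment.
    """
    rng = np.random.default_rng(seed)
    frags = predict_fragments(entry, polarity)
    true_mz = np.array(sorted({round(f.mz.value, 6) for f in frags}))
    intensities = rng.uniform(1e4, 1e6, size=true_mz.size)
    mzs = list(true_mz)
    ints = list(intensities)
    placed = 0
    while placed < n_decoys:
        m = float(rng.uniform(100.0, max(1000.0, true_mz.max() + 50)))
        if np.all(np.abs(true_mz - m) > decoy_exclusion_ppm * 1e-6 * true_mz):
            mzs.append(m)
            ints.append(float(rng.uniform(1e3, 1e5)))
            placed += 1
    precursor = _entry_mz(entry, polarity)
    return Spectrum(
        scan_time=scan_time,
        polarity=polarity,
        ms_level=2,
        precursor_mz=precursor,
        mz=np.array(mzs),
        intensity=np.array(ints),
    )


def simulate_msi(
    seed: int,
    shape: Tuple[int, int] = (48, 64),
    pattern: str = "pericentral-zonation",
    background: float = 100.0,
    contrast: float = 8.0,
    n_centers: int = 6,
    radius_px: int = 6,
    noise_cv: float = 0.10,
    pixel_pitch_um: float = 60.0,
) -> Tuple[MsiGrid, np.ndarray]:
    """Liver-section-like transition raster with a boolean truth mask.

    'pericentral-zonation' puts ``n_centers`` elevated disks (mean
    ``background * contrast``) on a low background, mimicking signal
    around central veins; 'uniform' is flat.  Multiplicative log-normal
    noise at ``noise_cv`` is applied everywhere.  ``background`` 0 gives
    an all-zero grid.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    base = np.full(shape, float(background))
    mask = np.zeros(shape, dtype=bool)
    if pattern == "pericentral-zonation":
        yy, xx = np.mgrid[0:ny, 0:nx]
        for _ in range(n_centers):
            cy = rng.integers(radius_px, ny - radius_px)
            cx = rng.integers(radius_px, nx - radius_px)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
            mask |= disk
        base[mask] *= contrast
    elif pattern != "uniform":
        raise SyntheticError(f"unknown MSI pattern {pattern!r}")
    noise = rng.lognormal(0.0, noise_cv, size=shape)
    grid = MsiGrid(base * noise, pixel_pitch_um=pixel_pitch_um)
    return grid, mask
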