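"""Simplified nontargeted LC-MS feature workflow.

Re-implements the differential (oxidized vs nonoxidized) screen as four
desk-scale steps: centroid feature detection by chaining peaks across
consecutive scans, retention-time alignment by median-shift correction,
[M-H]-/[M+HCOO]- adduct grouping, and the >2.0 oxidized/nonoxidized
area-ratio background subtraction.  Defaults mirror a high-resolution
Orbitrap workflow: 5 ppm mass tolerance, S/N 3, minimum apex intensity
10,000, three scans per peak, 0.1 min maximum RT shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import C13_C12_DELTA, MzValue, mass_of

__all__ = [
    "Spectrum",
    "Feature",
    "DetectionParams",
    "PeakprocError",
    "detect_features",
    "align_runs",
    "group_adducts",
    "background_subtract",
    "extract_eic",
    "FORMIC_ACID_MASS",
]

#: Mass separating [M-H]- from [M+HCOO]- of the same compound.
FORMIC_ACID_MASS = mass_of("CH2O2")


class PeakprocError(ValueError):
    pass


@dataclass
class Spectrum:
    """One centroided scan: peaks sorted ascending by m/z."""

    scan_time: float  # minutes
    polarity: str  # '+' or '-'
    ms_level: int = 1
    precursor_mz: Optional[float] = None
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise PeakprocError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise PeakprocError("negative peak intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.ms_level == 2 and self.precursor_mz is None:
            raise PeakprocError("MS2 spectrum requires a precursor m/z")


@dataclass
class Feature:
    """An aligned LC-MS signal: one chromatographic peak of one ion."""

    mz: float
    rt: float  # apex retention time, minutes
    area: float
    apex_intensity: float
    sample_id: str = ""
    scan_count: int = 0
    is_isotopologue: bool = False
    ms2: List[Spectrum] = field(default_factory=list)


@dataclass(frozen=True)
class DetectionParams:
    ppm_tol: float = 5.0
    sn_threshold: float = 3.0
    min_intensity: float = 10_000.0
    min_scans: int = 3
    min_isotopes: int = 1
    max_rt_shift: float = 0.1  # minutes

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "sn_threshold", "min_intensity", "min_scans", "max_rt_shift"):
            if getattr(self, name) <= 0:
                raise PeakprocError(f"{name} must be strictly positive")


def _chain_centroids(run: Sequence[Spectrum], ppm_tol: float) -> List[List[Tuple[int, int]]]:
    """Greedily chain centroids across consecutive MS1 scans within tolerance.

    Returns lists of (scan_index, peak_index) pairs, one list per chain.
    """
    chains: List[List[Tuple[int, int]]] = []
    open_chains: List[List[Tuple[int, int]]] = []
    for si, spec in enumerate(run):
        if spec.ms_level != 1:
            continue
        used = np.zeros(spec.mz.size, dtype=bool)
        next_open: List[List[Tuple[int, int]]] = []
        for chain in open_chains:
            last_si, last_pi = chain[-1]
            target = run[last_si].mz[last_pi]
            tol = target * ppm_tol * 1e-6
            lo = np.searchsorted(spec.mz, target - tol)
            hi = np.searchsorted(spec.mz, target + tol, side="right")
            cands = [p for p in range(lo, hi) if not used[p]]
            if cands:
                best = max(cands, key=lambda p: spec.intensity[p])
                used[best] = True
                chain.append((si, best))
                next_open.append(chain)
            else:
                chains.append(chain)
        for p in range(spec.mz.size):
            if not used[p]:
                next_open.append([(si, p)])
        open_chains = next_open
    chains.extend(open_chains)
    return chains


def _local_noise(
    run: Sequence[Spectrum], chain: List[Tuple[int, int]], mz: float, ppm_tol: float
) -> float:
    """Median absolute intensity of same-m/z-window centroids outside the chain."""
    member = set(chain)
    tol = mz * 2 * ppm_tol * 1e-6
    vals = []
    for si, spec in enumerate(run):
        if spec.ms_level != 1:
            continue
        lo = np.searchsorted(spec.mz, mz - tol)
        hi = np.searchsorted(spec.mz, mz + tol, side="right")
        for p in range(lo, hi):
            if (si, p) not in member:
                vals.append(spec.intensity[p])
    return max(float(np.median(vals)) if vals else 0.0, 1.0)


def detect_features(run: Sequence[Spectrum], params: DetectionParams = DetectionParams(),
                    sample_id: str = "") -> List[Feature]:
    """Detect chromatographic features in one centroided MS1 run.

    A chain of co-m/z centroids becomes a feature iff it spans at least
    ``min_scans`` scans, its apex exceeds ``min_intensity`` and
    ``sn_threshold`` times the local noise, and (when ``min_isotopes``
    >= 1) a lower-abundance +1.00336 Da isotopologue partner co-elutes.
    Partner chains themselves are reported as isotopologues and dropped.
    Area is the trapezoidal integral over the chain (intensity * min).
    """
    if not run:
        raise PeakprocError("run is empty")
    pols = {s.polarity for s in run}
    if len(pols) > 1:
        raise PeakprocError(f"mixed polarity run: {sorted(pols)}")

    ms1 = [s for s in run if s.ms_level == 1]
    if not ms1:
        raise PeakprocError("run has no MS1 spectra")
    chains = _chain_centroids(ms1, params.ppm_tol)

    cands = []
    for chain in chains:
        if len(chain) < params.min_scans:
            continue
        times = np.array([ms1[si].scan_time for si, _ in chain])
        ints = np.array([ms1[si].intensity[pi] for si, pi in chain])
        mzs = np.array([ms1[si].mz[pi] for si, pi in chain])
        apex = float(ints.max())
        if apex < params.min_intensity:
            continue
        mz = float(np.average(mzs, weights=ints))
        cands.append(
            dict(
                chain=chain,
                mz=mz,
                rt=float(times[int(np.argmax(ints))]),
                t0=float(times[0]),
                t1=float(times[-1]),
                area=float(np.trapezoid(ints, times)),
                apex=apex,
                n=len(chain),
            )
        )

    features = []
    for c in cands:
        noise = _local_noise(ms1, c["chain"], c["mz"], params.ppm_tol)
        if c["apex"] / noise < params.sn_threshold:
            continue
        # isotopologue bookkeeping against all candidates (pre-S/N)
        is_partner_of_heavier = False
        has_partner = False
        for other in cands:
            if other is c:
                continue
            overlap = min(c["t1"], other["t1"]) - max(c["t0"], other["t0"])
            if overlap < 0:
                continue
            delta = other["mz"] - c["mz"]
            tol = c["mz"] * 2 * params.ppm_tol * 1e-6
            if abs(delta - C13_C12_DELTA) <= tol and other["apex"] < c["apex"]:
                has_partner = True
            if abs(delta + C13_C12_DELTA) <= tol and other["apex"] > c["apex"]:
                is_partner_of_heavier = True
        if is_partner_of_heavier:
            continue  # this chain is the 13C partner of a monoisotopic feature
        if params.min_isotopes >= 1 and not has_partner:
            continue
        features.append(
            Feature(
                mz=c["mz"],
                rt=c["rt"],
                area=c["area"],
                apex_intensity=c["apex"],
                sample_id=sample_id,
                scan_count=c["n"],
            )
        )
    return sorted(features, key=lambda f: (f.mz, f.rt))


def extract_eic(run: Sequence[Spectrum], target: MzValue | float, tol_ppm: float
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Extracted ion chromatogram: per-MS1-scan summed intensity within +/-tol."""
    if not run:
        raise PeakprocError("run is empty")
    mz = target.value if isinstance(target, MzValue) else float(target)
    half = mz * tol_ppm * 1e-6
    times, ints = [], []
    for spec in run:
        if spec.ms_level != 1:
            continue
        lo = np.searchsorted(spec.mz, mz - half)
        hi = np.searchsorted(spec.mz, mz + half, side="right")
        times.append(spec.scan_time)
        ints.append(float(spec.intensity[lo:hi].sum()))
    return np.array(times), np.array(ints)


def _median_shift(a: List[Feature], b: List[Feature], ppm_tol: float, max_shift: float) -> float:
    """Median RT offset (b relative to a) over mutual best matches."""
    deltas = []
    for fa in a:
        tol = fa.mz * ppm_tol * 1e-6
        near = [fb for fb in b if abs(fb.mz - fa.mz) <= tol and abs(fb.rt - fa.rt) <= max_shift]
        if not near:
            continue
        fb = min(near, key=lambda f: abs(f.rt - fa.rt))
        # mutual: fa must be fb's best match too
        back = [fx for fx in a if abs(fx.mz - fb.mz) <= tol and abs(fx.rt - fb.rt) <= max_shift]
        if back and min(back, key=lambda f: abs(f.rt - fb.rt)) is fa:
            deltas.append(fb.rt - fa.rt)
    return float(np.median(deltas)) if deltas else 0.0


def align_runs(
    feature_sets: Sequence[Sequence[Feature]],
    ppm_tol: float = 5.0,
    max_shift: float = 0.1,
) -> List[List[Optional[Feature]]]:
    """Group features across runs within 5 ppm / ``max_shift`` minutes.

    A per-run median RT shift is estimated from mutual best matches to
    the first run (anchors found inside the +/-``max_shift`` window) and
    subtracted before grouping, so a systematic drift slightly beyond the
    window is recovered as long as some anchors fall inside it; with no
    anchors, no correction is applied.  Grouping itself is greedy on the
    combined (ppm, dRT) distance, pairing closest candidates first so the
    result does not depend on run order.  Each group is a list with one
    slot per run (None when absent).
    """
    if len(feature_sets) < 2:
        raise PeakprocError("alignment needs at least two runs")
    sets = [list(fs) for fs in feature_sets]
    ref = sets[0]
    shifts = [0.0] + [
        _median_shift(ref, s, ppm_tol, max_shift) for s in sets[1:]
    ]
    corrected: List[List[Tuple[Feature, float]]] = [
        [(f, f.rt - shifts[ri]) for f in s] for ri, s in enumerate(sets)
    ]

    # seed groups from run 0, then attach best candidates from later runs
    groups: List[List[Optional[Feature]]] = []
    group_anchor: List[Tuple[float, float]] = []
    for f, rt in corrected[0]:
        groups.append([f] + [None] * (len(sets) - 1))
        group_anchor.append((f.mz, rt))
    for ri in range(1, len(sets)):
        pairs = []
        for gi, (gmz, grt) in enumerate(group_anchor):
            tol = gmz * ppm_tol * 1e-6
            for fi, (f, rt) in enumerate(corrected[ri]):
                if abs(f.mz - gmz) <= tol and abs(rt - grt) <= max_shift:
                    pairs.append((abs(f.mz - gmz) / tol + abs(rt - grt) / max_shift, gi, fi))
        pairs.sort()
        taken_g, taken_f = set(), set()
        for _, gi, fi in pairs:
            if gi in taken_g or fi in taken_f:
                continue
            taken_g.add(gi)
            taken_f.add(fi)
            groups[gi][ri] = corrected[ri][fi][0]
        for fi, (f, rt) in enumerate(corrected[ri]):
            if fi not in taken_f:
                g: List[Optional[Feature]] = [None] * len(sets)
                g[ri] = f
                groups.append(g)
                group_anchor.append((f.mz, rt))
    return groups


def group_adducts(
    features: Sequence[Feature],
    ppm_tol: float = 5.0,
    rt_tol: float = 0.1,
    mass_delta: float = FORMIC_ACID_MASS,
) -> List[List[Feature]]:
    """Merge co-eluting [M-H]-/[M+HCOO]- pairs into compounds.

    Two features whose m/z differ by the formic-acid mass within tolerance
    and whose RTs agree within ``rt_tol`` become one compound, represented
    by its most abundant member (first element of each returned group).
    """
    feats = sorted(features, key=lambda f: f.mz)
    parent = list(range(len(feats)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, f in enumerate(feats):
        tol = f.mz * ppm_tol * 1e-6
        for j in range(i + 1, len(feats)):
            g = feats[j]
            if g.mz - f.mz > mass_delta + tol:
                break
            if abs((g.mz - f.mz) - mass_delta) <= tol and abs(g.rt - f.rt) <= rt_tol:
                parent[find(j)] = find(i)
    clusters: Dict[int, List[Feature]] = {}
    for i, f in enumerate(feats):
        clusters.setdefault(find(i), []).append(f)
    return [sorted(grp, key=lambda f: -f.area) for grp in clusters.values()]


def background_subtract(
    oxidized: pd.DataFrame | Dict[str, float],
    nonoxidized: pd.DataFrame | Dict[str, float],
    ratio_threshold: float = 2.0,
) -> List[str]:
    """Oxidation-product screen: keep compounds with area ratio > threshold.

    Inputs map compound keys to areas (dict, or DataFrame with an ``area``
    column indexed by compound).  A compound absent (or zero) in the
    nonoxidized channel but present in the oxidized one is retained: the
    screen is a presence filter and an empty blank is the strongest
    possible evidence.  The comparison is strict (ratio exactly equal to
    the threshold is dropped).
    """
    def to_map(t) -> Dict[str, float]:
        if isinstance(t, pd.DataFrame):
            return dict(t["area"])
        return dict(t)

    ox, blank = to_map(oxidized), to_map(nonoxidized)
    for name, table in (("oxidized", ox), ("nonoxidized", blank)):
        for k, v in table.items():
            if v < 0:
                raise PeakprocError(f"negative area for {k!r} in {name} table")
    retained = []
    for key, a_ox in ox.items():
        a_bg = blank.get(key, 0.0)
        if a_bg == 0.0:
            if a_ox > 0:
                retained.append(key)
        elif a_ox / a_bg > ratio_threshold:
            retained.append(key)
    return retained
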