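"""Feature detection, alignment, adduct grouping and background subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxpclib.chem import C13_C12_DELTA
from oxpclib.peakproc import (
    DetectionParams,
    Feature,
    FORMIC_ACID_MASS,
    PeakprocError,
    Spectrum,
    align_runs,
    background_subtract,
    detect_features,
    extract_eic,
    group_adducts,
)


def gaussian_run(
    compounds,
    t0=0.0,
    t1=2.0,
    dt=0.02,
    sigma=0.05,
    polarity="-",
    isotope_fraction=0.35,
):
    """Noise-free MS1 run: list of (mz, rt, apex) with a 13C partner each."""
    times = np.arange(t0, t1, dt)
    run = []
    for t in times:
        mzs, ints = [], []
        for mz, rt, apex in compounds:
            h = apex * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
            if h >= 1.0:
                mzs.extend([mz, mz + C13_C12_DELTA])
                ints.extend([h, h * isotope_fraction])
        run.append(Spectrum(t, polarity, 1, None, np.array(mzs), np.array(ints)))
    return run


class TestDetect:
    def test_single_trace_gives_one_feature(self):
        run = gaussian_run([(680.4144, 1.0, 5e5)])
        feats = detect_features(run, DetectionParams())
        assert len(feats) == 1
        f = feats[0]
        assert f.mz == pytest.approx(680.4144, abs=1e-3)
        assert f.rt == pytest.approx(1.0, abs=0.02)
        assert f.scan_count >= 8

    def test_below_min_intensity_dropped(self):
        run = gaussian_run([(680.4144, 1.0, 5e3)])
        assert detect_features(run, DetectionParams()) == []

    def test_two_scan_trace_dropped(self):
        run = gaussian_run([(680.4144, 1.0, 5e5)])
        two_scans = []
        kept = 0
        for s in run:
            if s.mz.size and kept < 2:
                kept += 1
                two_scans.append(s)
            elif not s.mz.size:
                two_scans.append(s)
        assert detect_features(two_scans, DetectionParams()) == []

    def test_isotopologue_requirement(self):
        run = gaussian_run([(680.4144, 1.0, 5e5)], isotope_fraction=0.0)
        # +1 partner absent: dropped when min_isotopes = 1
        assert detect_features(run, DetectionParams()) == []
        assert len(detect_features(run, DetectionParams(min_isotopes=0))) == 1

    def test_mixed_polarity_rejected(self):
        run = gaussian_run([(680.4144, 1.0, 5e5)])
        run[0].polarity = "+"
        with pytest.raises(PeakprocError, match="polarity"):
            detect_features(run, DetectionParams())

    def test_eic_area_matches_feature_area(self):
        run = gaussian_run([(680.4144, 1.0, 5e5)])
        f = detect_features(run, DetectionParams())[0]
        times, trace = extract_eic(run, 680.4144, tol_ppm=5.0)
        eic_area = float(np.trapezoid(trace, times))
        # EIC includes the 13C partner-free window only at the target m/z
        assert f.area == pytest.approx(eic_area, rel=0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        min_intensity=st.floats(1e3, 1e6),
        sn=st.floats(1.0, 50.0),
        seed=st.integers(0, 2**16),
    )
    def test_detection_monotone_in_thresholds(self, min_intensity, sn, seed):
        rng = np.random.default_rng(seed)
        compounds = [
            (float(rng.uniform(400, 900)), float(rng.uniform(0.3, 1.7)),
             float(rng.uniform(1e4, 1e6)))
            for _ in range(5)
        ]
        run = gaussian_run(compounds)
        base = len(detect_features(run, DetectionParams()))
        stricter = DetectionParams(min_intensity=max(10_000.0, min_intensity),
                                   sn_threshold=max(3.0, sn))
        assert len(detect_features(run, stricter)) <= base


class TestEic:
    def test_absent_mass_gives_zero_trace_of_full_length(self):
        run = gaussian_run([(680.4144, 1.0, 5e5)])
        times, trace = extract_eic(run, 500.0, tol_ppm=5.0)
        assert len(times) == len(run)
        assert np.all(trace == 0.0)

    def test_single_spike_localized(self):
        run = gaussian_run([(680.4144, 1.0, 5e5)])
        spike_scan = 10
        run[spike_scan] = Spectrum(
            run[spike_scan].scan_time, "-", 1, None, np.array([555.0]), np.array([777.0])
        )
        times, trace = extract_eic(run, 555.0, tol_ppm=5.0)
        assert trace[spike_scan] == 777.0
        assert np.count_nonzero(trace) == 1

    def test_zero_tolerance_exact_only(self):
        run = [Spectrum(0.0, "-", 1, None, np.array([500.0, 500.001]), np.array([10.0, 20.0]))]
        _, trace = extract_eic(run, 500.0, tol_ppm=0.0)
        assert trace[0] == 10.0


def _features(pairs, sample="s"):
    return [Feature(mz=m, rt=t, area=a, apex_intensity=a, sample_id=sample)
            for m, t, a in pairs]


class TestAlign:
    def test_constant_shift_pairs_all(self):
        a = _features([(600.0, 5.0, 1e5), (700.0, 7.0, 1e5), (800.0, 9.0, 1e5)])
        b = _features([(600.0, 5.05, 1e5), (700.0, 7.05, 1e5), (800.0, 9.05, 1e5)])
        groups = align_runs([a, b], max_shift=0.1)
        paired = [g for g in groups if all(f is not None for f in g)]
        assert len(paired) == 3 and len(groups) == 3

    def test_shift_outside_window_without_anchor(self):
        a = _features([(600.0, 5.0, 1e5)])
        b = _features([(600.0, 5.2, 1e5)])
        groups = align_runs([a, b], max_shift=0.1)
        assert all(None in g for g in groups) and len(groups) == 2

    def test_median_shift_correction_restores_pairing(self):
        # one anchor inside the window estimates the systematic drift,
        # rescuing features whose raw offset exceeds the window
        a = _features([(600.0, 5.0, 1e5), (700.0, 7.0, 1e5), (800.0, 9.0, 1e5)])
        b = _features([(600.0, 5.08, 1e5), (700.0, 7.15, 1e5), (800.0, 9.15, 1e5)])
        groups = align_runs([a, b], max_shift=0.1)
        paired = [g for g in groups if all(f is not None for f in g)]
        assert len(paired) == 3

    def test_alignment_symmetric_in_run_order(self):
        a = _features([(600.0, 5.0, 1e5), (700.0, 7.0, 2e5)], "a")
        b = _features([(600.0, 5.03, 3e5), (750.0, 8.0, 4e5)], "b")
        g_ab = align_runs([a, b])
        g_ba = align_runs([b, a])
        pairs_ab = {
            tuple(sorted((f.mz, f.sample_id) for f in g if f is not None)) for g in g_ab
        }
        pairs_ba = {
            tuple(sorted((f.mz, f.sample_id) for f in g if f is not None)) for g in g_ba
        }
        assert pairs_ab == pairs_ba


class TestGroupAdducts:
    def test_formate_pair_merges_to_most_abundant(self):
        fa = _features([(664.4190, 3.0, 2e5), (664.4190 + FORMIC_ACID_MASS, 3.02, 5e5)])
        groups = group_adducts(fa)
        assert len(groups) == 1
        assert groups[0][0].area == 5e5  # representative = larger area

    def test_rt_gate_keeps_separate(self):
        fa = _features([(664.4190, 3.0, 2e5), (664.4190 + FORMIC_ACID_MASS, 3.3, 5e5)])
        assert len(group_adducts(fa)) == 2

    def test_singleton_passthrough(self):
        fa = _features([(700.0, 3.0, 2e5)])
        assert group_adducts(fa) == [[fa[0]]]


class TestBackgroundSubtract:
    def test_ratio_rules(self):
        ox = {"a": 2.5e6, "b": 2.0e6, "c": 1.0e5, "d": 0.0}
        bg = {"a": 1.0e6, "b": 1.0e6, "c": 0.0, "d": 0.0}
        assert background_subtract(ox, bg) == ["a", "c"]

    def test_negative_area_rejected(self):
        with pytest.raises(PeakprocError, match="negative"):
            background_subtract({"a": -1.0}, {"a": 1.0})

    def test_noise_free_pair_retains_exactly_spiked_set(self):
        matrix = {f"m{i}": 1e6 for i in range(6)}
        spikes = {f"spike{i}": 5e5 for i in range(4)}
        ox = {**matrix, **spikes}
        assert sorted(background_subtract(ox, matrix)) == sorted(spikes)
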