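"""MS1 search: windows, XICs, thresholds, slope-rule isomer detection."""

import numpy as np
import pytest

from glyscreen.io import MS1DatabaseEntry, Scan, ScanSet
from glyscreen.ms1 import (
    MS1Params,
    _slope_peak_indices,
    align_lc_to_ms,
    build_xic,
    detect_isomer_peaks,
    find_primary_peak,
    mz_window,
    run_ms1,
)
from glyscreen.masses import mz_from_mass
from glyscreen.simulate import make_lc_trace, make_run, PlantSpec


def _scanset_from_profile(mz0, profile, rt0=10.0, dt=0.02, base_extra=None):
    """MS1 scans with one stick at mz0 following the intensity profile."""
    scans = []
    for i, y in enumerate(profile):
        mzs, ys = [], []
        if y > 0:
            mzs.append(mz0)
            ys.append(float(y))
        if base_extra is not None:
            mzs.append(base_extra[0])
            ys.append(base_extra[1])
        scans.append(Scan(i + 1, 1, rt0 + i * dt, np.array(mzs), np.array(ys)))
    return ScanSet(scans)


class TestMzWindow:
    def test_ppm_half_width(self):
        entry = MS1DatabaseEntry("X", 1843.8)
        lo, hi = mz_window(entry, 2, MS1Params())
        center = mz_from_mass(1843.8, 2)
        assert (hi - lo) / 2 == pytest.approx(center * 10e-6, rel=1e-9)
        assert lo < center < hi

    def test_da_tolerance_scales_with_charge(self):
        entry = MS1DatabaseEntry("X", 1843.8)
        params = MS1Params(tolerance=0.5, tolerance_unit="Da")
        lo, hi = mz_window(entry, 2, params)
        assert (hi - lo) / 2 == pytest.approx(0.25)


class TestSlopeRule:
    def test_triangle_has_single_apex_peak(self):
        profile = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1], dtype=float)
        assert _slope_peak_indices(profile) == [4]

    def test_flat_profile_no_peaks(self):
        assert _slope_peak_indices(np.full(10, 3.0)) == []

    def test_one_noisy_slope_tolerated(self):
        # dip on the rising flank: 3 of 4 slopes before apex still positive
        profile = np.array([1, 3, 2, 4, 6, 8, 5, 3, 2, 1], dtype=float)
        assert 5 in _slope_peak_indices(profile)

    def test_two_gaussians_two_peaks(self):
        rt = np.arange(0, 2, 0.02)
        y = np.exp(-0.5 * ((rt - 0.6) / 0.08) ** 2) + 0.5 * np.exp(
            -0.5 * ((rt - 1.4) / 0.08) ** 2
        )
        peaks = _slope_peak_indices(y)
        assert len(peaks) == 2
        assert rt[peaks[0]] == pytest.approx(0.6, abs=0.03)
        assert rt[peaks[1]] == pytest.approx(1.4, abs=0.03)


class TestPrimaryPeak:
    def test_picks_planted_maximum(self):
        profile = np.array([0, 10, 100, 10, 0], dtype=float)
        scans = _scanset_from_profile(922.9, profile)
        xic = build_xic(scans, (922.85, 922.95))
        cand = find_primary_peak(xic, scans, MS1Params())
        assert cand is not None
        assert cand.intensity == 100.0
        assert cand.observed_mz == pytest.approx(922.9)

    def test_relative_threshold_blocks_small_peak(self):
        # planted peak is only 20% of the co-eluting base peak
        profile = np.array([0, 20, 0], dtype=float)
        scans = _scanset_from_profile(922.9, profile, base_extra=(600.0, 100.0))
        xic = build_xic(scans, (922.85, 922.95))
        assert find_primary_peak(xic, scans, MS1Params(threshold=25.0)) is None
        assert find_primary_peak(xic, scans, MS1Params(threshold=15.0)) is not None

    def test_same_mz_two_rts_both_full_relative(self):
        # relative intensity is per scan: both isolated peaks are 100%
        profile = np.array([0, 50, 0, 0, 80, 0], dtype=float)
        scans = _scanset_from_profile(922.9, profile)
        xic = build_xic(scans, (922.85, 922.95))
        cand = find_primary_peak(xic, scans, MS1Params())
        assert cand.relative_intensity == 100.0

    def test_empty_window_returns_none(self):
        scans = _scanset_from_profile(922.9, np.array([1.0, 2.0, 1.0]))
        xic = build_xic(scans, (500.0, 500.1))
        assert find_primary_peak(xic, scans, MS1Params()) is None


class TestIsomerDetection:
    def test_three_gaussians_numbered_by_rt(self):
        rt0, dt = 12.0, 0.02
        rts = np.arange(rt0, 16.0, dt)
        apexes = [(13.39, 7.59e6), (13.78, 1.61e6), (14.08, 3.6e5)]
        profile = sum(
            a * np.exp(-0.5 * ((rts - c) / 0.06) ** 2) for c, a in apexes
        )
        scans = _scanset_from_profile(922.9, profile, rt0=rt0, dt=dt)
        xic = build_xic(scans, (922.85, 922.95))
        params = MS1Params()
        primary = find_primary_peak(xic, scans, params)
        peaks = detect_isomer_peaks(xic, primary, 3, scans, params)
        assert len(peaks) == 3
        found_rts = [p.rt for p in peaks]
        assert found_rts == sorted(found_rts)
        for (center, _), rt in zip(apexes, found_rts):
            assert rt == pytest.approx(center, abs=dt + 1e-9)

    def test_flat_profile_primary_only(self):
        profile = np.array([0, 0, 100, 0, 0], dtype=float)
        scans = _scanset_from_profile(922.9, profile)
        xic = build_xic(scans, (922.85, 922.95))
        params = MS1Params()
        primary = find_primary_peak(xic, scans, params)
        peaks = detect_isomer_peaks(xic, primary, 3, scans, params)
        assert len(peaks) == 1
        assert peaks[0].rt == primary.rt

    def test_cap_at_n_isomers(self):
        rts = np.arange(12.0, 16.0, 0.02)
        profile = sum(
            1e6 * np.exp(-0.5 * ((rts - c) / 0.06) ** 2) for c in (13.3, 13.7, 14.1)
        )
        scans = _scanset_from_profile(922.9, profile, rt0=12.0)
        xic = build_xic(scans, (922.85, 922.95))
        params = MS1Params()
        primary = find_primary_peak(xic, scans, params)
        assert len(detect_isomer_peaks(xic, primary, 2, scans, params)) == 2


class TestLCAlignment:
    def test_identical_apexes_zero_offset(self):
        plants = [PlantSpec("X", {"HeN": 4, "Hex": 3}, rts=(12.0,), apexes=(1e6,))]
        scans, lc, _ = make_run(3, plants)
        assert align_lc_to_ms(lc, scans) == pytest.approx(0.0, abs=0.03)

    def test_shifted_lc_recovered(self):
        plants = [PlantSpec("X", {"HeN": 4, "Hex": 3}, rts=(12.0,), apexes=(1e6,))]
        scans, lc, _ = make_run(3, plants, lc_offset=0.3)
        # LC runs 0.3 min behind the MS: offset maps LC time -> MS time
        assert align_lc_to_ms(lc, scans) == pytest.approx(-0.3, abs=0.03)


class TestRunMS1:
    def test_single_plant_recovered(self):
        plants = [PlantSpec("A2G0", {"HeN": 4, "Hex": 3}, rts=(12.0,), apexes=(1e6,))]
        scans, _, truth = make_run(42, plants)
        db = [MS1DatabaseEntry("A2G0", plants[0].labeled_mass())]
        hits = run_ms1(scans, db)
        assert len(hits) == 1
        assert hits[0].name == "A2G0"
        assert hits[0].rt == pytest.approx(12.0, abs=0.021)
        assert hits[0].relative_intensity == 100.0
        assert abs(hits[0].ppm_error) <= 10.0

    def test_three_same_mass_entries_nine_rows(self, study_scenario):
        plants, db, decoys, scans, lc, truth = study_scenario
        trio = [e for e in db if e.name.startswith(("A1G1F", "A2G0M4F"))]
        hits = run_ms1(scans, trio)
        assert len(hits) == 9  # 3 glycans x 3 isomer peaks
        for name in {e.name for e in trio}:
            assert sorted(h.isomer_peak for h in hits if h.name == name) == [1, 2, 3]

    def test_tolerance_below_planted_error_no_hits(self):
        plants = [
            PlantSpec("A2G0", {"HeN": 4, "Hex": 3}, rts=(12.0,), apexes=(1e6,), jitter_ppm=5.0)
        ]
        scans, _, truth = make_run(13, plants)
        jitter = abs(truth["jitter_ppm"].iloc[0])
        assert jitter > 0.2
        db = [MS1DatabaseEntry("A2G0", plants[0].labeled_mass())]
        params = MS1Params(tolerance=jitter * 0.2)
        assert run_ms1(scans, db, params) == []

    def test_hits_satisfy_own_contract(self, study_scenario):
        plants, db, decoys, scans, lc, truth = study_scenario
        params = MS1Params()
        hits = run_ms1(scans, db, params)
        for h in hits:
            assert abs(h.ppm_error) <= params.tolerance
            assert 0 < h.relative_intensity <= 100
            assert h.relative_intensity >= params.threshold

    def test_db_rt_restriction_finds_planted_peak(self):
        plants = [PlantSpec("A2G0", {"HeN": 4, "Hex": 3}, rts=(12.0,), apexes=(1e6,))]
        scans, _, _ = make_run(5, plants)
        db = [MS1DatabaseEntry("A2G0", plants[0].labeled_mass(), rt=12.1)]
        hits = run_ms1(scans, db)
        assert len(hits) == 1
        assert hits[0].rt == pytest.approx(12.0, abs=0.021)

    def test_lc_restriction_hits_subset_of_unrestricted(self, study_scenario):
        plants, db, decoys, scans, lc, truth = study_scenario
        free = {(h.name, h.isomer_peak, h.charge) for h in run_ms1(scans, db)}
        restricted = {
            (h.name, h.isomer_peak, h.charge) for h in run_ms1(scans, db, lc=lc)
        }
        assert restricted <= free

    def test_empty_db_warns(self, study_scenario):
        plants, db, decoys, scans, lc, truth = study_scenario
        with pytest.warns(UserWarning):
            assert run_ms1(scans, []) == []
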