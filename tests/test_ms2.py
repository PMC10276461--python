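"""MS2 confirmation: scan location, fragment matching, details statistics."""

import numpy as np
import pytest

from glyscreen.fragments import enumerate_fragments, parse_structure_code
from glyscreen.io import Scan, ScanSet
from glyscreen.masses import adduct_mz, mz_from_mass
from glyscreen.ms1 import MS1Hit
from glyscreen.ms2 import (
    MS2Params,
    compute_details,
    locate_ms2_scan,
    match_fragments,
    run_ms2,
    MS2Result,
)


def _hit(mass=1843.7708, rt=13.39, z=2):
    return MS1Hit(
        name="A1G1F(a1,3)",
        isomer_peak=1,
        rt=rt,
        charge=z,
        observed_mz=mz_from_mass(mass, z),
        theoretical_mass=mass,
        observed_mass=mass,
        ppm_error=0.0,
        intensity=1e6,
        relative_intensity=100.0,
    )


def _ms2_scan(rt, precursor_mz, mzs, intens, num=100, z=2):
    return Scan(
        num, 2, rt, np.asarray(mzs, float), np.asarray(intens, float),
        precursor_mz=precursor_mz, precursor_charge=z,
    )


def _ms1_pad(rt):
    return Scan(1, 1, rt, np.array([500.0]), np.array([1.0]))


class TestLocateScan:
    def test_scan_shortly_after_hit_selected(self):
        hit = _hit()
        prec = mz_from_mass(hit.theoretical_mass, 2)
        scans = ScanSet([_ms1_pad(13.0), _ms2_scan(13.44, prec, [200.0], [10.0])])
        scan = locate_ms2_scan(scans, hit)
        assert scan is not None and scan.rt == pytest.approx(13.44)

    def test_scan_before_backward_window_rejected(self):
        hit = _hit(rt=13.39)
        prec = mz_from_mass(hit.theoretical_mass, 2)
        scans = ScanSet([_ms1_pad(12.0), _ms2_scan(12.89, prec, [200.0], [10.0])])
        assert locate_ms2_scan(scans, hit) is None

    def test_first_of_two_candidates_wins(self):
        hit = _hit(rt=13.39)
        prec = mz_from_mass(hit.theoretical_mass, 2)
        scans = ScanSet(
            [
                _ms2_scan(13.41, prec, [200.0], [10.0], num=5),
                _ms2_scan(13.69, prec, [200.0], [10.0], num=6),
            ]
        )
        assert locate_ms2_scan(scans, hit).num == 5

    def test_wrong_precursor_charge_skipped(self):
        hit = _hit(z=2)
        prec = mz_from_mass(hit.theoretical_mass, 2)
        scans = ScanSet([_ms2_scan(13.44, prec, [200.0], [10.0], z=3)])
        assert locate_ms2_scan(scans, hit) is None

    def test_missing_precursor_charge_matches_with_warning(self):
        hit = _hit(z=2)
        prec = mz_from_mass(hit.theoretical_mass, 2)
        scan = _ms2_scan(13.44, prec, [200.0], [10.0])
        scan.precursor_charge = None
        with pytest.warns(UserWarning, match="precursor charge"):
            assert locate_ms2_scan(ScanSet([scan]), hit) is not None


@pytest.fixture(scope="module")
def frag_set():
    return enumerate_fragments(
        parse_structure_code(
            "GlN(Fuc)GlN Man(Man[a1,3] GlN Gal)(Man[a1,6] GlN)", "A1G1F(a1,3)"
        )
    )


class TestMatchFragments:
    def test_plain_b_ion_annotated(self, frag_set):
        b = next(f for f in frag_set if f.ion_class == "B")
        mz = mz_from_mass(b.neutral_mass, 1)
        scan = _ms2_scan(13.44, 922.9, [mz, 1500.0], [50.0, 100.0])
        anns = match_fragments(scan, frag_set)
        matched = [a for a in anns if a.matches]
        assert len(matched) == 1
        assert matched[0].matches[0].adduct is None
        assert abs(matched[0].matches[0].ppm) < 1e-6

    def test_sodium_adduct_annotated(self, frag_set):
        b = next(f for f in frag_set if f.ion_class == "B")
        mz = mz_from_mass(b.neutral_mass, 1) + 21.98194
        scan = _ms2_scan(13.44, 922.9, [mz, 1500.0], [50.0, 100.0])
        matched = [a for a in match_fragments(scan, frag_set) if a.matches]
        assert matched and matched[0].matches[0].adduct == "+Na"

    def test_sub_threshold_peak_unannotated(self, frag_set):
        b = next(f for f in frag_set if f.ion_class == "B")
        mz = mz_from_mass(b.neutral_mass, 1)
        scan = _ms2_scan(13.44, 922.9, [mz, 1500.0], [2.0, 100.0])
        anns = match_fragments(scan, frag_set)
        assert all(a.mz != pytest.approx(mz) for a in anns)

    def test_at_most_two_annotations_ranked(self, frag_set):
        # pick a mass shared by several fragments (isomeric pieces)
        from collections import Counter

        counts = Counter(round(f.neutral_mass, 4) for f in frag_set)
        mass = next(m for m, c in counts.items() if c >= 3)
        scan = _ms2_scan(13.44, 922.9, [mz_from_mass(mass, 1)], [100.0])
        anns = match_fragments(scan, frag_set)
        assert len(anns[0].matches) == 2
        # ranked: no-adduct before adduct, then |ppm|, then fewer cuts
        m1, m2 = anns[0].matches
        assert m1.adduct is None
        assert m1.cut_count <= m2.cut_count or m2.adduct is not None

    def test_raising_threshold_never_adds_annotations(self, frag_set):
        rng = np.random.default_rng(0)
        mzs = [mz_from_mass(f.neutral_mass, 1) for f in list(frag_set)[:8]]
        intens = rng.uniform(2.0, 100.0, size=len(mzs))
        intens[0] = 100.0
        scan = _ms2_scan(13.44, 922.9, sorted(mzs), intens)
        n_prev = None
        for thr in (1.0, 5.0, 20.0, 60.0):
            n = sum(
                bool(a.matches)
                for a in match_fragments(scan, frag_set, MS2Params(label_threshold=thr))
            )
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_determinism(self, frag_set):
        mzs = [mz_from_mass(f.neutral_mass, 1) for f in list(frag_set)[:10]]
        scan = _ms2_scan(13.44, 922.9, sorted(mzs), np.linspace(100, 10, len(mzs)))
        a1 = match_fragments(scan, frag_set)
        a2 = match_fragments(scan, frag_set)
        assert [(a.mz, [(m.fragment_id, m.adduct) for m in a.matches]) for a in a1] == [
            (a.mz, [(m.fragment_id, m.adduct) for m in a.matches]) for a in a2
        ]


class TestComputeDetails:
    def test_half_matched_is_fifty_percent(self, frag_set):
        from glyscreen.fragments import multi_residue_unique_fragments

        qualifying = list(multi_residue_unique_fragments(frag_set))
        half = qualifying[: len(qualifying) // 2]
        mzs = sorted(mz_from_mass(f.neutral_mass, 1) for f in half)
        scan = _ms2_scan(13.44, 922.9, mzs, np.full(len(mzs), 80.0))
        result = MS2Result(
            name="A1G1F(a1,3)", rt=13.44, precursor_mz=922.9, charge=2,
            confirmed=True, annotations=match_fragments(scan, frag_set),
        )
        result = compute_details(result, frag_set)
        assert result.n_qualifying == len(qualifying)
        assert result.percent_identified == pytest.approx(
            100.0 * len(half) / len(qualifying)
        )

    def test_no_qualifying_fragments_undefined(self):
        fs = enumerate_fragments(parse_structure_code("Hex Hex"))
        # only single-residue pieces: nothing qualifies
        scan = _ms2_scan(1.0, 500.0, [400.0], [100.0])
        result = MS2Result(
            name="X", rt=1.0, precursor_mz=500.0, charge=1, confirmed=True,
            annotations=match_fragments(scan, fs),
        )
        result = compute_details(result, fs)
        assert result.n_qualifying == 0
        assert result.percent_identified is None

    def test_isomer_unique_masses_empty_for_arm_pair(self, a1g1f_fragments):
        f3, f6 = a1g1f_fragments
        mzs = sorted(mz_from_mass(f.neutral_mass, 1) for f in list(f3)[:5])
        scan = _ms2_scan(13.44, 922.9, mzs, np.full(len(mzs), 80.0))
        result = MS2Result(
            name="A1G1F(a1,3)", rt=13.44, precursor_mz=922.9, charge=2,
            confirmed=True, annotations=match_fragments(scan, f3),
        )
        result = compute_details(result, f3, isomer_sets=[f6])
        assert result.unique_masses_found == set()


class TestRunMS2:
    def test_select_all_confirms_planted(self, study_scenario):
        from glyscreen.ms1 import run_ms1

        plants, db, decoys, scans, lc, truth = study_scenario
        fragdb = {
            p.name: enumerate_fragments(parse_structure_code(p.structure_code, p.name))
            for p in plants
        }
        hits = run_ms1(scans, db)
        results = run_ms2(scans, hits, fragdb)
        confirmed = [r for r in results if r.confirmed]
        assert confirmed
        for r in confirmed:
            assert r.n_annotated_peaks >= 1
            assert all(len(a.matches) <= 2 for a in r.annotations)

    def test_glycan_without_scan_unconfirmed(self, frag_set):
        hit = _hit(rt=13.39)
        scans = ScanSet([_ms1_pad(13.0)])
        results = run_ms2(scans, [hit], {"A1G1F(a1,3)": frag_set})
        assert len(results) == 1 and not results[0].confirmed

    def test_unknown_selection_rejected(self, frag_set):
        hit = _hit()
        scans = ScanSet([_ms1_pad(13.0)])
        with pytest.raises(KeyError):
            run_ms2(
                scans, [hit], {"A1G1F(a1,3)": frag_set}, select=[("nope", 1.0)]
            )

    def test_same_glycan_two_rts_independent_results(self, frag_set):
        prec = mz_from_mass(1843.7708, 2)
        b = next(f for f in frag_set if f.ion_class == "B")
        mz = mz_from_mass(b.neutral_mass, 1)
        scans = ScanSet(
            [
                _ms2_scan(13.44, prec, [mz], [100.0], num=5),
                _ms2_scan(13.83, prec, [mz], [100.0], num=6),
            ]
        )
        hits = [_hit(rt=13.39), _hit(rt=13.78)]
        results = run_ms2(scans, hits, {"A1G1F(a1,3)": frag_set})
        assert [r.rt for r in results] == [pytest.approx(13.44), pytest.approx(13.83)]
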