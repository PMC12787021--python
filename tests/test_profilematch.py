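"""Quantification profiles, multiplet pattern matching, area extraction."""

import json
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qnmr1d import PatternSpec, QuantProfile
from qnmr1d import profilematch as pm
from qnmr1d import simulate as sim
from qnmr1d.peakproc import FitReport, PeakModel

from conftest import FREQ, make_simspec, singlet
from oracles import brute_force_best


def peak(ppm, area=1.0, amp=None, fwhm=1.0):
    a = amp if amp is not None else area / (np.pi / 2 * fwhm)
    return PeakModel(center_ppm=ppm, amplitude=a, fwhm_hz=fwhm, eta=1.0)


def doublet_peaks(center, j_hz, area_each=1.0):
    half = j_hz / 2 / FREQ
    return [peak(center - half, area_each), peak(center + half, area_each)]


class TestProfile:
    def test_default_profile_covers_all_signals(self, wine_profile):
        assert len(wine_profile.patterns) == 21
        names = {p.compound for p in wine_profile.patterns}
        assert len(names) == 21
        zgpr_only = {p.compound for p in wine_profile.patterns
                     if p.applicability == "zgpr"}
        assert zgpr_only == {"glycerol", "methanol"}

    def test_malic_acid_is_two_half_proton_doublets(self, wine_profile):
        malic = next(p for p in wine_profile.patterns
                     if p.compound == "malic acid")
        assert [s.center_ppm for s in malic.sub_signals] == [2.871, 2.903]
        assert all(s.multiplicity == "d" and s.j_hz == [4.5]
                   and s.proton_weight == 0.5 for s in malic.sub_signals)

    def test_empty_pattern_list_is_valid(self):
        prof = QuantProfile(patterns=[], rois=[])
        assert pm.extract_areas({}, prof, FREQ) == []

    def test_sub_signal_outside_rois_rejected(self):
        with pytest.raises(Exception, match="outside every ROI"):
            QuantProfile(
                rois=[{"name": "a", "ppm_low": 1.0, "ppm_high": 2.0}],
                patterns=[singlet(ppm=5.0)],
            )

    def test_duplicate_compounds_rejected(self):
        with pytest.raises(Exception, match="duplicate"):
            QuantProfile(
                rois=[{"name": "a", "ppm_low": 8.0, "ppm_high": 10.0}],
                patterns=[singlet(), singlet()],
            )

    def test_nonpositive_cf_rejected(self):
        with pytest.raises(Exception, match="correction factor"):
            QuantProfile(correction_factors={"x": 0.0})

    def test_json_and_yaml_round_trip(self, wine_profile, tmp_path):
        pm.save_profile(wine_profile, tmp_path / "p.json")
        back = pm.load_profile(tmp_path / "p.json")
        assert back == wine_profile
        (tmp_path / "p.yaml").write_text(
            json.dumps(wine_profile.model_dump()))  # JSON is valid YAML
        assert pm.load_profile(tmp_path / "p.yaml") == wine_profile


class TestCalibrateRoi:
    def test_on_target_zero_shift(self):
        peaks = [peak(2.08), peak(2.07)]
        shifted, shift, found = pm.calibrate_roi(peaks, (2.075, 2.085), 2.08)
        assert found and shift == pytest.approx(0.0, abs=1e-12)

    def test_displacement_restores_matching(self, wine_profile):
        trig = next(p for p in wine_profile.patterns
                    if p.compound == "trigonelline")
        displaced = [peak(9.14 + 0.015)]  # outside the 0.01 ppm tolerance
        assert not pm.match_pattern(displaced, trig, FREQ).matched
        shifted, shift, found = pm.calibrate_roi(
            displaced, (9.10, 9.20), 9.14)
        assert found and shift == pytest.approx(-0.015)
        assert pm.match_pattern(shifted, trig, FREQ).matched

    def test_absent_calibration_peak_flagged(self):
        peaks = [peak(2.08)]
        shifted, shift, found = pm.calibrate_roi(peaks, (5.0, 5.1), 5.05)
        assert not found and shift == 0.0
        assert [p.center_ppm for p in shifted] == [2.08]


class TestMatchPattern:
    def test_malic_acid_joint_doublets(self, wine_profile):
        malic = next(p for p in wine_profile.patterns
                     if p.compound == "malic acid")
        peaks = doublet_peaks(2.871, 4.5, 1.0) + doublet_peaks(2.903, 4.5, 1.2)
        res = pm.match_pattern(peaks, malic, FREQ)
        assert res.matched and not res.flags
        # per-proton area = sum of all four line areas / 1.0 total protons
        assert res.per_proton_area == pytest.approx(2 * 1.0 + 2 * 1.2)

    def test_empty_peak_list_unmatched(self, wine_profile):
        trig = next(p for p in wine_profile.patterns
                    if p.compound == "trigonelline")
        res = pm.match_pattern([], trig, FREQ)
        assert "unmatched" in res.flags
        assert res.per_proton_area is None

    def test_nearest_of_two_candidates_wins(self, wine_profile):
        trig = next(p for p in wine_profile.patterns
                    if p.compound == "trigonelline")
        peaks = [peak(9.147, area=5.0), peak(9.141, area=1.0)]
        res = pm.match_pattern(peaks, trig, FREQ)
        assert res.matched_peaks[0].center_ppm == pytest.approx(9.141)

    def test_wrong_j_rejected(self):
        p = PatternSpec(compound="d", mw=100.0, sub_signals=[
            {"multiplicity": "d", "center_ppm": 5.0, "j_hz": [8.0],
             "proton_weight": 1.0}])
        res = pm.match_pattern(doublet_peaks(5.0, 4.0), p, FREQ)  # J off by 4 Hz
        assert not res.matched

    def test_partial_match_flagged(self, wine_profile):
        cat = next(p for p in wine_profile.patterns
                   if p.compound == "catechin")
        peaks = doublet_peaks(5.99, 2.0, 1.0)  # only one of two doublets
        res = pm.match_pattern(peaks, cat, FREQ)
        assert res.matched and "partial" in res.flags
        assert res.matched_weight == pytest.approx(1.0)
        assert res.per_proton_area == pytest.approx(2.0)

    def test_invariant_to_peak_ordering(self, wine_profile):
        malic = next(p for p in wine_profile.patterns
                     if p.compound == "malic acid")
        peaks = (doublet_peaks(2.871, 4.5) + doublet_peaks(2.903, 4.5)
                 + [peak(2.93, 0.4), peak(2.85, 0.3)])
        ref = pm.match_pattern(peaks, malic, FREQ)
        rng = random.Random(1)
        for _ in range(5):
            shuffled = peaks[:]
            rng.shuffle(shuffled)
            res = pm.match_pattern(shuffled, malic, FREQ)
            assert res.score == pytest.approx(ref.score)
            assert sorted(p.center_ppm for p in res.matched_peaks) == \
                pytest.approx(sorted(p.center_ppm for p in ref.matched_peaks))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_exhaustive_search(self, data):
        """The chosen assignment's score equals the brute-force optimum for
        up to 8 candidate peaks."""
        pattern = PatternSpec(compound="x", mw=100.0, sub_signals=[
            {"multiplicity": "d", "center_ppm": 5.0, "j_hz": [6.0],
             "proton_weight": 1.0}])
        n = data.draw(st.integers(2, 8))
        ppms = data.draw(st.lists(
            st.floats(4.985, 5.015), min_size=n, max_size=n,
            unique_by=lambda v: round(v, 5)))
        peaks = [peak(p, area=1.0 + i * 0.1) for i, p in enumerate(ppms)]
        res = pm.match_pattern(peaks, pattern, FREQ)
        oracle_score, _ = brute_force_best(peaks, pattern, FREQ)
        if oracle_score is None:
            assert not res.matched
        else:
            assert res.matched
            assert res.score == pytest.approx(oracle_score, abs=1e-9)


class TestExtractAreas:
    def run_profile(self, profile, patterns_conc, pulse="noesy", points=131072):
        spec = make_simspec(patterns_conc, fwhm_hz=0.8, points=points)
        s = sim.render_spectrum(spec)
        fits = pm.process_rois(s, profile, pulse_program=pulse,
                               fit_asym=False)
        return pm.extract_areas(fits, profile, FREQ, pulse)

    def test_single_compound_single_result(self, wine_profile):
        trig = next(p for p in wine_profile.patterns
                    if p.compound == "trigonelline")
        results = self.run_profile(wine_profile, [(trig, 50.0)], points=65536)
        matched = [r for r in results if r.matched]
        assert [r.compound for r in matched] == ["trigonelline"]

    def test_glucose_three_outputs(self, wine_profile):
        pats = {p.compound: p for p in wine_profile.patterns}
        results = self.run_profile(
            wine_profile,
            [(pats["alpha-glucose"], 300.0), (pats["beta-glucose"], 500.0)],
            points=65536)
        matched = {r.compound: r for r in results if r.matched}
        assert {"alpha-glucose", "beta-glucose", "glucose"} <= set(matched)
        # the anomer combination pools areas over pooled proton weights
        a, b = matched["alpha-glucose"], matched["beta-glucose"]
        expected = ((a.per_proton_area * a.matched_weight
                     + b.per_proton_area * b.matched_weight)
                    / (a.matched_weight + b.matched_weight))
        assert matched["glucose"].per_proton_area == pytest.approx(expected)

    def test_zgpr_only_signals_skipped_for_noesy(self, wine_profile):
        pats = {p.compound: p for p in wine_profile.patterns}
        results = self.run_profile(wine_profile,
                                   [(pats["methanol"], 100.0)],
                                   pulse="noesy", points=65536)
        assert "methanol" not in {r.compound for r in results}
        results_zg = self.run_profile(wine_profile,
                                      [(pats["methanol"], 100.0)],
                                      pulse="zgpr", points=65536)
        matched = {r.compound for r in results_zg if r.matched}
        assert "methanol" in matched

    def test_area_linearity(self, wine_profile):
        """Doubling all concentrations doubles every per-proton area."""
        pats = {p.compound: p for p in wine_profile.patterns}
        use = [("trigonelline", 40.0), ("malic acid", 200.0)]
        res1 = self.run_profile(wine_profile,
                                [(pats[c], v) for c, v in use],
                                points=65536)
        res2 = self.run_profile(wine_profile,
                                [(pats[c], 2 * v) for c, v in use],
                                points=65536)
        a1 = {r.compound: r.per_proton_area for r in res1 if r.matched}
        a2 = {r.compound: r.per_proton_area for r in res2 if r.matched}
        for c, _ in use:
            assert a2[c] / a1[c] == pytest.approx(2.0, rel=5e-3)
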