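"""Peak detection, trapezoidal integration and family semiquantitation."""

import numpy as np
import pytest

from venompsc.psc import PSCTrace
from venompsc.quant import (
    classify_family,
    detect_peaks,
    family_abundance,
    integrate_peak,
    match_uv_peaks,
    summed_score,
)


def trace_of(values, dt=0.1, accession="T"):
    values = tuple(float(v) for v in values)
    rt = tuple(round(dt * (i + 0.5), 10) for i in range(len(values)))
    return PSCTrace(accession=accession, description="", rt_min=rt, values=values)


def brute_force_area(values, lo, hi, dt):
    """Independent trapezoid: zero anchors one step outside [lo, hi]."""
    ys = [0.0] + [float(v) for v in values[lo : hi + 1]] + [0.0]
    return sum(0.5 * (a + b) * dt for a, b in zip(ys, ys[1:]))


class TestDetectPeaks:
    def test_unimodal_run_is_one_peak_with_central_apex(self):
        peaks = detect_peaks(trace_of([0, 100, 200, 100, 0]))
        assert len(peaks) == 1
        assert peaks[0].apex_value == 200.0
        assert peaks[0].apex_rt == pytest.approx(0.25)
        assert peaks[0].n_fractions == 3

    def test_gap_wider_than_tolerance_splits(self):
        peaks = detect_peaks(trace_of([0, 100, 0, 0, 100, 0]), gap_tolerance=1)
        assert len(peaks) == 2

    def test_gap_within_tolerance_absorbed(self):
        peaks = detect_peaks(trace_of([0, 100, 0, 100, 0]), gap_tolerance=1)
        assert len(peaks) == 1
        assert peaks[0].n_fractions == 3

    def test_deep_valley_splits_two_maxima(self):
        peaks = detect_peaks(trace_of([0, 200, 40, 180, 0]), split_ratio=0.5)
        assert len(peaks) == 2
        assert peaks[0].apex_value == 200.0
        assert peaks[1].apex_value == 180.0

    def test_shallow_valley_kept_as_one_peak(self):
        peaks = detect_peaks(trace_of([0, 200, 150, 180, 0]), split_ratio=0.5)
        assert len(peaks) == 1

    def test_all_zero_trace_yields_no_peaks(self):
        assert detect_peaks(trace_of([0, 0, 0, 0])) == []

    def test_peaks_ordered_and_disjoint(self):
        rng = np.random.default_rng(5)
        values = np.where(rng.random(200) < 0.5, 0.0, rng.random(200) * 100)
        peaks = detect_peaks(trace_of(values), gap_tolerance=1)
        for a, b in zip(peaks, peaks[1:]):
            assert a.rt_start <= a.rt_end < b.rt_start

    def test_every_nonzero_fraction_in_at_most_one_peak(self):
        rng = np.random.default_rng(9)
        values = np.where(rng.random(300) < 0.6, 0.0, rng.random(300) * 50)
        trace = trace_of(values)
        peaks = detect_peaks(trace, gap_tolerance=2, split_ratio=0.5)
        claimed = np.zeros(len(values), dtype=int)
        rt = np.asarray(trace.rt_min)
        for p in peaks:
            claimed[(rt >= p.rt_start - 1e-12) & (rt <= p.rt_end + 1e-12)] += 1
        assert claimed.max() <= 1
        assert all(claimed[i] == 1 for i in np.flatnonzero(values > 0))


class TestIntegration:
    def test_symmetric_triangle_area(self):
        trace = trace_of([0, 100, 200, 100, 0])
        peaks = detect_peaks(trace)
        # trapezoid oracle: 0.1 * (50 + 150 + 150 + 50)
        assert peaks[0].area == pytest.approx(40.0)

    def test_single_fraction_peak_gets_triangle_pair(self):
        trace = trace_of([0, 100, 0])
        peaks = detect_peaks(trace)
        assert peaks[0].area == pytest.approx(10.0)

    def test_explicit_bounds_on_zero_segment(self):
        trace = trace_of([0, 0, 0, 0, 0])
        assert integrate_peak(trace, 0.05, 0.25) == 0.0

    def test_integrate_accepts_peak_object(self):
        trace = trace_of([0, 100, 200, 100, 0])
        peak = detect_peaks(trace)[0]
        assert integrate_peak(trace, peak) == pytest.approx(peak.area)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(2)
        values = np.where(rng.random(100) < 0.5, 0.0, rng.random(100) * 10)
        base = detect_peaks(trace_of(values))
        scaled = detect_peaks(trace_of(values * 7.5))
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert b.area == pytest.approx(7.5 * a.area, rel=1e-12)

    def test_areas_match_brute_force_on_random_traces(self):
        """Oracle equivalence over many random sparse traces."""
        rng = np.random.default_rng(42)
        dt = 0.1
        worst = 0.0
        for _ in range(200):
            values = np.where(rng.random(120) < 0.55, 0.0, rng.random(120) * 1000)
            trace = trace_of(values, dt=dt)
            rt = np.asarray(trace.rt_min)
            for p in detect_peaks(trace, gap_tolerance=0, split_ratio=0.0):
                lo = int(np.flatnonzero(np.isclose(rt, p.rt_start))[0])
                hi = int(np.flatnonzero(np.isclose(rt, p.rt_end))[0])
                expected = brute_force_area(values, lo, hi, dt)
                worst = max(worst, abs(p.area - expected) / expected)
        assert worst <= 1e-9


class TestSummedScore:
    def test_sums_over_wells(self, small_merged):
        assert summed_score(small_merged, "TOX1") == 550.0

    def test_absent_accession_is_zero(self, small_merged):
        assert summed_score(small_merged, "NOPE") == 0.0

    def test_equals_trace_total(self, small_merged, schedule_6s):
        from venompsc.psc import build_psc

        trace = build_psc(small_merged, "TOX1", schedule_6s)
        assert summed_score(small_merged, "TOX1") == trace.total


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "description,family",
        [
            ("Zinc metalloproteinase/disintegrin", "SVMP"),
            ("Phospholipase A2", "PLA2"),
            ("Thrombin-like serine protease", "SVSP"),
            ("Snake venom serine proteinase 2", "SVSP"),
            ("C-type lectin lectoxin", "CTL"),
            ("L-amino acid oxidase", "LAAO"),
            ("Cytotoxin 3, three-finger toxin", "3FTx"),
            ("Cysteine-rich secretory protein", "CRISP"),
            ("Kunitz-type protease inhibitor", "VKTI"),
            ("Disintegrin lebein", "disintegrin"),
            ("hypothetical protein", "other"),
        ],
    )
    def test_default_keyword_table(self, description, family):
        assert classify_family(description) == family

    def test_custom_rules_override(self):
        rules = [("lebein", "custom")]
        assert classify_family("Disintegrin lebein", rules=rules) == "custom"


class TestFamilyAbundance:
    def test_normalized_fractions(self):
        quants = family_abundance(
            {"A": 300.0, "B": 100.0}, {"A": "SVMP", "B": "PLA2"}
        )
        assert [(q.family, q.fraction) for q in quants] == [
            ("SVMP", 0.75), ("PLA2", 0.25),
        ]

    def test_single_family_fraction_one(self):
        quants = family_abundance({"A": 5.0}, {"A": "3FTx"})
        assert quants[0].fraction == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        quantities = {f"T{i}": float(v) for i, v in enumerate(rng.random(20) * 100)}
        families = {f"T{i}": f"F{i % 5}" for i in range(20)}
        quants = family_abundance(quantities, families)
        assert sum(q.fraction for q in quants) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_yields_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert family_abundance({"A": 0.0}, {"A": "SVMP"}) == []
        assert "zero" in caplog.text

    def test_unclassified_accessions_fall_into_other(self):
        quants = family_abundance({"A": 1.0}, {})
        assert quants[0].family == "other"


class TestMatchUvPeaks:
    @staticmethod
    def uv_gaussian(apexes, heights, sigma=0.05):
        rt = np.arange(9.0, 11.5, 0.005)
        uv = np.zeros_like(rt)
        for a, h in zip(apexes, heights):
            uv += h * np.exp(-0.5 * ((rt - a) / sigma) ** 2)
        return rt, uv

    @staticmethod
    def psc_peak_at(apex_rt):
        values = [0.0] * 120
        rt = [round(0.1 * (i + 0.5), 10) for i in range(120)]
        idx = min(range(120), key=lambda i: abs(rt[i] - apex_rt))
        values[idx - 1], values[idx], values[idx + 1] = 50.0, 100.0, 50.0
        trace = PSCTrace("T", "", tuple(rt), tuple(values))
        return detect_peaks(trace)[0]

    def test_apex_within_tolerance_matched(self):
        rt, uv = self.uv_gaussian([10.03], [1.0])
        matches = match_uv_peaks([self.psc_peak_at(10.05)], rt, uv, 0.1)
        assert matches[0].status == "matched"
        assert matches[0].uv_area > 0

    def test_apex_outside_tolerance_unmatched(self):
        rt, uv = self.uv_gaussian([10.5], [1.0])
        matches = match_uv_peaks([self.psc_peak_at(10.05)], rt, uv, 0.1)
        assert matches[0].status == "unmatched"

    def test_coeluting_psc_peaks_flagged_ambiguous(self):
        rt, uv = self.uv_gaussian([10.0], [1.0])
        peaks = [self.psc_peak_at(9.95), self.psc_peak_at(10.05)]
        matches = match_uv_peaks(peaks, rt, uv, 0.1)
        assert [m.status for m in matches] == ["ambiguous", "ambiguous"]

    def test_empty_uv_trace_leaves_all_unmatched(self):
        matches = match_uv_peaks([self.psc_peak_at(10.05)], np.array([]), np.array([]))
        assert matches[0].status == "unmatched"
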